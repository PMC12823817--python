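"""Study constants and published reference values for the worked example.

The shipped example is the FAERS peripheral-nerve-palsy analysis
(2004Q1-2024Q3 public extract): the fixed margins of that study and the
published per-drug statistics of its five headline drugs, used by the
``verify-published`` entry point and the regression suite through the
contingency-table inversion oracle.
"""

from __future__ import annotations

import csv
from importlib import resources

#: total reaction-level records in the study window (the default counting universe)
REAC_RECORD_UNIVERSE = 53_463_446
#: total deduplicated reports in the study window (alternative counting universe)
REPORT_UNIVERSE = 21_838_627
#: reports of the target event (peripheral nerve palsy), the shared a+c margin
PALSY_EVENT_MARGIN = 5_787

#: published demographic/outcome counts of the 5,787 target-event case reports,
#: by facet; "unknown" rows included so every facet sums to the case total.
DEMOGRAPHIC_COUNTS: dict[str, dict[str, int]] = {
    "gender": {"F": 3551, "M": 1909, "unknown": 327},
    "weight": {"<50": 147, "50-100": 1249, ">100": 198, "unknown": 4193},
    "age": {
        "0-20": 118,
        "21-30": 171,
        "31-40": 462,
        "41-50": 748,
        "51-60": 1002,
        "61-70": 764,
        "71-80": 387,
        ">80": 131,
        "unknown": 2004,
    },
    "reporter": {"consumer": 3097, "health-professional": 2462, "unknown": 228},
    "country": {
        "United States": 3982,
        "United Kingdom": 271,
        "Canada": 214,
        "Germany": 193,
        "Japan": 144,
        "Other-Country": 983,
    },
    "outcome": {
        "CA": 7,
        "DE": 147,
        "DS": 365,
        "HO": 1740,
        "LT": 128,
        "OT": 1564,
        "RI": 10,
        "unknown": 1826,
    },
}

_NUMERIC = ("ror", "ror_low", "ror_high", "prr", "chi2", "ebgm", "ebgm05", "ic", "ic025")


def load_printed_signal_rows() -> list[dict]:
    """Published per-drug statistics shipped with the package.

    Each row carries the drug name, its report count ``a`` and the nine
    printed statistics, ready for
    :func:`faersig.inversion_oracle.verify_printed_row`.
    """
    rows = []
    path = resources.files("faersig").joinpath("data/printed_signal_rows.csv")
    with path.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            parsed: dict = {"drug": row["drug"], "a": int(row["a"])}
            for key in _NUMERIC:
                parsed[key] = float(row[key])
            rows.append(parsed)
    return rows
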