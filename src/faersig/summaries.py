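"""Demographic and outcome summaries of a case set.

One summary per facet (gender, weight band, age band, reporter type,
country, outcome), each partitioning the case set exactly: every report
lands in one level (``unknown`` included), counts sum to the case total,
and percentages are of that total.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .disproportionality import _round2
from .records import UNKNOWN, AEReport

#: pass-through map from country codes to display names; unmapped strings
#: are kept as-is (uppercased codes or already-spelled-out names).
DEFAULT_COUNTRY_NAMES = {
    "US": "United States",
    "GB": "United Kingdom",
    "UK": "United Kingdom",
    "CA": "Canada",
    "DE": "Germany",
    "JP": "Japan",
    "FR": "France",
    "IT": "Italy",
}

AGE_BANDS = ("0-20", "21-30", "31-40", "41-50", "51-60", "61-70", "71-80", ">80")
_AGE_EDGES = (20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0)

WEIGHT_BANDS = ("<50", "50-100", ">100")


@dataclass
class DemographicSummary:
    facet: str
    levels: dict[str, tuple[int, float]]  # label -> (count, percent of case total)
    denominator: int


def age_band(age_years: float | None) -> str:
    """Band with upper-inclusive edges: age 20 falls in 0-20, 20.5 in 21-30."""
    if age_years is None or age_years < 0:
        return UNKNOWN
    for edge, label in zip(_AGE_EDGES, AGE_BANDS):
        if age_years <= edge:
            return label
    return AGE_BANDS[-1]


def weight_band(weight_kg: float | None) -> str:
    if weight_kg is None or weight_kg < 0:
        return UNKNOWN
    if weight_kg < 50.0:
        return "<50"
    if weight_kg <= 100.0:
        return "50-100"
    return ">100"


def _facet_summary(facet: str, counts: Counter, denominator: int, order: list[str]) -> DemographicSummary:
    levels = {}
    for label in order:
        n = counts.get(label, 0)
        pct = _round2(100.0 * n / denominator) if denominator else 0.0
        levels[label] = (n, pct)
    return DemographicSummary(facet=facet, levels=levels, denominator=denominator)


def summarize(
    cases: list[AEReport],
    country_names: dict[str, str] | None = None,
    top_countries: int = 5,
) -> list[DemographicSummary]:
    """Per-facet counts and percentages over the case set.

    The country facet lists the ``top_countries`` most frequent countries
    plus an ``Other-Country`` catch-all (which absorbs unknowns).  An empty
    case set yields all-zero facets with denominator 0.
    """
    names = {**DEFAULT_COUNTRY_NAMES, **(country_names or {})}
    n = len(cases)

    gender = Counter(r.sex if r.sex in ("F", "M") else UNKNOWN for r in cases)
    weight = Counter(weight_band(r.weight_kg) for r in cases)
    age = Counter(age_band(r.age_years) for r in cases)
    reporter = Counter(r.reporter for r in cases)
    outcome = Counter(r.outcome for r in cases)

    country_raw = Counter(
        names.get(r.country, r.country) for r in cases if r.country != UNKNOWN
    )
    top = [c for c, _ in sorted(country_raw.items(), key=lambda kv: (-kv[1], kv[0]))[:top_countries]]
    country = Counter()
    for label, cnt in country_raw.items():
        country[label if label in top else "Other-Country"] += cnt
    country["Other-Country"] += sum(1 for r in cases if r.country == UNKNOWN)

    return [
        _facet_summary("gender", gender, n, ["F", "M", UNKNOWN]),
        _facet_summary("weight", weight, n, [*WEIGHT_BANDS, UNKNOWN]),
        _facet_summary("age", age, n, [*AGE_BANDS, UNKNOWN]),
        _facet_summary("reporter", reporter, n, ["consumer", "health-professional", UNKNOWN]),
        _facet_summary("country", country, n, [*top, "Other-Country"]),
        _facet_summary(
            "outcome", outcome, n, [*sorted(set(outcome) - {UNKNOWN}), UNKNOWN]
        ),
    ]


def yearly_counts(cases: list[AEReport]) -> dict[int, int]:
    """Reports per FDA-receipt year, densified so gap years appear with 0."""
    years = [r.event_year for r in cases if r.fda_dt > 0]
    if not years:
        return {}
    counts = Counter(years)
    return {y: counts.get(y, 0) for y in range(min(years), max(years) + 1)}
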