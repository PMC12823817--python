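"""Case-level deduplication and outcome collapsing.

FAERS distributes a new version of a case whenever it is re-reported, so
the same clinical event appears under several PRIMARYIDs sharing one
CASEID.  The FDA-recommended rule keeps, per CASEID, the report with the
most recent FDA receipt date, breaking ties on the higher PRIMARYID.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .records import OUTCOME_CODES, UNKNOWN, AEReport

#: Severity order used to collapse multiple outcome codes to one:
#: death > life-threatening > disability > congenital anomaly >
#: required intervention > hospitalization > other serious.
DEFAULT_OUTCOME_PRECEDENCE = OUTCOME_CODES


@dataclass
class DedupAudit:
    """Conservation record for a deduplication pass: n_in = n_out + n_dropped_same_caseid."""

    n_in: int
    n_out: int
    n_dropped_same_caseid: int
    #: for each dropped report, which comparison decided it: "FDA_DT" or "PRIMARYID"
    rule_used_per_drop: list[str] = field(default_factory=list)


def _primaryid_key(primaryid: str) -> tuple[int, int | str]:
    """Sort key for 'higher PRIMARYID': numeric when the id parses as an integer."""
    try:
        return (1, int(primaryid))
    except (TypeError, ValueError):
        return (0, str(primaryid))


def _survivor_key(report: AEReport) -> tuple:
    fda = report.fda_dt if isinstance(report.fda_dt, int) else 0
    return (fda, _primaryid_key(report.primaryid))


def deduplicate(reports: list[AEReport]) -> tuple[list[AEReport], DedupAudit]:
    """Keep one report per caseid: latest fda_dt, ties broken on higher primaryid.

    Output is sorted by caseid so repeated runs are byte-stable.  An
    unparseable fda_dt sorts as the minimal date, so any dated version of
    the case wins over it.
    """
    by_case: dict[str, AEReport] = {}
    rules: list[str] = []
    for rep in reports:
        held = by_case.get(rep.caseid)
        if held is None:
            by_case[rep.caseid] = rep
            continue
        if _survivor_key(rep) > _survivor_key(held):
            loser = held
            by_case[rep.caseid] = rep
        else:
            loser = rep
        winner = by_case[rep.caseid]
        rules.append("FDA_DT" if winner.fda_dt != loser.fda_dt else "PRIMARYID")
    survivors = [by_case[cid] for cid in sorted(by_case)]
    audit = DedupAudit(
        n_in=len(reports),
        n_out=len(survivors),
        n_dropped_same_caseid=len(reports) - len(survivors),
        rule_used_per_drop=rules,
    )
    return survivors, audit


def drop_reactionless(reports: list[AEReport]) -> tuple[list[AEReport], int]:
    """Remove reports with no reaction rows (they cannot enter any 2x2 cell)."""
    kept = [r for r in reports if r.reactions]
    return kept, len(reports) - len(kept)


def collapse_outcome(
    outcome_codes: set[str],
    precedence: tuple[str, ...] = DEFAULT_OUTCOME_PRECEDENCE,
) -> str:
    """Collapse a report's outcome codes to the single most severe one.

    Unknown codes are ignored with a warning; an empty (or all-unknown) set
    collapses to ``"unknown"``.
    """
    known = {c for c in outcome_codes if c in precedence}
    bad = set(outcome_codes) - known
    if bad:
        warnings.warn(f"ignoring unknown outcome codes: {sorted(bad)}", stacklevel=2)
    if not known:
        return UNKNOWN
    return min(known, key=precedence.index)
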