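"""Per-drug 2x2 contingency tables against the database background.

For a target drug and target event the quadruple is

=============  ============  ===========
               target event  other events
=============  ============  ===========
target drug         a             b
other drugs         c             d
=============  ============  ===========

Two counting universes are supported.  Under the default ``records``
universe the counting unit is the reaction-level record (one (report, PT)
pair), so N is the total number of reaction records and a report with k
matching PTs contributes k to the drug's ``a``.  Under the ``reports``
universe the unit is the deduplicated report.  The record universe is the
one whose margins make the printed reference statistics internally
consistent, and is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

from .case_query import PTQuery, normalize_drug, normalize_pt
from .records import AEReport

SUSPECT_ROLES = frozenset({"PS", "SS"})
ALL_ROLES = frozenset({"PS", "SS", "C", "I"})


@dataclass(frozen=True)
class ContingencyTable:
    """The (a, b, c, d) quadruple; N is the size of the counting universe."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative cell in {self!r}")

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def event_margin(self) -> int:
        return self.a + self.c

    @property
    def drug_margin(self) -> int:
        return self.a + self.b

    def haldane(self) -> "HaldaneTable":
        """The same table with 0.5 added to every cell (zero-cell correction)."""
        return HaldaneTable(self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)


@dataclass(frozen=True)
class HaldaneTable:
    a: float
    b: float
    c: float
    d: float

    @property
    def n_total(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def event_margin(self) -> float:
        return self.a + self.c

    @property
    def drug_margin(self) -> float:
        return self.a + self.b


def build_tables(
    reports: list[AEReport],
    cases: set[str],
    drugs: list[str],
    *,
    query: PTQuery | None = None,
    universe: str = "records",
    roles: frozenset[str] = SUSPECT_ROLES,
    synonym_map=None,
) -> dict[str, ContingencyTable]:
    """One 2x2 table per requested drug, all sharing the same event margin and N.

    ``cases`` is the report-level case set from :func:`~faersig.case_query.select_cases`.
    Under the ``records`` universe ``query`` is required, because the
    matching reactions must be identified within each case report; under
    the ``reports`` universe ``cases`` alone suffices.  Drug names (both in
    ``drugs`` and on the reports) are canonicalized with ``synonym_map``.
    A drug absent from the data gets a valid a = b = 0 table.
    """
    if universe not in ("records", "reports"):
        raise ValueError(f"unknown universe {universe!r}")
    if universe == "records" and query is None:
        raise ValueError("record universe requires the PT query to classify reaction records")
    active = query.active_terms() if query is not None else None

    targets = {normalize_drug(d, synonym_map) for d in drugs}
    a_by_drug = dict.fromkeys(targets, 0)
    ab_by_drug = dict.fromkeys(targets, 0)
    n_total = 0
    event_margin = 0

    for rep in reports:
        if universe == "records":
            k = len(rep.reactions)
            m = sum(1 for pt in rep.reactions if normalize_pt(pt) in active)  # type: ignore[operator]
        else:
            k = 1
            m = 1 if rep.primaryid in cases else 0
        n_total += k
        event_margin += m
        if k == 0:
            continue
        for name in {normalize_drug(nm, synonym_map) for nm, role in rep.drugs if role in roles}:
            if name in targets:
                a_by_drug[name] += m
                ab_by_drug[name] += k

    tables = {}
    for name in targets:
        a = a_by_drug[name]
        b = ab_by_drug[name] - a
        c = event_margin - a
        d = n_total - a - b - c
        tables[name] = ContingencyTable(a, b, c, d)
    return tables


def margin_check(tables: dict[str, ContingencyTable]) -> list[str]:
    """Diagnostic: every table from one dataset must share (a+c) and N.

    Returns a list of human-readable violations; empty means consistent.
    """
    if not tables:
        return []
    violations = []
    ref_drug = next(iter(sorted(tables)))
    ref = tables[ref_drug]
    for drug in sorted(tables):
        t = tables[drug]
        if t.event_margin != ref.event_margin:
            violations.append(
                f"{drug}: event margin a+c={t.event_margin} != {ref.event_margin} ({ref_drug})"
            )
        if t.n_total != ref.n_total:
            violations.append(f"{drug}: N={t.n_total} != {ref.n_total} ({ref_drug})")
    return violations
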