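"""Core record containers shared across the pipeline.

``AEReport`` is the unit everything downstream works on: one safety report
with its identifiers, demographics, drug list and reaction set.
``RawRecordSet`` is the pre-join bundle of table rows parsed from one
quarterly file set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

UNKNOWN = "unknown"

#: FDA outcome codes: death, life-threatening, disability, congenital anomaly,
#: required intervention, hospitalization (initial or prolonged), other serious.
OUTCOME_CODES = ("DE", "LT", "DS", "CA", "RI", "HO", "OT")

#: FAERS drug role codes: primary suspect, secondary suspect, concomitant,
#: interacting.
DRUG_ROLES = ("PS", "SS", "C", "I")


@dataclass
class AEReport:
    """One safety report (one version of one case).

    ``primaryid`` identifies the report version, ``caseid`` the underlying
    case; several primaryids may share a caseid across quarters until
    deduplication keeps one.  Unknown demographics are ``None`` (numeric
    fields) or the string ``"unknown"`` (categorical fields).
    """

    primaryid: str
    caseid: str
    fda_dt: int  # YYYYMMDD; partial dates padded with 01
    sex: str = UNKNOWN  # "F" | "M" | "unknown"
    age_years: float | None = None
    weight_kg: float | None = None
    reporter: str = UNKNOWN  # "consumer" | "health-professional" | "unknown"
    country: str = UNKNOWN
    outcome: str = UNKNOWN  # single collapsed code from OUTCOME_CODES, or unknown
    drugs: list[tuple[str, str]] = field(default_factory=list)  # (name, role)
    reactions: set[str] = field(default_factory=set)  # MedDRA PT strings

    @property
    def event_year(self) -> int:
        return self.fda_dt // 10000

    def drug_names(self, roles: set[str] | None = None) -> set[str]:
        """Distinct drug names, optionally restricted to the given role codes."""
        if roles is None:
            return {name for name, _ in self.drugs}
        return {name for name, role in self.drugs if role in roles}


def report_to_dict(report: AEReport) -> dict:
    """JSON-serializable form of a report (inverse of :func:`report_from_dict`)."""
    return {
        "primaryid": report.primaryid,
        "caseid": report.caseid,
        "fda_dt": report.fda_dt,
        "sex": report.sex,
        "age_years": report.age_years,
        "weight_kg": report.weight_kg,
        "reporter": report.reporter,
        "country": report.country,
        "outcome": report.outcome,
        "drugs": [list(d) for d in report.drugs],
        "reactions": sorted(report.reactions),
    }


def report_from_dict(data: dict) -> AEReport:
    return AEReport(
        primaryid=data["primaryid"],
        caseid=data["caseid"],
        fda_dt=data["fda_dt"],
        sex=data.get("sex", UNKNOWN),
        age_years=data.get("age_years"),
        weight_kg=data.get("weight_kg"),
        reporter=data.get("reporter", UNKNOWN),
        country=data.get("country", UNKNOWN),
        outcome=data.get("outcome", UNKNOWN),
        drugs=[tuple(d) for d in data.get("drugs", [])],
        reactions=set(data.get("reactions", [])),
    )


@dataclass
class RawRecordSet:
    """Parsed rows of one quarterly file set, before the table join.

    Rows whose report id never appears in DEMO are kept in the per-table
    maps but tallied in ``orphans`` so nothing is silently lost; lines that
    could not be parsed at all are tallied in ``skips``.  For every table,
    ``lines_in = rows_out + skips + 1`` (the header).
    """

    demo_rows: list[dict] = field(default_factory=list)
    drug_rows: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    reac_rows: dict[str, list[str]] = field(default_factory=dict)
    outc_rows: dict[str, list[str]] = field(default_factory=dict)
    skips: dict[str, int] = field(default_factory=dict)
    orphans: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def n_rows(self) -> dict[str, int]:
        return {
            "DEMO": len(self.demo_rows),
            "DRUG": sum(len(v) for v in self.drug_rows.values()),
            "REAC": sum(len(v) for v in self.reac_rows.values()),
            "OUTC": sum(len(v) for v in self.outc_rows.values()),
        }
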