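"""Reading and writing FAERS-style quarterly ASCII tables.

The public FAERS extract ships one ``$``-delimited text file per table and
quarter (``DEMO24Q3.txt``, ``DRUG24Q3.txt``, ``REAC24Q3.txt``,
``OUTC24Q3.txt``), each with a header line and no quoting convention.
Only the post-2012 layout is modeled; columns are resolved by header name
through a case-insensitive synonym table, never by position.
"""

from __future__ import annotations

import warnings
from pathlib import Path

from .preprocess import collapse_outcome
from .records import DRUG_ROLES, UNKNOWN, AEReport, RawRecordSet

DELIMITER = "$"
TABLES = ("DEMO", "DRUG", "REAC", "OUTC")

LBS_PER_KG = 0.453592

# header-name synonyms, case-insensitive -> canonical field
_COLUMN_SYNONYMS = {
    "primaryid": "primaryid",
    "caseid": "caseid",
    "fda_dt": "fda_dt",
    "age": "age",
    "age_cod": "age_cod",
    "sex": "sex",
    "gndr_cod": "sex",
    "wt": "wt",
    "wt_cod": "wt_cod",
    "occp_cod": "occp_cod",
    "occr_country": "occr_country",
    "reporter_country": "occr_country",
    "drugname": "drugname",
    "role_cod": "role_cod",
    "pt": "pt",
    "outc_cod": "outc_cod",
    "outc_code": "outc_cod",
}

_AGE_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

_OCCP_TO_REPORTER = {
    "CN": "consumer",
    "MD": "health-professional",
    "PH": "health-professional",
    "HP": "health-professional",
    "OT": "health-professional",
    "RN": "health-professional",
}


def _resolve_header(header_line: str) -> list[str | None]:
    cols = []
    for name in header_line.rstrip("\n").split(DELIMITER):
        cols.append(_COLUMN_SYNONYMS.get(name.strip().lower()))
    return cols


def _read_table(path: Path, required_fields: tuple[str, ...]) -> tuple[list[dict], int]:
    """Parse one table file into row dicts; returns (rows, skipped-line count)."""
    rows: list[dict] = []
    skips = 0
    with path.open("r", encoding="utf-8", errors="replace") as fh:
        header = fh.readline()
        if not header.strip():
            return [], 0
        columns = _resolve_header(header)
        n_cols = len(columns)
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split(DELIMITER)
            if len(parts) != n_cols:
                skips += 1
                continue
            row = {col: val.strip() for col, val in zip(columns, parts) if col}
            if any(not row.get(f) for f in required_fields):
                skips += 1
                continue
            rows.append(row)
    return rows, skips


def read_quarter(dir_path: str | Path, quarter_tag: str) -> RawRecordSet:
    """Read one quarter's DEMO/DRUG/REAC/OUTC files into a :class:`RawRecordSet`.

    A missing DEMO file is a hard error; a missing OUTC (or DRUG/REAC) file
    degrades to a warning and empty rows.  Malformed lines are skipped and
    counted per table; rows referencing a report id absent from DEMO are
    retained but counted as orphans.
    """
    dir_path = Path(dir_path)
    raw = RawRecordSet()

    demo_path = dir_path / f"DEMO{quarter_tag}.txt"
    if not demo_path.exists():
        raise FileNotFoundError(f"required file missing: {demo_path}")

    raw.demo_rows, raw.skips["DEMO"] = _read_table(demo_path, ("primaryid", "caseid"))
    demo_ids = {row["primaryid"] for row in raw.demo_rows}

    for table, target, fields in (
        ("DRUG", raw.drug_rows, ("primaryid", "drugname")),
        ("REAC", raw.reac_rows, ("primaryid", "pt")),
        ("OUTC", raw.outc_rows, ("primaryid", "outc_cod")),
    ):
        path = dir_path / f"{table}{quarter_tag}.txt"
        if not path.exists():
            msg = f"missing {table} file for quarter {quarter_tag}; continuing without it"
            warnings.warn(msg, stacklevel=2)
            raw.warnings.append(msg)
            raw.skips[table] = 0
            raw.orphans[table] = 0
            continue
        rows, raw.skips[table] = _read_table(path, fields)
        orphans = 0
        for row in rows:
            pid = row["primaryid"]
            if pid not in demo_ids:
                orphans += 1
            if table == "DRUG":
                role = row.get("role_cod", "").upper()
                target.setdefault(pid, []).append(
                    (row["drugname"], role if role in DRUG_ROLES else "C")
                )
            elif table == "REAC":
                target.setdefault(pid, []).append(row["pt"])
            else:
                target.setdefault(pid, []).append(row["outc_cod"].upper())
        raw.orphans[table] = orphans
    return raw


def _parse_date(text: str | None) -> int:
    """YYYYMMDD integer; partial dates (YYYYMM, YYYY) are padded with 01."""
    if not text or not text.isdigit():
        return 0
    if len(text) == 8:
        return int(text)
    if len(text) == 6:
        return int(text) * 100 + 1
    if len(text) == 4:
        return int(text) * 10000 + 101
    return 0


def _parse_age(age: str | None, age_cod: str | None) -> float | None:
    try:
        value = float(age)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        return None
    factor = _AGE_TO_YEARS.get((age_cod or "YR").upper())
    if factor is None or value < 0:
        return None
    return value * factor


def _parse_weight(wt: str | None, wt_cod: str | None) -> float | None:
    try:
        value = float(wt)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        return None
    if value < 0:
        return None
    code = (wt_cod or "KG").upper()
    if code == "KG":
        return value
    if code == "LBS":
        return value * LBS_PER_KG
    if code == "GMS":
        return value / 1000.0
    return None


def assemble_reports(raw: RawRecordSet) -> list[AEReport]:
    """Join the four tables on report id into pre-dedup :class:`AEReport` records.

    Every field falls back to unknown on a missing or invalid value; no row
    is rejected here.
    """
    reports = []
    for row in raw.demo_rows:
        pid = row["primaryid"]
        sex = row.get("sex", "").upper()
        country = row.get("occr_country", "")
        reports.append(
            AEReport(
                primaryid=pid,
                caseid=row.get("caseid") or pid,
                fda_dt=_parse_date(row.get("fda_dt")),
                sex=sex if sex in ("F", "M") else UNKNOWN,
                age_years=_parse_age(row.get("age"), row.get("age_cod")),
                weight_kg=_parse_weight(row.get("wt"), row.get("wt_cod")),
                reporter=_OCCP_TO_REPORTER.get(row.get("occp_cod", "").upper(), UNKNOWN),
                country=country or UNKNOWN,
                outcome=collapse_outcome(set(raw.outc_rows.get(pid, []))),
                drugs=list(raw.drug_rows.get(pid, [])),
                reactions=set(raw.reac_rows.get(pid, [])),
            )
        )
    return reports


def _sanitize(text: str) -> str:
    # FAERS ASCII has no quoting convention; an embedded delimiter would
    # shift every downstream column, so it is replaced on write.
    return text.replace(DELIMITER, "?").replace("\n", " ").replace("\r", " ")


def _fmt_num(value: float | None) -> str:
    if value is None:
        return ""
    return f"{value:.6g}"


def write_quarter(reports: list[AEReport], dir_path: str | Path, quarter_tag: str) -> list[Path]:
    """Write reports as a readable FAERS-style quarter (inverse of read+assemble).

    Ages are written in years (``YR``) and weights in kilograms, so a
    round-trip reproduces every modeled field; the original unit codes are
    not preserved.
    """
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    reporter_back = {"consumer": "CN", "health-professional": "MD"}
    paths = []

    def lines(table: str):
        if table == "DEMO":
            yield "primaryid$caseid$fda_dt$age$age_cod$sex$wt$wt_cod$occp_cod$occr_country"
            for r in reports:
                age = _fmt_num(r.age_years)
                wt = _fmt_num(r.weight_kg)
                yield DELIMITER.join(
                    [
                        _sanitize(r.primaryid),
                        _sanitize(r.caseid),
                        str(r.fda_dt) if r.fda_dt else "",
                        age,
                        "YR" if age else "",
                        r.sex if r.sex in ("F", "M") else "",
                        wt,
                        "KG" if wt else "",
                        reporter_back.get(r.reporter, ""),
                        "" if r.country == UNKNOWN else _sanitize(r.country),
                    ]
                )
        elif table == "DRUG":
            yield "primaryid$caseid$drug_seq$role_cod$drugname"
            for r in reports:
                for seq, (name, role) in enumerate(r.drugs, start=1):
                    yield DELIMITER.join(
                        [r.primaryid, r.caseid, str(seq), role, _sanitize(name)]
                    )
        elif table == "REAC":
            yield "primaryid$caseid$pt"
            for r in reports:
                for pt in sorted(r.reactions):
                    yield DELIMITER.join([r.primaryid, r.caseid, _sanitize(pt)])
        else:
            yield "primaryid$caseid$outc_cod"
            for r in reports:
                if r.outcome != UNKNOWN:
                    yield DELIMITER.join([r.primaryid, r.caseid, r.outcome])

    for table in TABLES:
        path = dir_path / f"{table}{quarter_tag}.txt"
        with path.open("w", encoding="utf-8") as fh:
            for line in lines(table):
                fh.write(line + "\n")
        paths.append(path)
    return paths
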