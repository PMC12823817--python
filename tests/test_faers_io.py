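"""Quarterly ASCII parsing, table joining and round-trip writing."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from faersig.faers_io import assemble_reports, read_quarter, write_quarter
from faersig.records import AEReport


def _write(path, name, lines):
    (path / name).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _stub_quarter(path, demo, drug=("primaryid$caseid$drug_seq$role_cod$drugname",),
                  reac=("primaryid$caseid$pt",), outc=("primaryid$caseid$outc_cod",)):
    _write(path, "DEMO24Q1.txt", demo)
    _write(path, "DRUG24Q1.txt", drug)
    _write(path, "REAC24Q1.txt", reac)
    _write(path, "OUTC24Q1.txt", outc)


def test_header_only_files_parse_to_zero_rows(tmp_path):
    _stub_quarter(tmp_path, ["primaryid$caseid$fda_dt"])
    raw = read_quarter(tmp_path, "24Q1")
    assert raw.n_rows() == {"DEMO": 0, "DRUG": 0, "REAC": 0, "OUTC": 0}
    assert sum(raw.skips.values()) == 0


def test_malformed_demo_row_is_skipped_and_counted(tmp_path):
    _stub_quarter(tmp_path, [
        "primaryid$caseid$fda_dt",
        "1011$1$20240101",
        "bad line without enough fields",
    ])
    raw = read_quarter(tmp_path, "24Q1")
    assert len(raw.demo_rows) == 1
    assert raw.skips["DEMO"] == 1


def test_orphan_drug_row_is_counted(tmp_path):
    _stub_quarter(
        tmp_path,
        ["primaryid$caseid$fda_dt", "1011$1$20240101"],
        drug=["primaryid$caseid$drug_seq$role_cod$drugname", "9999$9$1$PS$drug z"],
    )
    raw = read_quarter(tmp_path, "24Q1")
    assert raw.orphans["DRUG"] == 1


def test_missing_demo_is_hard_error(tmp_path):
    with pytest.raises(FileNotFoundError):
        read_quarter(tmp_path, "24Q1")


def test_missing_outc_degrades_to_unknown_outcomes(tmp_path):
    _stub_quarter(tmp_path, ["primaryid$caseid$fda_dt", "1011$1$20240101"])
    (tmp_path / "OUTC24Q1.txt").unlink()
    with pytest.warns(UserWarning, match="missing OUTC"):
        raw = read_quarter(tmp_path, "24Q1")
    reports = assemble_reports(raw)
    assert reports[0].outcome == "unknown"


def test_byte_noise_in_non_demo_files_never_raises(tmp_path):
    _stub_quarter(
        tmp_path,
        ["primaryid$caseid$fda_dt", "1011$1$20240101"],
        reac=["primaryid$caseid$pt", "1011$1$nausea", "\x00\xff garbage $$$$", "$$$"],
    )
    raw = read_quarter(tmp_path, "24Q1")
    # every input line is accounted for: rows + skips + header
    assert 1 + raw.skips["REAC"] == 3
    assert raw.reac_rows["1011"] == ["nausea"]


def test_unit_conversions_and_join(tmp_path):
    _stub_quarter(
        tmp_path,
        [
            "primaryid$caseid$fda_dt$age$age_cod$sex$wt$wt_cod$occp_cod$occr_country",
            "1011$1$20240101$720$MON$F$220$LBS$CN$US",
        ],
        drug=["primaryid$caseid$drug_seq$role_cod$drugname",
              "1011$1$1$PS$drug a", "1011$1$2$SS$drug b"],
        reac=["primaryid$caseid$pt", "1011$1$nausea", "1011$1$rash", "1011$1$headache"],
        outc=["primaryid$caseid$outc_cod", "1011$1$HO", "1011$1$DE"],
    )
    rep = assemble_reports(read_quarter(tmp_path, "24Q1"))[0]
    assert rep.age_years == pytest.approx(60.0)
    assert rep.weight_kg == pytest.approx(99.79, abs=0.01)
    assert len(rep.drugs) == 2 and len(rep.reactions) == 3
    assert rep.outcome == "DE"  # death outranks hospitalization
    assert rep.reporter == "consumer"


def test_partial_dates_padded(tmp_path):
    _stub_quarter(tmp_path, [
        "primaryid$caseid$fda_dt",
        "1011$1$202403", "2011$2$2024",
    ])
    reports = assemble_reports(read_quarter(tmp_path, "24Q1"))
    assert {r.fda_dt for r in reports} == {20240301, 20240101}


def test_column_resolution_by_synonym_header(tmp_path):
    # pre-2014 DEMO spells the sex column gndr_cod
    _stub_quarter(tmp_path, [
        "primaryid$caseid$fda_dt$gndr_cod", "1011$1$20240101$F",
    ])
    rep = assemble_reports(read_quarter(tmp_path, "24Q1"))[0]
    assert rep.sex == "F"


def test_dollar_in_drug_name_sanitized_on_write(tmp_path, micro4):
    rep = micro4[0]
    rep.drugs[0] = ("drug$with$dollars", "PS")
    write_quarter([rep], tmp_path, "24Q1")
    back = assemble_reports(read_quarter(tmp_path, "24Q1"))[0]
    assert ("drug?with?dollars", "PS") in back.drugs
    assert sum(read_quarter(tmp_path, "24Q1").skips.values()) == 0


def test_empty_report_list_writes_header_only_files(tmp_path):
    paths = write_quarter([], tmp_path, "24Q1")
    assert all(len(p.read_text().splitlines()) == 1 for p in paths)


def test_round_trip_micro_fixture(tmp_path, micro4):
    write_quarter(micro4, tmp_path, "24Q1")
    back = assemble_reports(read_quarter(tmp_path, "24Q1"))
    assert {r.primaryid: r for r in back} == {r.primaryid: r for r in micro4}


_names = st.text(
    alphabet=st.characters(codec="ascii", exclude_characters="$\n\r", categories=["L", "N", "Zs"]),
    min_size=1, max_size=12,
).map(str.strip).filter(bool)


@st.composite
def _reports(draw):
    i = draw(st.integers(1, 10_000))
    return AEReport(
        primaryid=f"{i}1",
        caseid=str(i),
        fda_dt=draw(st.integers(2004, 2024)) * 10000 + draw(st.integers(1, 12)) * 100
        + draw(st.integers(1, 28)),
        sex=draw(st.sampled_from(["F", "M", "unknown"])),
        age_years=draw(st.one_of(st.none(), st.floats(0, 100).map(lambda x: round(x, 3)))),
        weight_kg=draw(st.one_of(st.none(), st.floats(1, 200).map(lambda x: round(x, 3)))),
        reporter=draw(st.sampled_from(["consumer", "health-professional", "unknown"])),
        country=draw(_names),
        outcome=draw(st.sampled_from(["DE", "HO", "OT", "unknown"])),
        drugs=draw(st.lists(st.tuples(_names, st.sampled_from(["PS", "SS", "C", "I"])), max_size=4)),
        reactions=draw(st.sets(_names, max_size=4)),
    )


@given(st.lists(_reports(), max_size=8, unique_by=lambda r: r.primaryid))
def test_read_write_identity_property(tmp_path_factory, reports):
    """read(write(x)) == x on all modeled fields, for arbitrary valid reports."""
    tmp = tmp_path_factory.mktemp("rt")
    write_quarter(reports, tmp, "24Q1")
    back = assemble_reports(read_quarter(tmp, "24Q1"))
    assert {r.primaryid: r for r in back} == {r.primaryid: r for r in reports}
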