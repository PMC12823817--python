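"""Disproportionality statistics against independent references, plus the
algebraic identities that tie the four estimators together."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import chi2_contingency
from statsmodels.stats.contingency_tables import Table2x2

from faersig.contingency import ContingencyTable
from faersig.disproportionality import (
    SignalCriteria,
    SignalResult,
    bcpnn_stat,
    classify_risk,
    evaluate_signal,
    mgps_stat,
    prr_stat,
    rank_report,
    ror_stat,
)

cells = st.integers(1, 5_000_000)
tables = st.builds(ContingencyTable, cells, cells, cells, cells)


@st.composite
def database_tables(draw):
    """Tables in the spontaneous-reporting regime: the drug's target-event
    records are a minority of its records and of the event margin, and the
    no-drug/no-event cell dominates the universe."""
    a = draw(st.integers(1, 2000))
    b = a * draw(st.integers(10, 500))
    c = a * draw(st.integers(1, 50)) + draw(st.integers(0, 1000))
    d = (a + b + c) * draw(st.integers(10, 2000))
    return ContingencyTable(a, b, c, d)


@given(tables)
def test_ror_matches_statsmodels(t):
    """Point ROR and Wald CI agree with the reference odds-ratio implementation."""
    res = ror_stat(t)
    ref = Table2x2(np.array([[t.a, t.b], [t.c, t.d]]))
    assert res.ror == pytest.approx(ref.oddsratio)
    low, high = ref.oddsratio_confint(0.05)
    # the conventional CI formula uses z = 1.96 where statsmodels uses the
    # exact 97.5% quantile; agreement is to ~4 significant digits
    assert res.ci_low == pytest.approx(low, rel=1e-3)
    assert res.ci_high == pytest.approx(high, rel=1e-3)


@given(tables)
def test_chi2_matches_scipy(t):
    """The chi-square pairs with scipy's uncorrected Pearson statistic."""
    chi2 = prr_stat(t).chi2
    ref = chi2_contingency([[t.a, t.b], [t.c, t.d]], correction=False).statistic
    assert chi2 == pytest.approx(ref, rel=1e-9)


@given(st.integers(1, 10_000))
def test_symmetric_table_is_null(k):
    t = ContingencyTable(k, k, k, k)
    assert ror_stat(t).ror == pytest.approx(1.0)
    prr = prr_stat(t)
    assert prr.prr == pytest.approx(1.0) and prr.chi2 == pytest.approx(0.0, abs=1e-9)
    ic = bcpnn_stat(t)
    assert ic.ic == pytest.approx(0.0) and ic.ic025 < 0
    assert mgps_stat(t).ebgm == pytest.approx(1.0)


@given(tables)
def test_ebgm_is_two_to_the_ic(t):
    """EBGM and IC share one core expression: ebgm = 2**ic to machine precision."""
    assert mgps_stat(t).ebgm == pytest.approx(2.0 ** bcpnn_stat(t).ic, rel=1e-12)


@given(tables)
def test_ror_prr_ordering_identity(t):
    """ROR and PRR sit on the same side of 1: sign(ror - prr) = sign(ror - 1)."""
    ror, prr = ror_stat(t).ror, prr_stat(t).prr
    if not math.isclose(ror, 1.0, rel_tol=1e-12):
        assert (ror > prr) == (ror > 1.0)


@given(database_tables())
def test_all_four_strictly_increase_in_a(t):
    """In the reporting-database regime, one more co-occurrence strictly
    strengthens all four statistics (IC and EBGM are not globally monotone:
    on tiny tables the margin growth can cancel the numerator's)."""
    bumped = ContingencyTable(t.a + 1, t.b, t.c, t.d)
    assert ror_stat(bumped).ror > ror_stat(t).ror
    assert prr_stat(bumped).prr > prr_stat(t).prr
    assert bcpnn_stat(bumped).ic > bcpnn_stat(t).ic
    assert mgps_stat(bumped).ebgm > mgps_stat(t).ebgm


@given(tables)
def test_interval_coherence_and_z_monotonicity(t):
    ror = ror_stat(t)
    assert ror.ci_low <= ror.ror <= ror.ci_high
    narrow = ror_stat(t, z=1.0)
    assert narrow.ci_high - narrow.ci_low < ror.ci_high - ror.ci_low
    ic = bcpnn_stat(t)
    assert ic.ic025 <= ic.ic
    ebgm = mgps_stat(t)
    assert ebgm.ebgm05 <= ebgm.ebgm
    assert mgps_stat(t, z=1.96).ebgm05 < ebgm.ebgm05


def test_zero_cells_yield_nan_without_haldane_and_values_with():
    t = ContingencyTable(3, 0, 5, 100)
    assert math.isnan(ror_stat(t).ror)
    corrected = ror_stat(t, haldane=True)
    assert corrected.ror == pytest.approx((3.5 * 100.5) / (0.5 * 5.5))
    assert math.isnan(bcpnn_stat(ContingencyTable(0, 5, 5, 100)).ic)
    assert math.isnan(mgps_stat(ContingencyTable(0, 5, 5, 100)).ebgm)


def test_bate_interval_close_to_calibrated_at_large_counts():
    # posterior expansion and the closed-form calibration agree when a is large
    t = ContingencyTable(625, 405517, 5162, 53052142)
    cal, bate = bcpnn_stat(t), bcpnn_stat(t, variant="bate")
    assert bate.ic == pytest.approx(cal.ic, abs=0.05)
    assert bate.ic025 == pytest.approx(cal.ic025, abs=0.1)


@pytest.mark.parametrize(
    "ic025,band",
    [
        (float("nan"), "none"), (-0.5, "none"), (0.0, "none"),
        (0.01, "low"), (1.5, "low"),
        (1.51, "moderate"), (2.0, "moderate"), (3.0, "moderate"),
        (3.01, "high"), (5.68, "high"),
    ],
)
def test_classify_risk_bands(ic025, band):
    assert classify_risk(ic025) == band


def test_evaluate_signal_flags_all_positive():
    # strongly associated table (reconstruction of the strongest example drug)
    t = ContingencyTable(31, 3888, 5756, 53453771)
    res = evaluate_signal(t, drug="bupivacaine")
    assert all(res.flags[k] for k in ("ror_pos", "prr_pos", "bcpnn_pos", "mgps_pos", "all_four", "any"))
    assert res.risk_band == "high"


def test_min_report_rule_gates_ror_and_prr_only():
    t = ContingencyTable(2, 10, 100, 1_000_000)  # strong ratio, only 2 reports
    res = evaluate_signal(t)
    assert not res.flags["ror_pos"] and not res.flags["prr_pos"]
    assert res.flags["bcpnn_pos"] and res.flags["mgps_pos"]  # evaluated on their own criteria
    assert res.flags["any"] and not res.flags["all_four"]


def test_independence_table_has_no_flags():
    res = evaluate_signal(ContingencyTable(50, 50, 50, 50))
    assert not res.flags["any"]


def test_criteria_thresholds_must_be_positive():
    with pytest.raises(ValueError):
        SignalCriteria(prr_ge=0.0)


def _result(drug, n):
    return SignalResult(drug=drug, n_reports=n, ror=1.234567, ror_ci95=(1.0, 1.5),
                        prr=1.0, chi2=0.5, ic=0.1, ic025=-0.2, ebgm=1.1, ebgm05=0.9,
                        flags={"any": False}, risk_band="none")


def test_rank_report_order_ties_and_truncation():
    results = [_result("natalizumab", 625), _result("dalfampridine", 406),
               _result("interferon beta-1a", 453), _result("aaa", 406)]
    rows = rank_report(results, top_k=3)
    assert [r["drug"] for r in rows] == ["natalizumab", "interferon beta-1a", "aaa"]
    assert rows[0]["ror"] == 1.23  # display rounding, 2 decimals
    assert rank_report(results, top_k=0) == []
    assert len(rank_report(results, top_k=1)) == 1
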