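"""The four disproportionality statistics, signal criteria and risk bands.

All four estimators compare a drug's share of target-event records with
the database background via the 2x2 table:

* ROR  = ad/(bc), with the log-normal Wald 95% CI
  ``exp(ln ROR ± 1.96·sqrt(1/a + 1/b + 1/c + 1/d))``.
* PRR  = [a/(a+b)] / [c/(c+d)], paired with the Pearson chi-square
  (no continuity correction).
* BCPNN information component IC = log2[ a·N / ((a+c)(a+b)) ] with a 95%
  credible interval of the form E(IC) ± 2·sqrt(V(IC)).
* EBGM = a·N / ((a+c)(a+b)) — the relative reporting ratio, i.e. the
  MGPS statistic without empirical-Bayes shrinkage — with a log-normal
  lower bound EBGM05.

Undefined statistics (zero cells without the Haldane correction) are
returned as NaN, never raised; NaN fails every signal criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

from .contingency import ContingencyTable

LN2 = math.log(2.0)

#: IC credible-interval variants: "calibrated" is the closed form
#: sqrt(V(IC)) = 1/(ln2·sqrt(a)); "bate" is the full posterior-variance
#: expansion of the original BCPNN with uniform priors.
IC_VARIANTS = ("calibrated", "bate")

RISK_BANDS = ("none", "low", "moderate", "high")


class RorResult(NamedTuple):
    ror: float
    ci_low: float
    ci_high: float


class PrrResult(NamedTuple):
    prr: float
    chi2: float


class IcResult(NamedTuple):
    ic: float
    ic025: float


class EbgmResult(NamedTuple):
    ebgm: float
    ebgm05: float


@dataclass(frozen=True)
class SignalCriteria:
    """Per-algorithm positivity rules; thresholds configurable, defaults standard."""

    ror_ci_low_gt: float = 1.0
    ror_min_reports: int = 3
    prr_ge: float = 2.0
    chi2_ge: float = 4.0
    prr_min_reports: int = 3
    ic025_gt: float = 0.0
    ebgm05_gt: float = 2.0

    def __post_init__(self) -> None:
        if min(self.ror_ci_low_gt, self.prr_ge, self.chi2_ge, self.ebgm05_gt) <= 0:
            raise ValueError("signal thresholds must be strictly positive")


@dataclass
class SignalResult:
    """All four estimators with interval bounds, flags and the BCPNN risk band."""

    drug: str
    n_reports: int  # the a cell
    ror: float
    ror_ci95: tuple[float, float]
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    flags: dict[str, bool] = field(default_factory=dict)
    risk_band: str = "none"


def _log_se(t) -> float:
    return math.sqrt(1.0 / t.a + 1.0 / t.b + 1.0 / t.c + 1.0 / t.d)


def _cells(t: ContingencyTable, haldane: bool):
    """Apply the zero-cell correction only when bc = 0 and it is enabled."""
    if haldane and (t.b == 0 or t.c == 0 or t.a == 0 or t.d == 0):
        return t.haldane()
    return t


def ror_stat(t: ContingencyTable, z: float = 1.96, haldane: bool = False) -> RorResult:
    """Reporting odds ratio with its two-sided log-normal Wald interval."""
    t = _cells(t, haldane)
    if t.a == 0 or t.b == 0 or t.c == 0 or t.d == 0:
        return RorResult(math.nan, math.nan, math.nan)
    ror = (t.a * t.d) / (t.b * t.c)
    half = z * _log_se(t)
    return RorResult(ror, ror * math.exp(-half), ror * math.exp(half))


def prr_stat(t: ContingencyTable, haldane: bool = False) -> PrrResult:
    """Proportional reporting ratio and the uncorrected Pearson chi-square."""
    t = _cells(t, haldane)
    if t.c == 0 or t.a + t.b == 0:
        return PrrResult(math.nan, math.nan)
    prr = (t.a * (t.c + t.d)) / (t.c * (t.a + t.b))
    n = t.n_total
    denom = (t.a + t.b) * (t.c + t.d) * (t.a + t.c) * (t.b + t.d)
    chi2 = math.nan if denom == 0 else (t.a * t.d - t.b * t.c) ** 2 * n / denom
    return PrrResult(prr, chi2)


def _bate_interval(t) -> IcResult:
    # Posterior mean/variance of the information component under the
    # original BCPNN priors (alpha1 = beta1 = 1, alpha = beta = 2,
    # gamma11 = 1, gamma tuned so E(IC) = 0 under independence).
    a, n = t.a, t.n_total
    a1 = b1 = 1.0
    al = be = 2.0
    g11 = 1.0
    row = t.drug_margin
    col = t.event_margin
    gamma = g11 * (n + al) * (n + be) / ((row + a1) * (col + b1))
    e_ic = math.log2((a + g11) * (n + al) * (n + be) / ((n + gamma) * (row + a1) * (col + b1)))
    v_ic = (
        (n - a + gamma - g11) / ((a + g11) * (1 + n + gamma))
        + (n - row + al - a1) / ((row + a1) * (1 + n + al))
        + (n - col + be - b1) / ((col + b1) * (1 + n + be))
    ) / (LN2**2)
    return IcResult(e_ic, e_ic - 2.0 * math.sqrt(v_ic))


def bcpnn_stat(t: ContingencyTable, variant: str = "calibrated", haldane: bool = False) -> IcResult:
    """Information component IC and the lower credible bound IC025.

    The default ``calibrated`` variant uses IC = log2[aN/((a+c)(a+b))] and
    sqrt(V(IC)) = 1/(ln2·sqrt(a)), i.e. the delta-method standard error of
    log2(a) under Poisson noise in the a cell; ``bate`` uses the full
    posterior-moment expansion.
    """
    if variant not in IC_VARIANTS:
        raise ValueError(f"unknown IC variant {variant!r}")
    if variant == "bate":
        return _bate_interval(t)
    t = _cells(t, haldane)
    if t.a == 0 or t.drug_margin == 0 or t.event_margin == 0:
        return IcResult(math.nan, math.nan)
    ic = math.log2(t.a * t.n_total / (t.event_margin * t.drug_margin))
    return IcResult(ic, ic - 2.0 / (LN2 * math.sqrt(t.a)))


def mgps_stat(t: ContingencyTable, z: float = 1.645, haldane: bool = False) -> EbgmResult:
    """Relative reporting ratio EBGM and its log-normal lower bound EBGM05.

    The default z = 1.645 (one-sided 5th percentile) is what published
    EBGM05 values are consistent with; z = 1.96 is available for a
    conventional two-sided bound.
    """
    t = _cells(t, haldane)
    if t.a == 0 or t.b == 0 or t.c == 0 or t.d == 0:
        return EbgmResult(math.nan, math.nan)
    ebgm = t.a * t.n_total / (t.event_margin * t.drug_margin)
    return EbgmResult(ebgm, math.exp(math.log(ebgm) - z * _log_se(t)))


def classify_risk(ic025: float) -> str:
    """BCPNN risk band from IC025: none (<=0), low (0,1.5], moderate (1.5,3], high (>3)."""
    if math.isnan(ic025) or ic025 <= 0.0:
        return "none"
    if ic025 <= 1.5:
        return "low"
    if ic025 <= 3.0:
        return "moderate"
    return "high"


def evaluate_signal(
    t: ContingencyTable,
    criteria: SignalCriteria | None = None,
    drug: str = "",
    *,
    ic_variant: str = "calibrated",
    ebgm05_z: float = 1.645,
    haldane: bool = False,
) -> SignalResult:
    """Compute all four statistics and the per-algorithm positivity flags.

    ``any`` is the OR of the four flags (the combined rule under which a
    drug counts as a signal); ``all_four`` the AND.  An undefined statistic
    (NaN) makes its flag False.
    """
    criteria = criteria or SignalCriteria()
    ror = ror_stat(t, haldane=haldane)
    prr = prr_stat(t, haldane=haldane)
    ic = bcpnn_stat(t, variant=ic_variant, haldane=haldane)
    ebgm = mgps_stat(t, z=ebgm05_z, haldane=haldane)

    def _gt(x: float, thr: float) -> bool:
        return (not math.isnan(x)) and x > thr

    def _ge(x: float, thr: float) -> bool:
        return (not math.isnan(x)) and x >= thr

    flags = {
        "ror_pos": _gt(ror.ci_low, criteria.ror_ci_low_gt) and t.a >= criteria.ror_min_reports,
        "prr_pos": _ge(prr.prr, criteria.prr_ge)
        and _ge(prr.chi2, criteria.chi2_ge)
        and t.a >= criteria.prr_min_reports,
        "bcpnn_pos": _gt(ic.ic025, criteria.ic025_gt),
        "mgps_pos": _gt(ebgm.ebgm05, criteria.ebgm05_gt),
    }
    flags["all_four"] = all(flags.values())
    flags["any"] = any(flags[k] for k in ("ror_pos", "prr_pos", "bcpnn_pos", "mgps_pos"))
    return SignalResult(
        drug=drug,
        n_reports=t.a,
        ror=ror.ror,
        ror_ci95=(ror.ci_low, ror.ci_high),
        prr=prr.prr,
        chi2=prr.chi2,
        ic=ic.ic,
        ic025=ic.ic025,
        ebgm=ebgm.ebgm,
        ebgm05=ebgm.ebgm05,
        flags=flags,
        risk_band=classify_risk(ic.ic025),
    )


def _round2(x: float) -> float:
    """Display rounding: 2 decimals, half away from zero."""
    if math.isnan(x):
        return math.nan
    return math.floor(abs(x) * 100 + 0.5) / 100 * (1 if x >= 0 else -1)


def rank_report(results: list[SignalResult], top_k: int) -> list[dict]:
    """Display rows sorted by report count (descending, ties alphabetical).

    Values are rounded to 2 decimals for display only; statistical
    comparisons should use the unrounded :class:`SignalResult` fields.
    """
    if top_k <= 0:
        return []
    ordered = sorted(results, key=lambda r: (-r.n_reports, r.drug))[:top_k]
    rows = []
    for r in ordered:
        rows.append(
            {
                "drug": r.drug,
                "n": r.n_reports,
                "ror": _round2(r.ror),
                "ror_low": _round2(r.ror_ci95[0]),
                "ror_high": _round2(r.ror_ci95[1]),
                "prr": _round2(r.prr),
                "chi2": _round2(r.chi2),
                "ebgm": _round2(r.ebgm),
                "ebgm05": _round2(r.ebgm05),
                "ic": _round2(r.ic),
                "ic025": _round2(r.ic025),
                **{k: r.flags.get(k, False) for k in ("ror_pos", "prr_pos", "bcpnn_pos", "mgps_pos", "all_four", "any")},
                "risk_band": r.risk_band,
            }
        )
    return rows
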