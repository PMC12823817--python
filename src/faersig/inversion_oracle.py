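"""Reconstruct a full 2x2 table from published summary values.

Published disproportionality tables print, per drug, the report count
``a`` and the point statistics — but not ``b`` and ``d``.  Because the
event margin ``a+c`` and the universe size ``N`` are fixed for every drug
in one study, the printed ROR determines the remaining cells: solve

    b = a·d / (ROR·c),   d = N − a − b − c,   c = (a+c) − a

by fixed-point iteration (converges in a handful of steps whenever
b << d, which holds throughout any large spontaneous-reporting database).
Every printed statistic then becomes a desk-scale regression check, with
no need for the underlying multi-gigabyte extract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .contingency import ContingencyTable
from .disproportionality import bcpnn_stat, mgps_stat, prr_stat, ror_stat

#: default comparison tolerances for :func:`verify_printed_row`:
#: relative for ratio-scale statistics, absolute (bits) for the IC pair.
DEFAULT_TOLERANCES = {
    "ror": 0.001,
    "ror_low": 0.001,
    "ror_high": 0.001,
    "prr": 0.01,
    "chi2": 0.01,
    "ebgm": 0.01,
    "ebgm05": 0.01,
    "ic": 0.02,
    "ic025": 0.02,
}
_ABSOLUTE_STATS = frozenset({"ic", "ic025"})


@dataclass
class InversionResult:
    table: ContingencyTable | None
    iterations: int
    residual: float  # |ROR(table) - target| / target
    converged: bool
    message: str = ""


def invert_ror(
    a: int,
    event_margin: int,
    n_total: int,
    ror_target: float,
    max_iter: int = 100,
    residual_tol: float = 0.005,
) -> InversionResult:
    """Recover the (a, b, c, d) table consistent with a printed point ROR.

    Preconditions: ``1 <= a < event_margin < n_total`` and
    ``ror_target > 0``.  ``b`` is rounded to the nearest integer; success
    requires the recomputed ROR to sit within ``residual_tol`` (default
    0.5%) of the target.
    """
    if not (1 <= a < event_margin < n_total) or ror_target <= 0:
        return InversionResult(None, 0, math.inf, False, "preconditions violated")
    c = event_margin - a
    d = float(n_total - a - c)
    # damped fixed-point iteration: the plain update has slope -b/d and
    # oscillates at the independence point (slope -1); averaging halves the
    # slope without slowing the b << d regime, where it converges in a
    # couple of steps.
    b = a * d / (ror_target * c)
    iterations = 0
    for iterations in range(1, max_iter + 1):
        d = n_total - a - c - b
        if d < 0:
            return InversionResult(None, iterations, math.inf, False, "negative cell")
        b_new = 0.5 * (b + a * d / (ror_target * c))
        delta = abs(b_new - b)
        b = b_new
        if delta < 0.5:
            break
    else:
        return InversionResult(None, iterations, math.inf, False, "no convergence")
    b_int = round(b)
    d_int = n_total - a - c - b_int
    if b_int < 0 or d_int < 0:
        return InversionResult(None, iterations, math.inf, False, "negative cell")
    table = ContingencyTable(a, b_int, c, d_int)
    recomputed = ror_stat(table).ror
    residual = abs(recomputed - ror_target) / ror_target
    if residual > residual_tol:
        return InversionResult(table, iterations, residual, False, "residual above tolerance")
    return InversionResult(table, iterations, residual, True)


def statistics_on_reconstruction(table: ContingencyTable, ebgm05_z: float = 1.645) -> dict[str, float]:
    """All nine reportable statistics of a (reconstructed) table, unrounded."""
    ror = ror_stat(table)
    prr = prr_stat(table)
    ic = bcpnn_stat(table)
    ebgm = mgps_stat(table, z=ebgm05_z)
    return {
        "ror": ror.ror,
        "ror_low": ror.ci_low,
        "ror_high": ror.ci_high,
        "prr": prr.prr,
        "chi2": prr.chi2,
        "ebgm": ebgm.ebgm,
        "ebgm05": ebgm.ebgm05,
        "ic": ic.ic,
        "ic025": ic.ic025,
    }


def verify_printed_row(
    a: int,
    printed: dict[str, float],
    tolerances: dict[str, float] | None = None,
    *,
    event_margin: int,
    n_total: int,
    ebgm05_z: float = 1.645,
) -> dict[str, dict]:
    """Check every printed statistic of one drug row against its reconstruction.

    ``printed`` must contain at least ``ror``; the other recognized keys
    are compared when present.  Returns per-statistic verdict dicts with
    the computed value, printed value, tolerance and pass flag.  An
    inversion failure fails every statistic with the reason attached.
    """
    if "ror" not in printed:
        raise ValueError("printed row must contain at least the point ROR")
    tol = dict(DEFAULT_TOLERANCES)
    if tolerances:
        tol.update(tolerances)
    inv = invert_ror(a, event_margin, n_total, printed["ror"])
    if not inv.converged or inv.table is None:
        return {
            stat: {"ok": False, "computed": math.nan, "printed": val, "reason": inv.message}
            for stat, val in printed.items()
        }
    computed = statistics_on_reconstruction(inv.table, ebgm05_z=ebgm05_z)
    verdicts = {}
    for stat, val in printed.items():
        if stat not in computed:
            continue
        got = computed[stat]
        if stat in _ABSOLUTE_STATS:
            err = abs(got - val)
        else:
            err = abs(got - val) / abs(val) if val != 0 else abs(got)
        verdicts[stat] = {
            "ok": err <= tol[stat],
            "computed": got,
            "printed": val,
            "error": err,
            "tolerance": tol[stat],
        }
    return verdicts
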