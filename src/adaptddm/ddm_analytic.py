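"""Closed-form predictions for the bounded-accumulation model and the fast
high-parameter fit to per-stimulus choice fractions and mean RTs.

For a unit-variance diffusion starting at 0 with drift ``mu``, upper
bound ``B - dB`` and lower bound ``-(B + dB)``:

    P(upper | mu) = [exp(2 mu B) - exp(-2 mu dB)]
                    / [exp(2 mu B) - exp(-2 mu B)]

    E[T] = [B (2 P - 1) - dB] / mu + T0

with the zero-drift limits P -> (B + dB) / (2 B) and
E[T] - T0 -> B^2 - dB^2.

The high-parameter fit optimizes one drift per stimulus plus the two
bound parameters and the nondecision mean, maximizing a binomial
log-likelihood of the choice fractions plus a Gaussian log-likelihood of
the observed mean RTs (standard error of the mean from the per-cell RT
variance). Drifts are profiled out cell by cell, so the outer search is
only three-dimensional.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .ddm_core import DDMParams, DriftMap
from .trial_data import TrialTable

__all__ = [
    "choice_prob_analytic",
    "mean_rt_analytic",
    "CellSummary",
    "DDMFit14",
    "summarize_cells",
    "fit_highparam_model",
]

_MU_EPS = 1e-12  # below this |mu| the zero-drift limits are used; expm1
# keeps the exact expressions cancellation-free down to this scale


def _check_bounds(b_bar: float, db: float) -> None:
    if not b_bar > 0 or not b_bar > abs(db):
        raise ValueError(f"invalid bounds: B={b_bar}, dB={db} "
                         "(need B > 0 and B > |dB|)")


def choice_prob_analytic(mu: float, b_bar: float, db: float = 0.0) -> float:
    """Probability of absorbing at the upper ("sad") bound."""
    _check_bounds(b_bar, db)
    if abs(mu) < _MU_EPS:
        return (b_bar + db) / (2.0 * b_bar)
    if mu > 0:
        # both expm1 arguments negative: overflow-safe
        return math.expm1(-2.0 * mu * (b_bar + db)) / math.expm1(-4.0 * mu * b_bar)
    # reflect: P_up(mu, dB) = 1 - P_up(-mu, -dB)
    return 1.0 - math.expm1(2.0 * mu * (b_bar - db)) / math.expm1(4.0 * mu * b_bar)


def mean_rt_analytic(mu: float, b_bar: float, db: float = 0.0,
                     t0: float = 0.0) -> float:
    """Mean response time (mean decision time when ``t0 = 0``)."""
    _check_bounds(b_bar, db)
    if t0 < 0:
        raise ValueError("t0 must be >= 0")
    if abs(mu) < _MU_EPS:
        return b_bar * b_bar - db * db + t0
    if abs(mu) < 0.1:
        # cancellation-safe form for small drift: with
        # S1 = e^{2muB} + e^{-2muB} - 2 e^{-2mu dB} (the ones cancel)
        # and S2 = 2 sinh(2muB), 2P - 1 = S1/S2 and
        # E[T] = (B S1 - dB S2) / (mu S2)
        s1 = (math.expm1(2 * mu * b_bar) + math.expm1(-2 * mu * b_bar)
              - 2.0 * math.expm1(-2 * mu * db))
        s2 = math.expm1(2 * mu * b_bar) - math.expm1(-2 * mu * b_bar)
        return (b_bar * s1 - db * s2) / (mu * s2) + t0
    p = choice_prob_analytic(mu, b_bar, db)
    return (b_bar * (2.0 * p - 1.0) - db) / mu + t0


@dataclass(frozen=True)
class CellSummary:
    """Per-(condition, stimulus) behavioral summary."""

    condition: str
    stimulus_strength: float
    n_trials: int
    n_sad: int
    mean_rt: float
    var_rt: float | None  # None for single-trial cells

    @property
    def p_sad(self) -> float:
        return self.n_sad / self.n_trials


@dataclass
class DDMFit14:
    """High-parameter fit: 11 per-stimulus drifts + B, dB, T0."""

    params: DDMParams
    loglik: float
    n_starts: int
    converged: bool
    start_logliks: list[float] = field(default_factory=list)
    se: dict[str, float] | None = None


def summarize_cells(table: TrialTable) -> list[CellSummary]:
    """One summary per (condition, stimulus strength); counts conserved."""
    if len(table) == 0:
        raise ValueError("cannot summarize an empty table")
    out = []
    grouped = table.df.groupby(["condition", "stimulus_strength"], observed=True)
    for (cond, s), grp in grouped:
        n = len(grp)
        rts = grp["rt"].to_numpy()
        out.append(CellSummary(
            condition=cond, stimulus_strength=float(s), n_trials=n,
            n_sad=int((grp["choice"] == "sad").sum()),
            mean_rt=float(rts.mean()),
            var_rt=float(rts.var(ddof=1)) if n > 1 else None,
        ))
    out.sort(key=lambda c: (c.condition, c.stimulus_strength))
    return out


def _cell_nll(mu: float, cell: CellSummary, b_bar: float, db: float,
              t0: float) -> float:
    p = choice_prob_analytic(mu, b_bar, db)
    p = min(max(p, 1e-12), 1 - 1e-12)
    nll = -(cell.n_sad * math.log(p) + (cell.n_trials - cell.n_sad) * math.log1p(-p))
    if cell.var_rt is not None and cell.var_rt > 0:
        se = math.sqrt(cell.var_rt / cell.n_trials)
        t_pred = mean_rt_analytic(mu, b_bar, db, t0)
        z = (cell.mean_rt - t_pred) / se
        nll += 0.5 * z * z + math.log(se) + 0.5 * math.log(2 * math.pi)
    return nll


_MU_MAX = 60.0


def _profile_drifts(cells: Sequence[CellSummary], b_bar: float, db: float,
                    t0: float) -> tuple[float, dict[float, float]]:
    """Optimal drift per cell for fixed (B, dB, T0); returns total NLL."""
    total = 0.0
    drifts = {}
    for cell in cells:
        res = minimize_scalar(_cell_nll, bounds=(-_MU_MAX, _MU_MAX),
                              args=(cell, b_bar, db, t0), method="bounded",
                              options={"xatol": 1e-7})
        drifts[cell.stimulus_strength] = float(res.x)
        total += float(res.fun)
    return total, drifts


def fit_highparam_model(cells: Sequence[CellSummary], n_starts: int = 20,
                        seed: int | None = None) -> DDMFit14:
    """Fit the per-stimulus-drift model to cell summaries of one condition.

    Outer Nelder-Mead over (log B, artanh(dB/B), log T0) with the drifts
    profiled out in closed loop; multi-start against local optima.
    """
    conds = {c.condition for c in cells}
    if len(conds) != 1:
        raise ValueError(f"cells must come from a single condition, got {sorted(conds)}")
    if len(cells) < 2:
        raise ValueError("need at least 2 stimulus cells")
    n_sad = sum(c.n_sad for c in cells)
    n_tot = sum(c.n_trials for c in cells)
    if n_sad == 0 or n_sad == n_tot:
        raise ValueError("both choices must be represented")

    rng = np.random.default_rng(seed)
    min_rt = min(c.mean_rt for c in cells)
    max_rt = max(c.mean_rt for c in cells)
    t0_init = max(0.06, 0.7 * min_rt)
    b_init = math.sqrt(max(max_rt - t0_init, 0.01))

    def unpack(x):
        b = math.exp(x[0])
        db = b * math.tanh(x[1])
        t0 = math.exp(x[2])
        return b, db, t0

    def objective(x):
        b, db, t0 = unpack(x)
        if t0 > 5.0:
            return 1e9
        nll, _ = _profile_drifts(cells, b, db, t0)
        return nll

    x0_base = np.array([math.log(b_init), 0.0, math.log(t0_init)])
    best = None
    start_lls = []
    for k in range(max(1, n_starts)):
        x0 = x0_base if k == 0 else x0_base + rng.normal(0, [0.4, 0.3, 0.3])
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 800})
        start_lls.append(-float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    b, db, t0 = unpack(best.x)
    nll, drifts = _profile_drifts(cells, b, db, t0)
    params = DDMParams(bound_mean=b, bound_offset=db, nd_mean=t0,
                       drift=DriftMap.from_table(drifts))
    return DDMFit14(params=params, loglik=-nll, n_starts=max(1, n_starts),
                    converged=bool(best.success), start_logliks=start_lls)
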