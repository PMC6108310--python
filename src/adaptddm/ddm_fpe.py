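"""First-passage densities by Crank-Nicolson solution of the forward
Fokker-Planck equation with two absorbing bounds, RT densities by
convolution with the nondecision distribution, and full joint
choice/RT maximum likelihood for the reduced (7-parameter) model.

The evolution equation for the accumulator density p(v, t) is

    dp/dt = -mu dp/dv + 0.5 d^2p/dv^2

with p(v, 0) a delta at 0 and p = 0 at both bounds. The scheme is
implicit Crank-Nicolson on a uniform evidence grid spanning the two
bounds; the delta start is split linearly between the two nodes
flanking 0 (exact for the zero-drift absorption probability). Absorbed
mass per step is the discrete mass loss, apportioned between the two
bounds by the ratio of second-order one-sided probability currents, so
up + low + survivor = 1 holds to machine precision.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

from .ddm_core import DDMParams, DriftMap, drift_at
from .ddm_analytic import fit_highparam_model, summarize_cells
from .trial_data import TrialTable

__all__ = [
    "FPEGrid",
    "FirstPassagePDF",
    "RTDensity",
    "DDMFit7",
    "solve_fpe",
    "rt_density",
    "loglik_trials",
    "fit_reduced_model",
    "bootstrap_fit_se",
]

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dep of the env
    _HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@dataclass(frozen=True)
class FPEGrid:
    """Discretization settings for the forward solver.

    ``dv`` is a target spacing; the actual spacing divides the bound
    span exactly. ``dv=None`` means span/200.
    """

    dv: float | None = None
    dt: float = 1e-3
    t_max: float = 6.0
    survivor_tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.dv is not None and not self.dv > 0:
            raise ValueError("dv must be > 0")
        if not self.dt > 0 or not self.t_max > self.dt:
            raise ValueError("need dt > 0 and t_max > dt")



@dataclass
class FirstPassagePDF:
    """Absorption mass per time step at each bound plus survivor trace.

    ``t`` holds interval midpoints; ``up``/``low`` are probability
    *masses* absorbed during each step (divide by ``dt`` for a
    density). ``survivor`` is the interior mass remaining after each
    step.
    """

    t: np.ndarray
    up: np.ndarray
    low: np.ndarray
    survivor: np.ndarray
    dt: float
    truncated: bool = False

    @property
    def p_up(self) -> float:
        return float(self.up.sum())

    @property
    def p_low(self) -> float:
        return float(self.low.sum())

    def mean_decision_time(self) -> float:
        tot = self.up + self.low
        return float((self.t * tot).sum() / tot.sum())


@dataclass
class RTDensity:
    """Per-choice RT mass on an extended time grid (masses per step)."""

    t: np.ndarray
    up: np.ndarray
    low: np.ndarray
    dt: float


@njit(cache=True)
def _cn_march(q, A_l, A_d, A_u, B_l, B_d, B_u, dv, nt, stop_mass):
    """Crank-Nicolson time march with Thomas solves; constant tridiagonals.

    Returns (up, low, survivor) arrays of length nt (trailing zeros after
    early termination) and the number of steps actually taken.
    """
    m = q.shape[0]
    cp = np.empty(m)
    denom = np.empty(m)
    denom[0] = A_d
    cp[0] = A_u / A_d
    for i in range(1, m):
        denom[i] = A_d - A_l * cp[i - 1]
        cp[i] = A_u / denom[i]
    up = np.zeros(nt)
    low = np.zeros(nt)
    surv = np.zeros(nt)
    d = np.empty(m)
    mass = 0.0
    for i in range(m):
        mass += q[i]
    ns = nt
    for s in range(nt):
        q0_0 = q[0]
        q0_1 = q[1]
        q0_m1 = q[m - 1]
        q0_m2 = q[m - 2]
        prev = q[0]
        d[0] = (B_d * q[0] + B_u * q[1]) / denom[0]
        for i in range(1, m - 1):
            rhs = B_l * prev + B_d * q[i] + B_u * q[i + 1]
            prev = q[i]
            d[i] = (rhs - A_l * d[i - 1]) / denom[i]
        rhs = B_l * prev + B_d * q[m - 1]
        d[m - 1] = (rhs - A_l * d[m - 2]) / denom[m - 1]
        q[m - 1] = d[m - 1]
        for i in range(m - 2, -1, -1):
            q[i] = d[i] - cp[i] * q[i + 1]
        newmass = 0.0
        for i in range(m):
            newmass += q[i]
        loss = mass - newmass
        if loss < 0.0:
            loss = 0.0
        mass = newmass
        # midpoint (CN-consistent) one-sided second-order currents
        p1 = 0.5 * (q0_0 + q[0])
        p2 = 0.5 * (q0_1 + q[1])
        pm1 = 0.5 * (q0_m1 + q[m - 1])
        pm2 = 0.5 * (q0_m2 + q[m - 2])
        f_low = (4.0 * p1 - p2) / (4.0 * dv)
        f_up = (4.0 * pm1 - pm2) / (4.0 * dv)
        if f_low < 0.0:
            f_low = 0.0
        if f_up < 0.0:
            f_up = 0.0
        tot = f_low + f_up
        share = 0.5 if tot <= 0.0 else f_up / tot
        up[s] = loss * share
        low[s] = loss * (1.0 - share)
        surv[s] = mass
        if mass < stop_mass and s > 10:
            ns = s + 1
            break
    return up, low, surv, ns


def solve_fpe(mu: float, b_bar: float, db: float, grid: FPEGrid | None = None,
              ) -> FirstPassagePDF:
    """Solve for the first-passage densities at both bounds.

    Flags the result as ``truncated`` when the survivor mass at
    ``t_max`` exceeds ``grid.survivor_tol``.
    """
    if not b_bar > 0 or not b_bar > abs(db):
        raise ValueError(f"invalid bounds: B={b_bar}, dB={db}")
    grid = grid or FPEGrid()
    lo = -(b_bar + db)
    hi = b_bar - db
    span = hi - lo
    dv_target = grid.dv if grid.dv is not None else span / 200.0
    n = max(8, int(round(span / dv_target)))
    dv = span / n
    # CFL-type sanity for the advection discretization (cell Peclet number)
    if abs(mu) * dv > 2.0:
        raise ValueError("advection too strong for grid: refine dv "
                         f"(|mu| dv = {abs(mu) * dv:.3f} > 2)")
    q = np.zeros(n - 1)
    i0 = int(np.floor((0.0 - lo) / dv))
    i0 = min(max(i0, 1), n - 1)
    w = ((lo + (i0 + 1) * dv) - 0.0) / dv  # mass share of the left node
    q[i0 - 1] = w
    if i0 < n - 1:
        q[i0] = 1.0 - w
    a_adv = mu / (2.0 * dv)
    a_dif = 0.5 / (dv * dv)
    l_lo = grid.dt / 2.0 * (a_adv + a_dif)
    l_di = grid.dt / 2.0 * (-2.0 * a_dif)
    l_hi = grid.dt / 2.0 * (-a_adv + a_dif)
    nt = int(round(grid.t_max / grid.dt))
    up, low, surv, ns = _cn_march(q, -l_lo, 1.0 - l_di, -l_hi,
                                  l_lo, 1.0 + l_di, l_hi,
                                  dv, nt, min(1e-12, grid.survivor_tol * 1e-4))
    up, low, surv = up[:ns], low[:ns], surv[:ns]
    t = (np.arange(ns) + 0.5) * grid.dt
    return FirstPassagePDF(t=t, up=up, low=low, survivor=surv, dt=grid.dt,
                           truncated=bool(surv[-1] > grid.survivor_tol))


def rt_density(fp: FirstPassagePDF, nd_mean: float, nd_sd: float) -> RTDensity:
    """Convolve first-passage masses with the nondecision distribution.

    The Gaussian kernel is discretized on the solver's time step,
    truncated at zero and renormalized. Per-choice mass is conserved.
    """
    if not nd_mean > 0:
        raise ValueError("nd_mean must be > 0")
    dt = fp.dt
    if nd_sd < dt / 2:
        # delta-kernel limit: pure shift by the nearest whole step
        shift = int(round(nd_mean / dt))
        kernel = np.zeros(shift + 1)
        kernel[shift] = 1.0
    else:
        trunc_mass = norm.cdf(0.0, loc=nd_mean, scale=nd_sd)
        if trunc_mass > 0.05:
            warnings.warn(
                f"{trunc_mass:.1%} of the nondecision distribution lies below 0 "
                "and is truncated", stacklevel=2)
        j_hi = int(math.ceil((nd_mean + 6 * nd_sd) / dt))
        tj = np.arange(j_hi + 1) * dt
        kernel = norm.pdf(tj, loc=nd_mean, scale=nd_sd)
        kernel[tj <= 0] = 0.0
        ksum = kernel.sum()
        if ksum <= 0:
            raise ValueError("nondecision kernel vanished after truncation")
        kernel = kernel / ksum
    up = np.convolve(fp.up, kernel)
    low = np.convolve(fp.low, kernel)
    t = fp.t[0] + np.arange(up.size) * dt
    return RTDensity(t=t, up=up, low=low, dt=dt)


def _condition_densities(params: DDMParams, strengths: Sequence[float],
                         grid: FPEGrid) -> dict[float, RTDensity]:
    out = {}
    for s in strengths:
        mu = drift_at(params.drift, s)
        fp = solve_fpe(mu, params.bound_mean, params.bound_offset, grid)
        out[float(s)] = rt_density(fp, params.nd_mean, params.nd_sd)
    return out


_DENSITY_FLOOR = 1e-10


def loglik_trials(params: DDMParams, table: TrialTable,
                  grid: FPEGrid | None = None,
                  warn_truncation: bool = True) -> float:
    """Joint log-likelihood of (choice, rt) across trials of one condition.

    The per-choice RT density is linearly interpolated on the time grid
    and floored at 1e-10; trials beyond the solve horizon contribute the
    floor and are counted (a warning fires above 1% of trials).
    """
    if len(table) == 0:
        return 0.0
    grid = grid or FPEGrid()
    df = table.df
    dens = _condition_densities(params, np.unique(df["stimulus_strength"]), grid)
    total = 0.0
    n_trunc = 0
    for s, grp in df.groupby("stimulus_strength", observed=True):
        d = dens[float(s)]
        rts = grp["rt"].to_numpy()
        sad = (grp["choice"] == "sad").to_numpy()
        d_up = np.interp(rts, d.t, d.up / d.dt, left=0.0, right=0.0)
        d_lo = np.interp(rts, d.t, d.low / d.dt, left=0.0, right=0.0)
        vals = np.where(sad, d_up, d_lo)
        n_trunc += int((rts > d.t[-1]).sum())
        total += float(np.log(np.maximum(vals, _DENSITY_FLOOR)).sum())
    if warn_truncation and n_trunc > 0.01 * len(df):
        warnings.warn(f"{n_trunc} of {len(df)} trials exceed the solve horizon",
                      stacklevel=2)
    return total


@dataclass
class DDMFit7:
    """Reduced-model fit: linear drift map + extremes, bounds, nondecision."""

    params: DDMParams
    loglik: float
    n_starts: int
    converged: bool
    start_logliks: list[float] = field(default_factory=list)
    boundary_flag: bool = False
    se: dict[str, float] | None = None
    n_boot_failed: int = 0


_T0_LO, _T0_HI = 0.05, 1.0


def _pack(k, s0, mu_lo, mu_hi, b, db, t0):
    z = np.clip((t0 - _T0_LO) / (_T0_HI - _T0_LO), 1e-4, 1 - 1e-4)
    return np.array([k, s0, mu_lo, mu_hi, math.log(b),
                     math.atanh(np.clip(db / b, -0.999, 0.999)),
                     math.log(z / (1 - z))])


def _unpack(x):
    k, s0, mu_lo, mu_hi = x[0], x[1], x[2], x[3]
    b = math.exp(x[4])
    db = b * math.tanh(x[5])
    t0 = _T0_LO + (_T0_HI - _T0_LO) / (1.0 + math.exp(-x[6]))
    return k, s0, mu_lo, mu_hi, b, db, t0


def _reduced_params(x, ex_lo: float, ex_hi: float,
                    nd_sd_ratio: float = 1.0 / 3.0) -> DDMParams:
    k, s0, mu_lo, mu_hi, b, db, t0 = _unpack(x)
    dmap = DriftMap.reduced(slope=k, center=s0, mu_low=mu_lo, mu_high=mu_hi,
                            extreme_low=ex_lo, extreme_high=ex_hi)
    return DDMParams(bound_mean=b, bound_offset=db, nd_mean=t0,
                     nd_sd=t0 * nd_sd_ratio, drift=dmap)


def _analytic_init(table: TrialTable, ex_lo: float, ex_hi: float) -> np.ndarray:
    """Seed the reduced fit from the fast closed-form fit."""
    cells = summarize_cells(table)
    fit = fit_highparam_model(cells, n_starts=5, seed=0)
    p = fit.params
    drifts = p.drift.table
    mids = sorted(s for s in drifts if ex_lo < s < ex_hi)
    mus = np.array([drifts[s] for s in mids])
    ss = np.array(mids)
    if len(mids) >= 2:
        k, c = np.polyfit(ss, mus, 1)
        k = max(k, 0.5)
        s0 = -c / k
    else:
        k, s0 = 8.0, 0.5
    t0 = float(np.clip(p.nd_mean, _T0_LO + 0.01, _T0_HI - 0.01))
    return _pack(k, float(np.clip(s0, -0.5, 1.5)),
                 drifts.get(round(ex_lo, 9), k * (ex_lo - s0)),
                 drifts.get(round(ex_hi, 9), k * (ex_hi - s0)),
                 p.bound_mean, p.bound_offset * 0.999, t0)


def fit_reduced_model(table: TrialTable, grid: FPEGrid | None = None,
                      n_starts: int = 10, seed: int | None = None,
                      init: DDMParams | None = None,
                      maxiter: int = 1200) -> DDMFit7:
    """Maximum-likelihood fit of the 7-parameter model to one condition.

    Free parameters: drift-map slope and zero-crossing, the two extreme
    drifts, bound mean and offset, and the nondecision mean (SD locked
    to mean/3). Starts at a closed-form-fit seed (or ``init``) plus
    random perturbations.
    """
    conds = set(table.conditions)
    if len(conds) != 1:
        raise ValueError(f"table must hold a single condition, got {sorted(conds)}")
    strengths = np.unique(table.df["stimulus_strength"])
    if strengths.size < 5:
        raise ValueError("need at least 5 distinct stimulus levels "
                         f"(got {strengths.size})")
    ex_lo, ex_hi = float(strengths[0]), float(strengths[-1])
    grid = grid or FPEGrid()
    rng = np.random.default_rng(seed)

    if init is not None:
        d = init.drift
        x0 = _pack(d.slope, d.center, d.mu_low, d.mu_high,
                   init.bound_mean, init.bound_offset, init.nd_mean)
    else:
        x0 = _analytic_init(table, ex_lo, ex_hi)

    def objective(x):
        try:
            params = _reduced_params(x, ex_lo, ex_hi)
            mus = [drift_at(params.drift, s) for s in strengths]
            if max(abs(m) for m in mus) > 50.0:  # saturated, unidentifiable
                return 1e12
            return -loglik_trials(params, table, grid, warn_truncation=False)
        except (ValueError, OverflowError):
            return 1e12

    scale = np.array([0.15, 0.03, 0.2, 0.2, 0.08, 0.15, 0.3])
    # absolute simplex steps: NM's default relative steps stall on
    # coordinates that start at (or near) zero, e.g. the bound offset
    steps = np.array([0.4, 0.02, 0.25, 0.25, 0.06, 0.12, 0.25])
    best = None
    start_lls: list[float] = []
    for kstart in range(max(1, n_starts)):
        xs = x0 if kstart == 0 else x0 + rng.normal(0, 1, 7) * scale
        simplex = np.vstack([xs, xs + np.diag(steps)])
        res = minimize(objective, xs, method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-3,
                                "maxiter": maxiter, "maxfev": maxiter,
                                "initial_simplex": simplex})
        start_lls.append(-float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("all starts failed for the reduced-model fit")
    params = _reduced_params(best.x, ex_lo, ex_hi)
    boundary = (params.nd_mean < _T0_LO + 1e-3 or params.nd_mean > _T0_HI - 1e-3
                or abs(params.bound_offset) > 0.99 * params.bound_mean)
    return DDMFit7(params=params, loglik=-float(best.fun),
                   n_starts=max(1, n_starts), converged=bool(best.success),
                   start_logliks=start_lls, boundary_flag=boundary)


def bootstrap_fit_se(table: TrialTable, grid: FPEGrid | None = None,
                     n_boot: int = 40, seed: int | None = None,
                     base_fit: DDMFit7 | None = None,
                     fit_fn: Callable[[TrialTable], dict[str, float]] | None = None,
                     maxiter: int = 400) -> dict[str, float]:
    """Parameter SEs as the SD of refits to bootstrap-resampled trials.

    By default each resample is refit with a single start at the base
    fit's parameters. A custom ``fit_fn(table) -> {name: value}``
    substitutes any other estimator (e.g. the closed-form fit) while
    keeping the same resampling scheme. Failed resamples are dropped;
    more than 25% failures raises.
    """
    if not 1 <= n_boot:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    if fit_fn is None:
        if base_fit is None:
            base_fit = fit_reduced_model(table, grid, n_starts=3, seed=seed)

        def fit_fn(tbl: TrialTable) -> dict[str, float]:
            f = fit_reduced_model(tbl, grid, n_starts=1, init=base_fit.params,
                                  maxiter=maxiter)
            p = f.params
            d = p.drift
            return {"slope": d.slope, "center": d.center, "mu_low": d.mu_low,
                    "mu_high": d.mu_high, "bound_mean": p.bound_mean,
                    "bound_offset": p.bound_offset, "nd_mean": p.nd_mean}

    n = len(table)
    draws: list[dict[str, float]] = []
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        resampled = TrialTable(table.df.iloc[idx].reset_index(drop=True),
                               table.experiment_id)
        try:
            draws.append(fit_fn(resampled))
        except Exception:  # noqa: BLE001 - failures are counted, not fatal
            n_failed += 1
    if n_failed > 0.25 * n_boot:
        raise RuntimeError(f"{n_failed}/{n_boot} bootstrap refits failed")
    keys = draws[0].keys()
    ses = {k: float(np.std([d[k] for d in draws], ddof=1)) for k in keys}
    ses["_n_failed"] = n_failed
    return ses
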