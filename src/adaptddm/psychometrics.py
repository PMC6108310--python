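"""Logistic psychometric models, PSE shifts, and bootstrap inference.

Two models are fit by maximum likelihood:

* simple:     logit P(sad) = b0 (S + b1)          (PSE = -b1)
* condition:  logit P(sad) = (b0 + b4 L3)(S + b1 + b2 L1 + b3 L2)

with L1/L2 indicators for the happy-/sad-adapted conditions and
L3 = L1 + L2. Both use the multiplicative slope-times-bias form; the
optimum is found in the equivalent linear-predictor space (where the
log-likelihood is concave, so Newton iterations converge globally) and
converted back, with delta-method standard errors for the converted
coefficients. Bootstrap SEs resample trials within condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .trial_data import CONDITIONS, TrialTable

__all__ = [
    "SimpleLogisticFit",
    "ConditionLogisticFit",
    "PSEShift",
    "BootstrapAggregate",
    "fit_simple_logistic",
    "fit_condition_logistic",
    "pse_shift",
    "aggregate_across_subjects",
    "logit_evidence_profile",
]

_SLOPE_RELIABLE = 1e-3  # |b0| below this -> PSE flagged unreliable


class SeparationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# concave core: binomial logistic regression by Newton / IRLS

def _fit_binomial_logit(X: np.ndarray, n: np.ndarray, k: np.ndarray,
                        max_iter: int = 100, tol: float = 1e-10,
                        ) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Newton ML for aggregated binomial logistic data.

    Returns (coef, covariance, loglik, separated). Separation is
    diagnosed when coefficients diverge without the gradient vanishing.
    """
    p_emp = (k + 0.5) / (n + 1.0)
    # crude init: least squares on empirical logits
    beta = np.linalg.lstsq(X, np.log(p_emp / (1 - p_emp)), rcond=None)[0]
    separated = False
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        g = X.T @ (k - n * p)
        w = n * p * (1 - p)
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            separated = True
            break
        # dampen huge steps (separation path)
        norm = np.abs(step).max()
        if norm > 10.0:
            step = step * (10.0 / norm)
        beta = beta + step
        if np.abs(g).max() < tol * max(1.0, n.sum()) and np.abs(step).max() < 1e-8:
            break
        if np.abs(beta).max() > 500.0:
            separated = True
            break
    eta = X @ beta
    p = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-300, 1 - 1e-16)
    ll = float((k * np.log(p) + (n - k) * np.log1p(-p)).sum())
    w = n * p * (1 - p)
    H = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((X.shape[1], X.shape[1]), np.nan)
    return beta, cov, ll, separated


def _aggregate(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    g = df.groupby("stimulus_strength", observed=True)["choice"]
    n = g.size().to_numpy(float)
    k = g.apply(lambda c: float((c == "sad").sum())).to_numpy()
    s = np.array(sorted(df["stimulus_strength"].unique()), dtype=float)
    return s, n, k


@dataclass
class SimpleLogisticFit:
    beta0: float  # slope (logit units per strength unit)
    beta1: float  # bias (strength units); PSE = -beta1
    loglik: float
    se_beta0: float | None = None
    se_beta1: float | None = None
    se_pse: float | None = None
    separated: bool = False
    slope_unreliable: bool = False
    n_trials: int = 0

    @property
    def pse(self) -> float:
        return -self.beta1


def _simple_from_counts(s: np.ndarray, n: np.ndarray, k: np.ndarray,
                        ) -> SimpleLogisticFit:
    X = np.column_stack([s, np.ones_like(s)])
    coef, cov, ll, separated = _fit_binomial_logit(X, n, k)
    b0, a = float(coef[0]), float(coef[1])
    if separated:
        return SimpleLogisticFit(beta0=np.inf if b0 >= 0 else -np.inf,
                                 beta1=-float(np.average(s, weights=n)),
                                 loglik=ll, separated=True,
                                 n_trials=int(n.sum()))
    unreliable = abs(b0) < _SLOPE_RELIABLE
    if unreliable:
        # PSE indeterminate at zero slope; report the trial-weighted
        # strength midpoint and flag it
        b1 = -float(np.average(s, weights=n))
    else:
        b1 = a / b0
    return SimpleLogisticFit(beta0=b0, beta1=b1, loglik=ll,
                             slope_unreliable=unreliable, n_trials=int(n.sum()))


def _resample_counts(n: np.ndarray, k: np.ndarray, rng: np.random.Generator,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Trial-level bootstrap via the equivalent multinomial on cell counts."""
    cells = np.concatenate([k, n - k])  # (strength x choice) cell counts
    tot = int(cells.sum())
    draw = rng.multinomial(tot, cells / tot)
    m = len(n)
    k_new = draw[:m].astype(float)
    n_new = k_new + draw[m:]
    return n_new, k_new


def fit_simple_logistic(table: TrialTable, condition: str | None = None,
                        n_boot: int = 0, seed: int | None = None,
                        ) -> SimpleLogisticFit:
    """ML fit of the simple psychometric model, optionally with bootstrap SEs.

    Requires at least two distinct strengths and both responses
    represented overall. Perfect separation is flagged (infinite-slope
    marker) rather than raised.
    """
    df = table.df if condition is None else table.df[table.df["condition"] == condition]
    if df.empty:
        raise ValueError("no trials to fit")
    s, n, k = _aggregate(df)
    if len(s) < 2:
        raise ValueError("need >= 2 distinct stimulus strengths")
    if k.sum() == 0 or k.sum() == n.sum():
        raise ValueError("both responses must be represented")
    fit = _simple_from_counts(s, n, k)
    if n_boot > 0 and not fit.separated:
        rng = np.random.default_rng(seed)
        draws = []
        for _ in range(n_boot):
            n_b, k_b = _resample_counts(n, k, rng)
            keep = n_b > 0
            try:
                f = _simple_from_counts(s[keep], n_b[keep], k_b[keep])
            except (ValueError, np.linalg.LinAlgError):
                continue
            if not f.separated and not f.slope_unreliable:
                draws.append((f.beta0, f.beta1, f.pse))
        if len(draws) >= 10:
            arr = np.array(draws)
            fit.se_beta0, fit.se_beta1, fit.se_pse = np.std(arr, axis=0, ddof=1)
    return fit


@dataclass
class ConditionLogisticFit:
    """Joint three-condition fit; beta2/beta3 are adapted-PSE changes
    (sign: positive shifts the curve leftward, i.e. PSE_adapted =
    -beta1 - beta{2,3}), beta4 the adapted slope change."""

    beta: np.ndarray  # (b0, b1, b2, b3, b4)
    se: np.ndarray
    loglik: float
    separated: bool = False

    @property
    def beta0(self) -> float:
        return float(self.beta[0])

    @property
    def beta4(self) -> float:
        return float(self.beta[4])

    def pse(self, condition: str) -> float:
        b = self.beta
        if condition == "unadapted":
            return -float(b[1])
        if condition == "happy_adapted":
            return -float(b[1] + b[2])
        if condition == "sad_adapted":
            return -float(b[1] + b[3])
        raise ValueError(f"unknown condition {condition!r}")


def fit_condition_logistic(table: TrialTable) -> ConditionLogisticFit:
    """Joint ML fit across all three adaptation conditions.

    Fit in the concave linear-predictor space
    eta = c0 S + c1 (S L3) + c2 + c3 L1 + c4 L2 and converted to the
    multiplicative coefficients with delta-method SEs.
    """
    df = table.df
    present = set(df["condition"].unique())
    if present != set(CONDITIONS):
        raise ValueError(f"all three conditions required, got {sorted(present)}")
    rows = []
    for cond, sub in df.groupby("condition", observed=True):
        s, n, k = _aggregate(sub)
        l1 = 1.0 if cond == "happy_adapted" else 0.0
        l2 = 1.0 if cond == "sad_adapted" else 0.0
        for si, ni, ki in zip(s, n, k):
            rows.append((si, ni, ki, l1, l2))
    arr = np.array(rows)
    s, n, k, l1, l2 = arr.T
    l3 = l1 + l2
    X = np.column_stack([s, s * l3, np.ones_like(s), l1, l2])
    coef, cov, ll, separated = _fit_binomial_logit(X, n, k)
    c0, c1, c2, c3, c4 = coef
    b0 = c0
    b4 = c1
    b1 = c2 / c0
    b2 = (c2 + c3) / (c0 + c1) - b1
    b3 = (c2 + c4) / (c0 + c1) - b1
    beta = np.array([b0, b1, b2, b3, b4])
    # delta method: J[i, j] = d beta_i / d c_j
    sa = c0 + c1
    J = np.array([
        [1, 0, 0, 0, 0],
        [-c2 / c0**2, 0, 1 / c0, 0, 0],
        [-(c2 + c3) / sa**2 + c2 / c0**2, -(c2 + c3) / sa**2, 1 / sa - 1 / c0,
         1 / sa, 0],
        [-(c2 + c4) / sa**2 + c2 / c0**2, -(c2 + c4) / sa**2, 1 / sa - 1 / c0,
         0, 1 / sa],
        [0, 1, 0, 0, 0],
    ])
    se = np.sqrt(np.maximum(np.diag(J @ cov @ J.T), 0.0))
    return ConditionLogisticFit(beta=beta, se=se, loglik=ll, separated=separated)


@dataclass
class PSEShift:
    shift: float
    se: float | None
    fit_adapted: SimpleLogisticFit
    fit_unadapted: SimpleLogisticFit
    n_boot: int = 0
    n_failed: int = 0


def pse_shift(adapted: TrialTable, unadapted: TrialTable,
              n_boot: int = 1000, seed: int | None = None) -> PSEShift:
    """PSE(adapted) - PSE(unadapted) with a trial-level bootstrap SE.

    Resampling happens independently within each condition's table;
    failed resample fits are dropped and counted.
    """
    fit_a = fit_simple_logistic(adapted)
    fit_u = fit_simple_logistic(unadapted)
    shift = fit_a.pse - fit_u.pse
    se = None
    n_failed = 0
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        sa, na, ka = _aggregate(adapted.df)
        su, nu, ku = _aggregate(unadapted.df)
        draws = []
        for _ in range(n_boot):
            try:
                n_b, k_b = _resample_counts(na, ka, rng)
                keep = n_b > 0
                fa = _simple_from_counts(sa[keep], n_b[keep], k_b[keep])
                n_b, k_b = _resample_counts(nu, ku, rng)
                keep = n_b > 0
                fu = _simple_from_counts(su[keep], n_b[keep], k_b[keep])
            except (ValueError, np.linalg.LinAlgError):
                n_failed += 1
                continue
            if fa.separated or fu.separated or fa.slope_unreliable or fu.slope_unreliable:
                n_failed += 1
                continue
            draws.append(fa.pse - fu.pse)
        if len(draws) >= 10:
            se = float(np.std(draws, ddof=1))
    return PSEShift(shift=shift, se=se, fit_adapted=fit_a, fit_unadapted=fit_u,
                    n_boot=n_boot, n_failed=n_failed)


@dataclass
class BootstrapAggregate:
    distribution: np.ndarray  # across-subject averages, one per iteration
    p_value: float
    alternative: str  # direction of the claimed effect: "less" | "greater"


def aggregate_across_subjects(per_subject: Sequence, n_iter: int = 10_000,
                              seed: int | None = None,
                              alternative: str = "less") -> BootstrapAggregate:
    """Across-subject bootstrap aggregation of a per-subject statistic.

    Each element of ``per_subject`` is either an array of bootstrap
    draws of that subject's statistic (sampled with replacement per
    iteration) or a callable ``f(rng) -> float`` that recomputes the
    statistic on resampled data. Per iteration one value per subject is
    drawn and averaged; the p-value is the fraction of iteration
    averages on the null side of zero (ties at zero count one half).

    ``alternative="less"`` claims the statistic is below zero, so the
    p-value is the proportion of averages that exceed zero.
    """
    if len(per_subject) < 2:
        raise ValueError("need >= 2 subjects")
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    if n_iter < 100:
        warnings.warn("n_iter < 100 gives unstable p-values", stacklevel=2)
    rng = np.random.default_rng(seed)
    cols = []
    for item in per_subject:
        if callable(item):
            cols.append(np.array([float(item(rng)) for _ in range(n_iter)]))
        else:
            arr = np.asarray(item, dtype=float)
            cols.append(arr[rng.integers(0, len(arr), n_iter)])
    avg = np.mean(cols, axis=0)
    gt = float((avg > 0).mean())
    lt = float((avg < 0).mean())
    ties = 1.0 - gt - lt
    p = (gt if alternative == "less" else lt) + 0.5 * ties
    return BootstrapAggregate(distribution=avg, p_value=p, alternative=alternative)


def logit_evidence_profile(table: TrialTable) -> pd.DataFrame:
    """Empirical per-stimulus P(sad) and its logit.

    P is clipped to [1/(2n), 1 - 1/(2n)] before the logit (n = trials at
    that stimulus); clipped cells are flagged in the ``clipped`` column.
    """
    s, n, k = _aggregate(table.df)
    p = k / n
    lo = 1.0 / (2.0 * n)
    clipped = (p < lo) | (p > 1 - lo)
    p_c = np.clip(p, lo, 1 - lo)
    return pd.DataFrame({
        "stimulus_strength": s, "n_trials": n.astype(int), "p_sad": p,
        "logit": np.log(p_c / (1 - p_c)), "clipped": clipped,
    })
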