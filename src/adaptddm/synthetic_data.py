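"""Synthetic trial generation from the bounded-accumulation model.

Trials are drawn with an Euler-Maruyama walk on the evidence process
(variance 1 per second) plus a Brownian-bridge crossing test within
each step, which removes the leading-order discretization bias of naive
threshold checks. Observed RT = first-passage time + a Gaussian
nondecision draw (SD = mean/3 by default; draws <= 0 are resampled).

Multi-subject experiment builders emulate two designs: a fixed shared
stimulus set, and a "balanced" design where each subject's middle
stimuli are recentred on the model-implied PSE of that subject and
condition so that both responses occur about equally often.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .ddm_analytic import choice_prob_analytic
from .ddm_core import DDMParams, DriftMap, drift_at
from .trial_data import CONDITIONS, EXP1_STIMULUS_SET, StimulusSet, TrialTable

__all__ = [
    "SubjectSpec",
    "ExperimentDesign",
    "AdaptationEffects",
    "simulate_trials",
    "make_experiment",
    "balanced_stimulus_selection",
    "default_unadapted_params",
    "adapted_params",
    "make_subject_specs",
]


@dataclass(frozen=True)
class SubjectSpec:
    """Ground-truth generating parameters for one subject."""

    subject_id: str
    params: Mapping[str, DDMParams]  # one entry per condition
    seed: int

    def __post_init__(self) -> None:
        if set(self.params) != set(CONDITIONS):
            raise ValueError(f"params must cover exactly {CONDITIONS}")


@dataclass(frozen=True)
class ExperimentDesign:
    design_kind: str  # "fixed_range" | "balanced"
    stimulus_set: StimulusSet = EXP1_STIMULUS_SET
    n_per_stimulus: int = 100
    dt: float = 5e-4

    def __post_init__(self) -> None:
        if self.design_kind not in ("fixed_range", "balanced"):
            raise ValueError(f"unknown design kind {self.design_kind!r}")
        if self.n_per_stimulus < 1:
            raise ValueError("n_per_stimulus must be >= 1")


def _first_passage_sample(mu: float, b_up: float, b_lo: float, n: int,
                          rng: np.random.Generator, dt: float,
                          t_cap: float = 60.0) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized first-passage simulation with bridge crossing tests.

    Returns (hit_upper: bool array, decision_time: float array).
    """
    v = np.zeros(n)
    hit_up_out = np.zeros(n, dtype=bool)
    fpt = np.full(n, t_cap)
    active = np.arange(n)
    sdt = math.sqrt(dt)
    max_steps = int(t_cap / dt)
    step = 0
    while active.size and step < max_steps:
        step += 1
        v0 = v[active]
        v1 = v0 + mu * dt + sdt * rng.standard_normal(active.size)
        hit_up = v1 >= b_up
        hit_lo = v1 <= -b_lo
        mid = ~(hit_up | hit_lo)
        if mid.any():
            vm0, vm1 = v0[mid], v1[mid]
            # P(bridge touched a bound within the step), one bound at a time;
            # simultaneous double-crossing within one step is negligible
            pu = np.exp(-2.0 * (b_up - vm0) * (b_up - vm1) / dt)
            pl = np.exp(-2.0 * (vm0 + b_lo) * (vm1 + b_lo) / dt)
            u = rng.random(int(mid.sum()))
            widx = np.flatnonzero(mid)
            hit_up[widx[u < pu]] = True
            hit_lo[widx[(u >= pu) & (u < pu + pl)]] = True
        done = hit_up | hit_lo
        idx = active[done]
        fpt[idx] = step * dt
        hit_up_out[idx] = hit_up[done]
        keep = ~done
        v[active[keep]] = v1[keep]
        active = active[keep]
    if active.size:  # pathological parameters only; absorb at nearer side
        hit_up_out[active] = v[active] > 0
    return hit_up_out, fpt


def _nondecision_draws(n: int, mean: float, sd: float,
                       rng: np.random.Generator) -> np.ndarray:
    out = rng.normal(mean, sd, n)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= 0
    return out


def simulate_trials(params: DDMParams, stimuli: StimulusSet,
                    n_per_stimulus: int, seed: int,
                    subject_id: str = "sim", condition: str = "unadapted",
                    dt: float = 5e-4) -> TrialTable:
    """Simulate ``n_per_stimulus`` trials at every stimulus in the set."""
    if n_per_stimulus < 1:
        raise ValueError("n_per_stimulus must be >= 1")
    rng = np.random.default_rng(seed)
    b_up, b_lo = params.bound_upper, params.bound_lower
    if not (b_up > 0 and b_lo > 0):
        raise ValueError("both bounds must have positive height")
    frames = []
    for s in stimuli.strengths:
        mu = drift_at(params.drift, s)
        hit_up, fpt = _first_passage_sample(mu, b_up, b_lo, n_per_stimulus,
                                            rng, dt)
        nd = _nondecision_draws(n_per_stimulus, params.nd_mean, params.nd_sd, rng)
        frames.append({
            "stimulus_strength": np.full(n_per_stimulus, s),
            "choice": np.where(hit_up, "sad", "happy"),
            "rt": fpt + nd,
        })
    df = pd.concat([pd.DataFrame(f) for f in frames], ignore_index=True)
    df.insert(0, "subject_id", subject_id)
    df.insert(1, "condition", condition)
    return TrialTable(df, provenance=[f"simulated (seed={seed}, dt={dt})"])


def model_pse(params: DDMParams) -> float:
    """Strength where the model's P(sad) crosses 0.5 (linear drift rule)."""
    if params.drift.kind != "reduced":
        raise ValueError("model_pse requires a reduced drift map")

    def f(s: float) -> float:
        return choice_prob_analytic(params.drift.linear_drift(s),
                                    params.bound_mean, params.bound_offset) - 0.5

    lo, hi = -1.0, 2.0
    if f(lo) * f(hi) > 0:
        raise ValueError("degenerate parameters: no P=0.5 crossing near [0, 1]")
    pse = brentq(f, lo, hi, xtol=1e-10)
    if not 0.0 <= pse <= 1.0:
        raise ValueError(f"model-implied PSE {pse:.3f} outside [0, 1]")
    return float(pse)


def balanced_stimulus_selection(params: DDMParams,
                                base_set: StimulusSet) -> StimulusSet:
    """Recentre the middle stimuli of ``base_set`` on the model-implied PSE.

    The extremes are kept in place; all members are clipped to [0, 1].
    """
    pse = model_pse(params)
    middle = np.array(base_set.middle)
    shift = pse - middle.mean()
    shifted = np.clip(middle + shift, 0.0, 1.0)
    i_lo, i_hi = base_set.extreme_indices
    strengths = sorted({*shifted.tolist(),
                        base_set.strengths[i_lo], base_set.strengths[i_hi]})
    return StimulusSet(tuple(strengths))


@dataclass(frozen=True)
class AdaptationEffects:
    """Config-driven effect sizes applied to the unadapted parameters.

    ``drift_shift`` moves the drift-map zero crossing toward the adaptor
    (strength units), ``bound_scale`` multiplies the bound mean,
    ``bound_offset_frac`` sets |dB| as a fraction of the scaled bound
    mean with the sign that lowers the bound *opposite* the adaptor, and
    ``nd_scale`` multiplies the nondecision mean.
    """

    drift_shift: float = 0.04
    bound_scale: float = 0.9
    bound_offset_frac: float = 0.1
    nd_scale: float = 0.92


def default_unadapted_params(slope: float = 8.0, center: float = 0.5,
                             mu_extreme: float = 3.2, bound_mean: float = 1.0,
                             nd_mean: float = 0.35,
                             stimuli: StimulusSet = EXP1_STIMULUS_SET,
                             ) -> DDMParams:
    dmap = DriftMap.reduced(slope=slope, center=center,
                            mu_low=-mu_extreme, mu_high=mu_extreme,
                            extreme_low=stimuli.extreme_low,
                            extreme_high=stimuli.extreme_high)
    return DDMParams(bound_mean=bound_mean, bound_offset=0.0,
                     nd_mean=nd_mean, drift=dmap)


def adapted_params(base: DDMParams, adaptor: str,
                   effects: AdaptationEffects) -> DDMParams:
    """Derive adapted-condition parameters from the unadapted ones.

    Happy adaptation shifts percepts toward sad: the drift map's zero
    crossing moves down (every stimulus drifts more positive) and the
    sad bound becomes the lower one (dB > 0). Sad adaptation mirrors.
    """
    if adaptor not in ("happy", "sad"):
        raise ValueError("adaptor must be 'happy' or 'sad'")
    sign = 1.0 if adaptor == "happy" else -1.0
    d = base.drift
    if d.kind != "reduced":
        raise ValueError("adapted_params requires a reduced drift map")
    k = d.slope
    dmap = replace(d, center=d.center - sign * effects.drift_shift,
                   mu_low=d.mu_low + sign * k * effects.drift_shift,
                   mu_high=d.mu_high + sign * k * effects.drift_shift)
    b = base.bound_mean * effects.bound_scale
    return DDMParams(bound_mean=b,
                     bound_offset=sign * effects.bound_offset_frac * b,
                     nd_mean=base.nd_mean * effects.nd_scale,
                     drift=dmap)


def make_subject_specs(n_subjects: int = 6, master_seed: int = 0,
                       effects: AdaptationEffects | None = None,
                       pse_spread: float = 0.03,
                       stimuli: StimulusSet = EXP1_STIMULUS_SET,
                       ) -> list[SubjectSpec]:
    """Paper-scale ground truth: subjects differ in baseline PSE and bounds."""
    effects = effects or AdaptationEffects()
    rng = np.random.default_rng(master_seed)
    specs = []
    for i in range(n_subjects):
        center = float(np.clip(0.5 + rng.normal(0, pse_spread), 0.3, 0.7))
        bound = float(rng.uniform(0.9, 1.15))
        nd = float(rng.uniform(0.3, 0.4))
        base = default_unadapted_params(center=center, bound_mean=bound,
                                        nd_mean=nd, stimuli=stimuli)
        params = {
            "unadapted": base,
            "happy_adapted": adapted_params(base, "happy", effects),
            "sad_adapted": adapted_params(base, "sad", effects),
        }
        specs.append(SubjectSpec(subject_id=f"s{i + 1:02d}", params=params,
                                 seed=int(rng.integers(0, 2**31 - 1))))
    return specs


def make_experiment(design: ExperimentDesign, subjects: Sequence[SubjectSpec],
                    master_seed: int = 0) -> tuple[list[TrialTable], dict]:
    """One trial table per subject (all three conditions) + ground truth.

    The manifest maps subject -> condition -> generating parameters and
    the realized stimulus set, sufficient for parameter-recovery tests.
    """
    rng = np.random.default_rng(master_seed)
    tables = []
    manifest: dict = {"design_kind": design.design_kind,
                      "n_per_stimulus": design.n_per_stimulus,
                      "master_seed": master_seed, "subjects": {}}
    for spec in subjects:
        sub_manifest = {}
        frames = []
        for cond in CONDITIONS:
            params = spec.params[cond]
            if design.design_kind == "balanced":
                stimset = balanced_stimulus_selection(params, design.stimulus_set)
            else:
                stimset = design.stimulus_set
            seed = int(rng.integers(0, 2**31 - 1)) ^ spec.seed
            tbl = simulate_trials(params, stimset, design.n_per_stimulus,
                                  seed=seed, subject_id=spec.subject_id,
                                  condition=cond, dt=design.dt)
            frames.append(tbl.df)
            sub_manifest[cond] = {"params": params.to_dict(),
                                  "stimuli": list(stimset.strengths),
                                  "seed": seed}
        df = pd.concat(frames, ignore_index=True)
        tables.append(TrialTable(df, experiment_id=design.design_kind,
                                 provenance=[f"simulated subject {spec.subject_id}"]))
        manifest["subjects"][spec.subject_id] = sub_manifest
    return tables, manifest
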