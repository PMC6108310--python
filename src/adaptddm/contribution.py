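"""Counterfactual partition of an adapted-vs-unadapted PSE shift into
sensitivity (drift), bound, and interaction components.

The partition swaps one parameter group at a time into the unadapted
model, predicts the psychometric function from the closed-form choice
probability, reads off the PSE of each prediction, and defines

    C_S   = PSE(unadapted bounds, adapted drifts)  - PSE(unadapted)
    C_B   = PSE(adapted bounds, unadapted drifts)  - PSE(unadapted)
    C_BxS = total - C_S - C_B          (residual, exactly additive)

The interaction is split evenly between the two overall contributions.
Nondecision time never enters: it cannot move the psychometric function.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ddm_analytic import choice_prob_analytic
from .ddm_core import DDMParams, drift_at
from .trial_data import StimulusSet

__all__ = [
    "ContributionResult",
    "predict_psychometric",
    "pse_from_predictions",
    "partition_shift",
]

_CLIP = 0.01  # probabilities this close to 0/1 are excluded from the logit fit


@dataclass(frozen=True)
class ContributionResult:
    total_shift: float
    c_sensitivity: float
    c_bound: float
    c_interaction: float

    @property
    def overall_sensitivity(self) -> float:
        return self.c_sensitivity + 0.5 * self.c_interaction

    @property
    def overall_bound(self) -> float:
        return self.c_bound + 0.5 * self.c_interaction

    def normalized(self) -> tuple[float, float]:
        """(overall sensitivity, overall bound) as fractions of the total."""
        if self.total_shift == 0:
            raise ZeroDivisionError("total shift is zero; nothing to normalize")
        return (self.overall_sensitivity / self.total_shift,
                self.overall_bound / self.total_shift)


def predict_psychometric(params: DDMParams,
                         stimuli: StimulusSet | Sequence[float]) -> np.ndarray:
    """Model-predicted P(sad) at each stimulus (closed form; exact)."""
    strengths = stimuli.strengths if isinstance(stimuli, StimulusSet) else stimuli
    return np.array([
        choice_prob_analytic(drift_at(params.drift, s),
                             params.bound_mean, params.bound_offset)
        for s in strengths
    ])


@dataclass(frozen=True)
class PSEFromPredictions:
    pse: float
    beta0: float
    extrapolated: bool  # no 0.5 crossing inside the stimulus range
    n_clipped: int


def pse_from_predictions(probs: Sequence[float],
                         stimuli: StimulusSet | Sequence[float],
                         ) -> PSEFromPredictions:
    """PSE of predicted probabilities via the simple logistic model.

    Unweighted least squares of logits on stimulus strength
    (logit p = b0 (S + b1)); returns -b1, flagged when the predictions
    never cross 0.5 inside the tested range. Cells whose probability is
    within 0.01 of 0 or 1 (where the logit is effectively unmeasurable)
    are excluded from the fit when at least three cells remain, else
    clipped and kept.
    """
    strengths = np.asarray(stimuli.strengths if isinstance(stimuli, StimulusSet)
                           else stimuli, dtype=float)
    p = np.asarray(probs, dtype=float)
    extrapolated = bool(p.min() >= 0.5 or p.max() <= 0.5)
    near_edge = (p < _CLIP) | (p > 1 - _CLIP)
    n_clipped = int(near_edge.sum())
    if (~near_edge).sum() >= 3:
        # logits near 0/1 are unmeasurable and exert huge leverage; drop them
        s_fit, p_fit = strengths[~near_edge], p[~near_edge]
    else:
        s_fit, p_fit = strengths, np.clip(p, _CLIP, 1 - _CLIP)
    y = np.log(p_fit / (1 - p_fit))
    slope, intercept = np.polyfit(s_fit, y, 1)
    if slope == 0:
        raise ValueError("flat predictions: PSE undefined")
    return PSEFromPredictions(pse=float(-intercept / slope), beta0=float(slope),
                              extrapolated=extrapolated, n_clipped=n_clipped)


def partition_shift(unadapted: DDMParams, adapted: DDMParams,
                    stimuli: StimulusSet | Sequence[float],
                    ) -> ContributionResult:
    """Partition the adapted-unadapted PSE shift into C_S, C_B, C_BxS.

    "Bounds" means the pair (bound mean, bound offset) moved together.
    """
    def pse_of(params: DDMParams) -> float:
        return pse_from_predictions(predict_psychometric(params, stimuli),
                                    stimuli).pse

    pse_u = pse_of(unadapted)
    total = pse_of(adapted) - pse_u
    c_s = pse_of(unadapted.with_drift(adapted.drift)) - pse_u
    c_b = pse_of(unadapted.with_bounds(adapted.bound_mean,
                                       adapted.bound_offset)) - pse_u
    return ContributionResult(total_shift=total, c_sensitivity=c_s,
                              c_bound=c_b, c_interaction=total - c_s - c_b)
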