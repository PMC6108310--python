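"""Shared drift-diffusion parameterization.

Conventions used throughout the package:

* Momentary evidence has variance 1 per second; time is in seconds.
* The accumulator starts at 0. The upper bound absorbs "sad" choices,
  the lower bound "happy" choices.
* ``bound_mean`` (B) is the mean of the two absolute bound heights and
  ``bound_offset`` (dB) their offset, with

      upper (sad) bound height  = B - dB
      lower (happy) bound depth = B + dB

  so a *positive* offset brings the sad bound closer to the start point.
  In the zero-drift limit the absorption probability at the upper bound
  is (B + dB) / (2 B), which fixes this sign convention.
* Nondecision time is Gaussian with standard deviation equal to one
  third of its mean unless explicitly overridden.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

__all__ = [
    "DriftMap",
    "DDMParams",
    "drift_at",
]

_KEY_DECIMALS = 9  # stimulus strengths are matched to this precision


def _skey(s: float) -> float:
    return round(float(s), _KEY_DECIMALS)


@dataclass(frozen=True)
class DriftMap:
    """Map from stimulus strength to drift rate.

    Two kinds are supported:

    ``per_stimulus``
        An explicit lookup table (one free drift per tested stimulus).
    ``reduced``
        A linear rule ``mu = slope * (S - center)`` for the middle
        stimuli plus two free drifts for the designated extreme
        stimuli, which bypass the linear rule.
    """

    kind: str  # "per_stimulus" | "reduced"
    table: Mapping[float, float] | None = None
    slope: float | None = None
    center: float | None = None
    mu_low: float | None = None
    mu_high: float | None = None
    extreme_low: float | None = None
    extreme_high: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "per_stimulus":
            if not self.table:
                raise ValueError("per_stimulus DriftMap requires a nonempty table")
            object.__setattr__(
                self, "table", {_skey(k): float(v) for k, v in self.table.items()}
            )
        elif self.kind == "reduced":
            for name in ("slope", "center", "mu_low", "mu_high",
                         "extreme_low", "extreme_high"):
                if getattr(self, name) is None:
                    raise ValueError(f"reduced DriftMap requires '{name}'")
            if not self.extreme_low < self.extreme_high:
                raise ValueError("extreme_low must be < extreme_high")
        else:
            raise ValueError(f"unknown DriftMap kind {self.kind!r}")

    @classmethod
    def from_table(cls, table: Mapping[float, float]) -> "DriftMap":
        return cls(kind="per_stimulus", table=dict(table))

    @classmethod
    def reduced(cls, slope: float, center: float, mu_low: float, mu_high: float,
                extreme_low: float, extreme_high: float) -> "DriftMap":
        return cls(kind="reduced", slope=slope, center=center,
                   mu_low=mu_low, mu_high=mu_high,
                   extreme_low=extreme_low, extreme_high=extreme_high)

    def __call__(self, strength: float) -> float:
        return drift_at(self, strength)

    def linear_drift(self, strength: float) -> float:
        """Evaluate the middle-stimulus linear rule at any strength.

        Only defined for the reduced kind; used for root finding
        (e.g. locating the model-implied PSE on a continuum).
        """
        if self.kind != "reduced":
            raise ValueError("linear_drift is only defined for reduced maps")
        return self.slope * (strength - self.center)

    def stimuli(self) -> tuple[float, ...]:
        if self.kind != "per_stimulus":
            raise ValueError("only per_stimulus maps enumerate their stimuli")
        return tuple(sorted(self.table))

    def to_dict(self) -> dict:
        if self.kind == "per_stimulus":
            return {"kind": self.kind,
                    "table": {repr(k): v for k, v in self.table.items()}}
        return {"kind": self.kind, "slope": self.slope, "center": self.center,
                "mu_low": self.mu_low, "mu_high": self.mu_high,
                "extreme_low": self.extreme_low, "extreme_high": self.extreme_high}

    @classmethod
    def from_dict(cls, d: Mapping) -> "DriftMap":
        if d["kind"] == "per_stimulus":
            return cls.from_table({float(k): float(v) for k, v in d["table"].items()})
        return cls.reduced(d["slope"], d["center"], d["mu_low"], d["mu_high"],
                           d["extreme_low"], d["extreme_high"])


def drift_at(dmap: DriftMap, strength: float) -> float:
    """Drift rate for stimulus ``strength`` under ``dmap``.

    Raises ``KeyError`` naming the strength when a per-stimulus lookup
    misses or a reduced-map strength falls outside the working range.
    """
    s = _skey(strength)
    if dmap.kind == "per_stimulus":
        try:
            return dmap.table[s]
        except KeyError:
            raise KeyError(f"no drift entry for stimulus strength {strength}") from None
    lo, hi = _skey(dmap.extreme_low), _skey(dmap.extreme_high)
    if s == lo:
        return dmap.mu_low
    if s == hi:
        return dmap.mu_high
    if lo < s < hi:
        return dmap.slope * (s - dmap.center)
    raise KeyError(f"stimulus strength {strength} outside reduced-map range [{lo}, {hi}]")


@dataclass(frozen=True)
class DDMParams:
    """Full decision-model parameterization.

    ``nd_sd`` defaults to ``nd_mean / 3`` when not given.
    """

    bound_mean: float
    bound_offset: float
    nd_mean: float
    drift: DriftMap
    nd_sd: float | None = None

    def __post_init__(self) -> None:
        if not self.bound_mean > 0:
            raise ValueError("bound_mean must be > 0")
        if not self.bound_mean > abs(self.bound_offset):
            raise ValueError("bound_mean must exceed |bound_offset| "
                             "(both bounds must have positive height)")
        if not self.nd_mean > 0:
            raise ValueError("nd_mean must be > 0")
        if self.nd_sd is None:
            object.__setattr__(self, "nd_sd", self.nd_mean / 3.0)
        elif self.nd_sd < 0:
            raise ValueError("nd_sd must be >= 0")

    @property
    def bound_upper(self) -> float:
        """Height of the upper (sad) bound: B - dB."""
        return self.bound_mean - self.bound_offset

    @property
    def bound_lower(self) -> float:
        """Depth of the lower (happy) bound (positive): B + dB."""
        return self.bound_mean + self.bound_offset

    def with_drift(self, drift: DriftMap) -> "DDMParams":
        return replace(self, drift=drift)

    def with_bounds(self, bound_mean: float, bound_offset: float) -> "DDMParams":
        return replace(self, bound_mean=bound_mean, bound_offset=bound_offset)

    def to_dict(self) -> dict:
        return {
            "units": {"evidence": "unit variance per second", "time": "seconds"},
            "bound_mean": self.bound_mean,
            "bound_offset": self.bound_offset,
            "nd_mean": self.nd_mean,
            "nd_sd": self.nd_sd,
            "drift": self.drift.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DDMParams":
        return cls(bound_mean=float(d["bound_mean"]),
                   bound_offset=float(d["bound_offset"]),
                   nd_mean=float(d["nd_mean"]),
                   nd_sd=float(d["nd_sd"]) if d.get("nd_sd") is not None else None,
                   drift=DriftMap.from_dict(d["drift"]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "DDMParams":
        return cls.from_dict(json.loads(Path(path).read_text()))
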