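"""Trial tables: I/O, outlier filtering, pooling, and cross-subject alignment.

A trial table wraps a pandas DataFrame with one row per behavioral trial
(columns ``subject_id, condition, stimulus_strength, choice, rt`` and an
optional ``block_id``) plus an experiment label and an append-only
provenance trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "CHOICES",
    "EXP1_STIMULI",
    "Trial",
    "TrialTable",
    "StimulusSet",
    "TrialValidationError",
    "load_trials",
    "write_trials",
    "filter_outliers",
    "pool_participants",
    "align_and_bin",
    "strength_to_morph_steps",
]

CONDITIONS = ("unadapted", "happy_adapted", "sad_adapted")
CHOICES = ("happy", "sad")

REQUIRED_COLUMNS = ("subject_id", "condition", "stimulus_strength", "choice", "rt")

#: The fixed 11-strength test set used by the fixed-range design:
#: nine equally spaced middle stimuli plus two near-extreme anchors.
EXP1_STIMULI = (0.125, 0.375, 0.400, 0.425, 0.450, 0.475,
                0.500, 0.525, 0.550, 0.575, 0.875)

#: Inter-image steps on the 41-image morph continuum (strength = index / 40).
MORPH_STEPS = 40


def strength_to_morph_steps(delta_strength: float) -> float:
    """Convert a stimulus-strength difference to morph-line image steps."""
    return delta_strength * MORPH_STEPS


class TrialValidationError(ValueError):
    """Raised when rows violate trial invariants; carries offending row numbers."""

    def __init__(self, message: str, rows: Sequence[int] = ()):
        super().__init__(message)
        self.rows = list(rows)


@dataclass(frozen=True)
class Trial:
    subject_id: str
    condition: str
    stimulus_strength: float
    choice: str
    rt: float
    block_id: str | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.choice not in CHOICES:
            raise ValueError(f"unknown choice {self.choice!r}")
        if not 0.0 <= self.stimulus_strength <= 1.0:
            raise ValueError("stimulus_strength must be in [0, 1]")
        if not self.rt > 0:
            raise ValueError("rt must be > 0")


@dataclass
class TrialTable:
    df: pd.DataFrame
    experiment_id: str = ""
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise TrialValidationError(f"missing required columns: {missing}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def subjects(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.df["subject_id"]))

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.df["condition"]))

    def select(self, condition: str | None = None,
               subject_id: str | None = None) -> "TrialTable":
        df = self.df
        if condition is not None:
            df = df[df["condition"] == condition]
        if subject_id is not None:
            df = df[df["subject_id"] == subject_id]
        return TrialTable(df.copy(), self.experiment_id, list(self.provenance))

    def with_note(self, note: str) -> "TrialTable":
        return TrialTable(self.df, self.experiment_id, [*self.provenance, note])

    def trials(self) -> Iterable[Trial]:
        has_block = "block_id" in self.df.columns
        for row in self.df.itertuples(index=False):
            yield Trial(str(row.subject_id), row.condition,
                        float(row.stimulus_strength), row.choice, float(row.rt),
                        str(row.block_id) if has_block else None)

    @classmethod
    def from_trials(cls, trials: Sequence[Trial], experiment_id: str = "") -> "TrialTable":
        rec = [{"subject_id": t.subject_id, "condition": t.condition,
                "stimulus_strength": t.stimulus_strength, "choice": t.choice,
                "rt": t.rt, **({"block_id": t.block_id} if t.block_id else {})}
               for t in trials]
        return cls(pd.DataFrame(rec), experiment_id)


@dataclass(frozen=True)
class StimulusSet:
    """Sorted distinct strengths with designated extreme members."""

    strengths: tuple[float, ...]
    extreme_indices: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        s = tuple(float(x) for x in self.strengths)
        if len(s) < 3:
            raise ValueError("a stimulus set needs at least 3 members")
        if any(not 0.0 <= x <= 1.0 for x in s):
            raise ValueError("stimulus strengths must lie in [0, 1]")
        if any(b <= a for a, b in zip(s, s[1:])):
            raise ValueError("stimulus strengths must be strictly increasing")
        object.__setattr__(self, "strengths", s)
        if self.extreme_indices is None:
            object.__setattr__(self, "extreme_indices", (0, len(s) - 1))

    @property
    def extreme_low(self) -> float:
        return self.strengths[self.extreme_indices[0]]

    @property
    def extreme_high(self) -> float:
        return self.strengths[self.extreme_indices[1]]

    @property
    def middle(self) -> tuple[float, ...]:
        ex = set(self.extreme_indices)
        return tuple(s for i, s in enumerate(self.strengths) if i not in ex)


EXP1_STIMULUS_SET = StimulusSet(EXP1_STIMULI)


# ---------------------------------------------------------------------------
# I/O

def _validate_frame(df: pd.DataFrame) -> None:
    bad: list[tuple[int, str]] = []
    strength = pd.to_numeric(df["stimulus_strength"], errors="coerce")
    rt = pd.to_numeric(df["rt"], errors="coerce")
    for i in df.index:
        row = i + 2  # header is line 1
        if df.at[i, "condition"] not in CONDITIONS:
            bad.append((row, f"condition {df.at[i, 'condition']!r}"))
        if df.at[i, "choice"] not in CHOICES:
            bad.append((row, f"choice {df.at[i, 'choice']!r}"))
        s = strength[i]
        if pd.isna(s) or not 0.0 <= s <= 1.0:
            bad.append((row, f"stimulus_strength {df.at[i, 'stimulus_strength']!r}"))
        r = rt[i]
        if pd.isna(r) or not r > 0:
            bad.append((row, f"rt {df.at[i, 'rt']!r}"))
    if bad:
        msg = "; ".join(f"row {r}: invalid {what}" for r, what in bad[:20])
        if len(bad) > 20:
            msg += f"; ... ({len(bad)} invalid rows total)"
        raise TrialValidationError(msg, rows=[r for r, _ in bad])
    df["stimulus_strength"] = strength.astype(float)
    df["rt"] = rt.astype(float)


def load_trials(path: str | Path, sep: str = ",",
                experiment_id: str | None = None) -> TrialTable:
    """Read a delimited trial file, validating every row.

    The header must name the five required columns; rows violating the
    trial invariants raise :class:`TrialValidationError` listing their
    (1-based, header-inclusive) line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, dtype={"subject_id": str, "block_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrialValidationError(f"{path}: missing required columns {missing}")
    _validate_frame(df)
    if experiment_id is None:
        experiment_id = path.stem
    return TrialTable(df, experiment_id, [f"loaded from {path.name}"])


def write_trials(table: TrialTable, path: str | Path, sep: str = ",") -> None:
    cols = [c for c in (*REQUIRED_COLUMNS, "block_id") if c in table.df.columns]
    table.df.to_csv(path, sep=sep, index=False, columns=cols)


# ---------------------------------------------------------------------------
# Filtering / pooling

def filter_outliers(table: TrialTable, max_rt: float = 5.0,
                    exclude_blocks: Sequence[str] = ()) -> tuple[TrialTable, pd.DataFrame]:
    """Drop trials with rt > ``max_rt`` (and, optionally, listed blocks).

    Returns the filtered table and a per-condition removal report with
    columns ``condition, n_before, n_removed, fraction_removed``.
    """
    if len(table) == 0:
        raise ValueError("cannot filter an empty table")
    df = table.df
    if exclude_blocks and "block_id" in df.columns:
        df = df[~df["block_id"].isin(list(exclude_blocks))]
    keep = df["rt"] <= max_rt
    rows = []
    for cond, grp in df.groupby("condition", observed=True):
        n = len(grp)
        nrem = int((grp["rt"] > max_rt).sum())
        rows.append({"condition": cond, "n_before": n, "n_removed": nrem,
                     "fraction_removed": nrem / n if n else 0.0})
    report = pd.DataFrame(rows)
    out = df[keep]
    if len(out) == 0:
        raise ValueError("outlier filter removed every trial — input looks corrupt")
    note = (f"filter_outliers(max_rt={max_rt}): removed "
            f"{len(df) - len(out)}/{len(df)} trials")
    return TrialTable(out.copy(), table.experiment_id,
                      [*table.provenance, note]), report


def pool_participants(tables: Sequence[TrialTable]) -> TrialTable:
    """Concatenate trials across participants (same experiment only)."""
    if not tables:
        raise ValueError("no tables to pool")
    exp_ids = {t.experiment_id for t in tables}
    if len(exp_ids) > 1:
        raise ValueError(f"refusing to pool across experiments: {sorted(exp_ids)}")
    df = pd.concat([t.df for t in tables], ignore_index=True)
    prov = [f"pooled {len(tables)} participant tables "
            f"({', '.join(sorted({s for t in tables for s in t.subjects}))})"]
    return TrialTable(df, tables[0].experiment_id, prov)


def align_and_bin(tables: Sequence[TrialTable], n_bins: int = 19,
                  min_participant_fraction: float = 2.0 / 3.0,
                  ) -> tuple[TrialTable, pd.DataFrame]:
    """Align per-subject strengths to the condition-mean PSE, then bin.

    Per condition: each subject's PSE is estimated with the simple
    logistic model; subject strengths are shifted by (group-average PSE
    - subject PSE); shifted strengths are assigned to ``n_bins``
    equal-width bins over their pooled range, bins with fewer than
    ``ceil(min_participant_fraction * n_subjects)`` contributing
    subjects are dropped, and retained trials adopt their bin center as
    the working strength.

    Returns the pooled aligned table and a bin report (condition, bin
    edges/center, per-bin subject and trial counts, kept flag). Binning
    is equal-width — a convention, noted in the report attrs.
    """
    from .psychometrics import fit_simple_logistic  # local import: avoid cycle

    if not tables:
        raise ValueError("no tables to align")
    pooled = pool_participants(tables)
    n_subjects = len({s for t in tables for s in t.subjects})
    min_count = int(np.ceil(min_participant_fraction * n_subjects))

    out_frames = []
    report_rows = []
    for cond in pooled.conditions:
        cdf = pooled.df[pooled.df["condition"] == cond].copy()
        pses = {}
        for subj, sdf in cdf.groupby("subject_id", observed=True):
            sub = TrialTable(sdf.copy(), pooled.experiment_id)
            try:
                fit = fit_simple_logistic(sub)
            except Exception as exc:  # noqa: BLE001 - re-raise with context
                raise RuntimeError(
                    f"logistic fit failed for subject {subj!r}, condition {cond!r}: {exc}"
                ) from exc
            pses[subj] = fit.pse
        group_pse = float(np.mean(list(pses.values())))
        shift = cdf["subject_id"].map(lambda s: group_pse - pses[s])
        cdf["stimulus_strength"] = cdf["stimulus_strength"] + shift

        lo = cdf["stimulus_strength"].min()
        hi = cdf["stimulus_strength"].max()
        width = (hi - lo) / n_bins if hi > lo else 1.0
        idx = np.floor((cdf["stimulus_strength"] - lo) / width).astype(int)
        idx = idx.clip(0, n_bins - 1)  # closes the top bin
        cdf["_bin"] = idx
        for b in range(n_bins):
            bdf = cdf[cdf["_bin"] == b]
            nsub = bdf["subject_id"].nunique()
            kept = nsub >= min_count
            center = lo + (b + 0.5) * width
            report_rows.append({
                "condition": cond, "bin": b,
                "lo": lo + b * width, "hi": lo + (b + 1) * width,
                "center": center, "n_subjects": int(nsub),
                "n_trials": len(bdf), "kept": bool(kept),
            })
            if kept and len(bdf):
                bdf = bdf.copy()
                bdf["stimulus_strength"] = np.clip(center, 0.0, 1.0)
                out_frames.append(bdf.drop(columns="_bin"))
    if not out_frames:
        raise ValueError("every bin was dropped by the participation rule")
    report = pd.DataFrame(report_rows)
    report.attrs["binning"] = "equal-width over pooled shifted range"
    out = pd.concat(out_frames, ignore_index=True)
    note = (f"align_and_bin(n_bins={n_bins}, min_fraction="
            f"{min_participant_fraction:.3f}): kept "
            f"{int(report['kept'].sum())}/{len(report)} condition-bins")
    return TrialTable(out, pooled.experiment_id, [*pooled.provenance, note]), report
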