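"""0-5 amplitude-anchored clinical tremor scale and score/amplitude links.

The ordinal scale maps visible tremor excursion (cm) onto six levels in
1.5 cm steps: 0 = no visible tremor, 1 = up to 1.5 cm, ..., 5 = 6 cm and
above.  Recorded displacement RMS is bridged to a visible peak-to-peak
excursion under a sinusoidal assumption (2*sqrt(2) * RMS).
"""

from __future__ import annotations

import math
import warnings
from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .agreement import pearson
from .metrics import TremorMetrics

__all__ = [
    "ClinicalScale",
    "ScoredTrial",
    "DEFAULT_SCALE",
    "score_from_amplitude",
    "rms_to_excursion",
    "retained_amplitude",
    "kinetic_marker",
    "clinical_correlation",
    "write_scored_csv",
    "read_scored_csv",
]

#: Peak-to-peak excursion of a sinusoid per unit RMS.
PEAK_TO_PEAK_PER_RMS = 2.0 * math.sqrt(2.0)


@dataclass(frozen=True)
class ClinicalScale:
    """Ordinal amplitude scale; ``boundaries`` are upper bin edges in cm."""

    boundaries: tuple[float, ...] = (1.5, 3.0, 4.5, 6.0)

    def __post_init__(self) -> None:
        b = tuple(float(v) for v in self.boundaries)
        object.__setattr__(self, "boundaries", b)
        if any(v <= 0 for v in b) or any(
            b[i] >= b[i + 1] for i in range(len(b) - 1)
        ):
            raise ValueError("boundaries must be positive and strictly increasing")

    @property
    def max_score(self) -> int:
        return len(self.boundaries) + 1


DEFAULT_SCALE = ClinicalScale()


@dataclass(frozen=True)
class ScoredTrial:
    """One trial with its clinical score and recorded per-axis metrics."""

    trial_id: str
    clinical_score: int
    recorded_metrics: list[TremorMetrics]
    task: str = "rest"

    def __post_init__(self) -> None:
        if not (0 <= self.clinical_score <= 5):
            raise ValueError(f"score must be 0-5, got {self.clinical_score}")
        if not self.recorded_metrics:
            raise ValueError("trial needs metrics for at least one axis")

    @property
    def retained_amplitude(self) -> float:
        return retained_amplitude(self.recorded_metrics)


def score_from_amplitude(
    excursion_cm: float, scale: ClinicalScale = DEFAULT_SCALE
) -> int:
    """Map a visible excursion (cm) to its ordinal score.

    Bins are half-open ``(lower, upper]`` so an excursion exactly on a
    boundary takes the lower score ("up to 1.5 cm" includes 1.5); zero
    excursion means no visible tremor (score 0).
    """
    if excursion_cm < 0:
        raise ValueError("excursion must be >= 0")
    if excursion_cm == 0:
        return 0
    return 1 + bisect_left(scale.boundaries, excursion_cm)


def rms_to_excursion(rms_mm: float) -> float:
    """Displacement RMS (mm) → sinusoid-equivalent peak-to-peak excursion (cm)."""
    if rms_mm < 0:
        raise ValueError("rms must be >= 0")
    return PEAK_TO_PEAK_PER_RMS * rms_mm / 10.0


def retained_amplitude(metrics_per_axis: list[TremorMetrics]) -> float:
    """Highest per-axis RMS; the amplitude retained for clinical comparison."""
    if not metrics_per_axis:
        raise ValueError("no axes supplied")
    return max(m.rms for m in metrics_per_axis)


def kinetic_marker(metrics: TremorMetrics) -> float:
    """Severity marker for the kinetic task: % power in the 3-7 Hz band.

    Substitutes for RMS when a slow (< 3 Hz) voluntary movement dominates
    the displacement amplitude.
    """
    return metrics.pow_dist


def _task_marker(trial: ScoredTrial) -> float:
    if trial.task == "kinetic":
        best = max(trial.recorded_metrics, key=lambda m: m.rms)
        return kinetic_marker(best)
    return trial.retained_amplitude


def clinical_correlation(
    trials: list[ScoredTrial],
) -> dict[str, tuple[float, float]]:
    """Per-task Pearson (r, p) between clinical score and recorded severity.

    Static tasks use the retained RMS amplitude; the kinetic task uses the
    3-7 Hz power-distribution marker instead.  Tasks with fewer than 3
    trials (or degenerate variance) are skipped with a warning.
    """
    by_task: dict[str, list[ScoredTrial]] = {}
    for t in trials:
        by_task.setdefault(t.task, []).append(t)
    out: dict[str, tuple[float, float]] = {}
    for task, ts in sorted(by_task.items()):
        if len(ts) < 3:
            warnings.warn(f"task {task!r}: fewer than 3 trials, skipped")
            continue
        scores = [t.clinical_score for t in ts]
        markers = [_task_marker(t) for t in ts]
        try:
            out[task] = pearson(scores, markers)
        except ValueError as exc:
            warnings.warn(f"task {task!r}: correlation undefined ({exc})")
    return out


# ---------------------------------------------------------------------------
# Scored-trial tables
# ---------------------------------------------------------------------------


def write_scored_csv(trials: list[ScoredTrial], path: str | Path) -> Path:
    """Write one row per trial: id, task, score, per-axis rms, markers."""
    rows = []
    for t in trials:
        row: dict[str, object] = {
            "trial_id": t.trial_id,
            "task": t.task,
            "clinical_score": t.clinical_score,
        }
        for m in t.recorded_metrics:
            row[f"rms_{m.axis}"] = m.rms
        row["retained_mm"] = t.retained_amplitude
        best = max(t.recorded_metrics, key=lambda m: m.rms)
        row["pow_dist"] = best.pow_dist
        rows.append(row)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")
    return path


def read_scored_csv(path: str | Path) -> pd.DataFrame:
    """Read a scored-trial table, validating scores lie in {0..5}."""
    df = pd.read_csv(path)
    for col in ("trial_id", "task", "clinical_score", "retained_mm"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    scores = df["clinical_score"]
    if not ((scores >= 0) & (scores <= 5) & (scores == scores.astype(int))).all():
        raise ValueError(f"{path}: clinical_score values must be integers 0-5")
    return df
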