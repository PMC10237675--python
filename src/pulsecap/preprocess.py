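"""Normalization of raw KTR tracks and variability-based track selection.

Raw nuclear reporter intensity is turned into the dimensionless
"translocation" signal x_t in two steps: (1) divide by the whole-image
mean intensity at the same time point (compensates global illumination /
bleaching changes), then (2) divide by the trailing 120-min mean of the
step-1 signal (compensates per-cell reporter expression).  The
translocation is x_t = 1 - (doubly normalized value), so x ~ 0 at rest
and rises when the reporter leaves the nucleus after an activity pulse.

Track selection ranks tracks by the sum of squared discrete derivatives
of the step-1 signal over the analyzed span and rejects the least
variable fraction f (default 20%), which removes cells whose receptor or
reporter is not functional.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from .simulate import RawTrajectory

__all__ = [
    "TranslocationTrajectory",
    "field_normalize",
    "normalize_trajectory",
    "variability_score",
    "select_tracks",
]

#: Trailing window (minutes, inclusive of t) of the second normalization step.
DEFAULT_HISTORY = 120


@dataclass
class TranslocationTrajectory:
    """Normalized per-cell translocation time series x_t."""

    track_id: int
    times: np.ndarray
    x: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        if len(self.times) != len(self.x):
            raise ValueError("times and x must have equal length")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("translocation values must be finite")


def field_normalize(raw: RawTrajectory) -> np.ndarray:
    """Step 1: nuclear intensity divided by the field mean, per time point."""
    if np.any(raw.field_mean_intensity <= 0):
        raise ValueError("field mean intensity must be positive")
    return raw.nuclear_intensity / raw.field_mean_intensity


def normalize_trajectory(
    raw: RawTrajectory, history: int = DEFAULT_HISTORY
) -> TranslocationTrajectory:
    """Two-step normalization into the translocation signal x_t.

    The trailing mean uses the most recent ``history`` samples inclusive
    of t.  The first ``history`` points of the track serve as burn-in and
    are excluded from the output.
    """
    y = field_normalize(raw)
    n = len(y)
    if n <= history:
        raise ValueError(
            f"track needs more than {history} points for normalization burn-in"
        )
    csum = np.concatenate(([0.0], np.cumsum(y)))
    # trailing mean over [t-history+1, t], defined from index history-1 on
    trailing = (csum[history:] - csum[:-history]) / history
    idx = np.arange(history, n)
    x = 1.0 - y[idx] / trailing[idx - history + 1]
    return TranslocationTrajectory(track_id=raw.track_id, times=raw.times[idx], x=x)


def variability_score(step1_values: Sequence[float]) -> float:
    """Sum of squared discrete derivatives of the step-1 signal.

    Low scores flag flat tracks, i.e. cells that never respond.  Invariant
    to constant offsets by construction.
    """
    y = np.asarray(step1_values, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least two points for a variability score")
    return float(np.sum(np.diff(y) ** 2))


def _analysis_scores(
    raws: Sequence[RawTrajectory], history: int
) -> Dict[int, float]:
    scores = {}
    for raw in raws:
        y = field_normalize(raw)[history:]
        scores[raw.track_id] = variability_score(y)
    return scores


def select_tracks(
    raws: Sequence[RawTrajectory],
    f: float = 0.2,
    history: int = DEFAULT_HISTORY,
) -> List[RawTrajectory]:
    """Reject the floor(f*N) least variable tracks; keep original order.

    Scores are computed on the step-1 (field-normalized) signal over the
    analyzed span (after the ``history`` burn-in).  Ties in the
    variability ranking are broken by track id for determinism.
    """
    if not 0.0 <= f < 1.0:
        raise ValueError("rejected fraction f must be in [0, 1)")
    raws = list(raws)
    if not raws:
        raise ValueError("empty trajectory ensemble")
    n_reject = math.floor(f * len(raws))
    if n_reject == 0:
        return raws
    scores = _analysis_scores(raws, history)
    ranked = sorted(raws, key=lambda r: (scores[r.track_id], r.track_id))
    rejected = {r.track_id for r in ranked[:n_reject]}
    return [r for r in raws if r.track_id not in rejected]
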