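"""Slice-based kNN reconstruction of the stimulus pulse train.

Translocation trajectories are cut into short overlapping "slices" of
``ell`` consecutive time points, represented by their ``ell - 1``
backward differences.  A k-nearest-neighbor classifier (k = 20, Euclidean
distance in difference space) predicts either

* (interval protocols) the time after pulse (TAP) of each slice, with
  slices predicting TAP in the voting set casting a vote for the implied
  pulse minute; minutes collecting at least two of their three possible
  votes become detections, which are then de-duplicated so that no two
  detections fall within any three consecutive minutes; or
* (binary protocols) a 0/1 pulse label per clock slot, with three
  shift-specific classifiers combined by hard voting (pulse iff >= 2 of 3
  say "pulse").

Either way the decision about a candidate pulse minute t0 uses only
reporter values in [t0 - 2, t0 + t_D] (``t_D`` = "time to decision",
default 5 min, giving the standard 8-min window and slice length 6).

The decoders follow the scikit-learn estimator contract (``fit`` /
``predict`` / ``get_params``), with fitted attributes carrying a trailing
underscore.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .preprocess import TranslocationTrajectory
from .protocols import PulseSequence

__all__ = [
    "Slice",
    "SliceKNNClassifier",
    "IntervalPulseDecoder",
    "BinaryPulseDecoder",
    "assign_tap",
    "make_slices",
    "knn_predict",
    "detect_interval",
    "detect_binary",
    "dedup_detections",
]

#: Minimum spacing (minutes) between de-duplicated detections.
MIN_DETECTION_SPACING = 3


def assign_tap(
    pulse_times: np.ndarray, slice_end: int, min_tap: int = 3
) -> Optional[int]:
    """Time-after-pulse label of a slice ending at ``slice_end``.

    Time from the last pulse at or before ``slice_end``, except when that
    time is shorter than ``min_tap`` minutes, in which case the time from
    the previous pulse is used (disambiguates very short inter-pulse
    intervals).  Returns ``None`` when no eligible pulse precedes the
    slice (such slices are excluded from training).
    """
    pulse_times = np.asarray(pulse_times)
    idx = int(np.searchsorted(pulse_times, slice_end, side="right")) - 1
    if idx < 0:
        return None
    tap = int(slice_end - pulse_times[idx])
    if tap < min_tap:
        idx -= 1
        if idx < 0:
            return None
        tap = int(slice_end - pulse_times[idx])
    return tap


class Slice:
    """Windowed feature vector of ``ell - 1`` backward differences."""

    __slots__ = ("track_id", "end_time", "features", "label")

    def __init__(self, track_id, end_time, features, label=None):
        self.track_id = track_id
        self.end_time = int(end_time)
        self.features = np.asarray(features, dtype=float)
        self.label = label

    def __repr__(self):  # pragma: no cover
        return (
            f"Slice(track={self.track_id}, end={self.end_time}, "
            f"label={self.label})"
        )


def _slice_features(x: np.ndarray, ell: int) -> np.ndarray:
    """All sliding windows of ell-1 consecutive backward differences."""
    d = np.diff(x)
    return np.lib.stride_tricks.sliding_window_view(d, ell - 1)


def make_slices(
    traj: TranslocationTrajectory,
    ell: int = 6,
    mode: str = "interval",
    pulses: Optional[PulseSequence] = None,
    min_tap: int = 3,
) -> List[Slice]:
    """Cut a trajectory into overlapping slices with per-mode labels.

    One slice per end time from the ``ell``-th point onward, so every
    non-terminal interior point is covered by ``ell`` slices.  In interval
    mode the label is the TAP (``None`` before the first pulse); in
    binary mode labelling is handled by the decoder (slices here carry
    ``None``).
    """
    if len(traj.x) < ell:
        raise ValueError(f"trajectory shorter than slice length {ell}")
    feats = _slice_features(traj.x, ell)
    ends = traj.times[ell - 1 :]
    out = []
    ptimes = pulses.times_array if pulses is not None else None
    for e, f in zip(ends, feats):
        label = None
        if mode == "interval" and ptimes is not None:
            label = assign_tap(ptimes, int(e), min_tap=min_tap)
        out.append(Slice(traj.track_id, e, f, label))
    return out


class SliceKNNClassifier(BaseEstimator, ClassifierMixin):
    """kNN majority-vote classifier on slice difference features.

    Parameters
    ----------
    k:
        Number of neighbors (default 20, as used throughout).

    Votes are hard: the majority label among the k nearest training
    slices wins.  Label ties are broken toward the tied label with the
    smaller mean neighbor distance, then toward the smaller label; this
    makes predictions deterministic.
    """

    def __init__(self, k: int = 20):
        self.k = k

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if len(X) < self.k:
            raise ValueError(f"need at least k={self.k} training slices")
        self.classes_, self._codes = np.unique(y, return_inverse=True)
        self._X = X
        self._nn = NearestNeighbors(n_neighbors=self.k).fit(X)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "_nn")
        X = check_array(X)
        dist, ind = self._nn.kneighbors(X)
        codes = self._codes[ind]  # (n_queries, k)
        n, n_classes = len(X), len(self.classes_)
        counts = np.zeros((n, n_classes), dtype=np.int32)
        np.add.at(counts, (np.repeat(np.arange(n), self.k), codes.ravel()), 1)
        best = counts.max(axis=1)
        is_tie = (counts == best[:, None]).sum(axis=1) > 1
        pred = counts.argmax(axis=1)
        for i in np.nonzero(is_tie)[0]:
            tied = np.nonzero(counts[i] == best[i])[0]
            means = [dist[i][codes[i] == c].mean() for c in tied]
            pred[i] = tied[int(np.argmin(means))]  # argmin -> smaller label on tie
        return self.classes_[pred]


def knn_predict(model: SliceKNNClassifier, slc: Slice):
    """Predict the label of a single slice with a fitted classifier."""
    return model.predict(slc.features.reshape(1, -1))[0]


def dedup_detections(times: Sequence[int]) -> np.ndarray:
    """Discard detections within 2 min after a kept detection.

    Scanning left to right, a detection is kept only if it is at least
    ``MIN_DETECTION_SPACING`` minutes after the previously kept one, so no
    two kept detections fall within any three consecutive minutes.
    """
    times = np.asarray(sorted(times), dtype=int)
    kept: List[int] = []
    for t in times:
        if not kept or t - kept[-1] >= MIN_DETECTION_SPACING:
            kept.append(int(t))
    return np.asarray(kept, dtype=int)


def _count_interval_votes(
    ends: np.ndarray,
    predicted_taps: np.ndarray,
    t_d: int,
    vote_min: int,
    t_lo: int,
    t_hi: int,
) -> np.ndarray:
    """Detections from predicted TAPs of one trajectory's slices.

    Slices predicting TAP in {t_d - 2, t_d - 1, t_d} vote for minute
    (end - TAP); minutes collecting >= ``vote_min`` of their three
    possible votes, with the full decision window inside [t_lo, t_hi],
    become detections (before de-duplication).
    """
    vote_set = {t_d - 2, t_d - 1, t_d}
    votes: Dict[int, int] = {}
    for e, tap in zip(ends, predicted_taps):
        if int(tap) in vote_set:
            cand = int(e) - int(tap)
            votes[cand] = votes.get(cand, 0) + 1
    detected = [
        t
        for t, v in sorted(votes.items())
        if v >= vote_min and t - 2 >= t_lo and t + t_d <= t_hi
    ]
    return dedup_detections(detected)


class IntervalPulseDecoder(BaseEstimator):
    """Reconstruct pulse times from trajectories under interval encoding.

    Parameters
    ----------
    k:
        Neighbors of the underlying slice classifier.
    t_D:
        Time to decision, minutes.  The decision window for a candidate
        pulse at t0 spans [t0 - 2, t0 + t_D]; slices have length
        ``t_D + 1`` and the voting TAP set is {t_D - 2, t_D - 1, t_D}.
        The default 5 reproduces the standard 8-min window with slice
        length 6 and votes from TAP 3, 4, 5.
    vote_min:
        Votes (out of the three possible) required for a detection.
    """

    def __init__(self, k: int = 20, t_D: int = 5, vote_min: int = 2):
        self.k = k
        self.t_D = t_D
        self.vote_min = vote_min

    @property
    def _ell(self) -> int:
        return self.t_D + 1

    @property
    def _min_tap(self) -> int:
        return self.t_D - 2

    def fit(self, X: Sequence[TranslocationTrajectory], y: PulseSequence):
        """Train the slice classifier on trajectories X and pulse train y."""
        if self.t_D < 2:
            raise ValueError("t_D must be >= 2 (window starts 2 min before t0)")
        feats, labels = [], []
        ptimes = y.times_array
        for traj in X:
            F = _slice_features(traj.x, self._ell)
            ends = traj.times[self._ell - 1 :]
            for e, f in zip(ends, F):
                tap = assign_tap(ptimes, int(e), min_tap=self._min_tap)
                if tap is not None:
                    feats.append(f)
                    labels.append(tap)
        self.classifier_ = SliceKNNClassifier(k=self.k).fit(
            np.asarray(feats), np.asarray(labels)
        )
        self.n_training_slices_ = len(labels)
        return self

    def predict(
        self, X: Sequence[TranslocationTrajectory]
    ) -> Dict[int, np.ndarray]:
        """Detected pulse times per track id (after de-duplication)."""
        check_is_fitted(self, "classifier_")
        # classify all test slices in one batch for speed
        blocks, ends_list, bounds = [], [], []
        for traj in X:
            F = _slice_features(traj.x, self._ell)
            blocks.append(F)
            ends_list.append(traj.times[self._ell - 1 :])
            bounds.append((int(traj.times[0]), int(traj.times[-1])))
        sizes = [len(b) for b in blocks]
        taps = self.classifier_.predict(np.concatenate(blocks))
        out: Dict[int, np.ndarray] = {}
        start = 0
        for traj, ends, n, (lo, hi) in zip(X, ends_list, sizes, bounds):
            out[traj.track_id] = _count_interval_votes(
                ends, taps[start : start + n], self.t_D, self.vote_min, lo, hi
            )
            start += n
        return out


class BinaryPulseDecoder(BaseEstimator):
    """Per-slot pulse detection for the binary (clocked) protocol.

    Three slice classifiers, one per shift of the slice window relative to
    the slot (starting 2, 1 and 0 minutes before the slot), are combined
    by hard voting: a slot is called a pulse iff at least ``vote_min`` of
    the three predictions are 1.
    """

    def __init__(self, k: int = 20, t_D: int = 5, vote_min: int = 2):
        self.k = k
        self.t_D = t_D
        self.vote_min = vote_min

    @property
    def _ell(self) -> int:
        return self.t_D + 1

    def _slot_slices(
        self,
        trajs: Sequence[TranslocationTrajectory],
        slots: np.ndarray,
        shift: int,
    ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Features, slot times and track ids of shift-``shift`` slices."""
        feats, slot_out, tracks = [], [], []
        for traj in trajs:
            t0, t1 = int(traj.times[0]), int(traj.times[-1])
            for s in slots:
                start = int(s) - 2 + shift
                if start < t0 or start + self._ell - 1 > t1:
                    continue  # slot too close to the trajectory edge
                i = start - t0
                seg = traj.x[i : i + self._ell]
                feats.append(np.diff(seg))
                slot_out.append(int(s))
                tracks.append(traj.track_id)
        return (
            np.asarray(feats),
            np.asarray(slot_out, dtype=int),
            np.asarray(tracks),
        )

    def fit(
        self,
        X: Sequence[TranslocationTrajectory],
        y: PulseSequence,
        slots: Optional[np.ndarray] = None,
    ):
        if slots is None:
            slots = self._slots_from(y)
        slots = np.asarray(slots, dtype=int)
        digit = {int(s): int(s in set(y.pulse_times)) for s in slots}
        self.classifiers_ = []
        for shift in range(3):
            F, sl, _ = self._slot_slices(X, slots, shift)
            labels = np.array([digit[s] for s in sl])
            self.classifiers_.append(SliceKNNClassifier(k=self.k).fit(F, labels))
        self.slots_ = slots
        return self

    @staticmethod
    def _slots_from(pulses: PulseSequence) -> np.ndarray:
        if pulses.protocol is None or pulses.protocol.kind != "binary":
            raise ValueError("binary decoder needs a binary protocol or slots")
        tau = pulses.protocol.tau_clock
        return np.arange(0, pulses.duration, tau, dtype=int)

    def predict(
        self,
        X: Sequence[TranslocationTrajectory],
        slots: Optional[np.ndarray] = None,
    ) -> Dict[int, Dict[int, int]]:
        """Per-track mapping slot time -> detected 0/1 (scored slots only)."""
        check_is_fitted(self, "classifiers_")
        slots = self.slots_ if slots is None else np.asarray(slots, dtype=int)
        votes: Dict[Tuple[int, int], int] = {}
        counted: Dict[Tuple[int, int], int] = {}
        for shift, clf in enumerate(self.classifiers_):
            F, sl, tr = self._slot_slices(X, slots, shift)
            if len(F) == 0:
                continue
            pred = clf.predict(F)
            for t, s, p in zip(tr, sl, pred):
                votes[(t, s)] = votes.get((t, s), 0) + int(p)
                counted[(t, s)] = counted.get((t, s), 0) + 1
        out: Dict[int, Dict[int, int]] = {traj.track_id: {} for traj in X}
        for (t, s), n in counted.items():
            if n == 3:  # only slots with all three shifts available are scored
                out[t][s] = int(votes[(t, s)] >= self.vote_min)
        return out


def detect_interval(
    traj: TranslocationTrajectory,
    model: IntervalPulseDecoder,
    t_D: Optional[int] = None,
) -> np.ndarray:
    """Detected pulse times of a single trajectory (fitted decoder)."""
    if t_D is not None and t_D != model.t_D:
        raise ValueError("t_D must match the fitted decoder")
    return model.predict([traj])[traj.track_id]


def detect_binary(
    traj: TranslocationTrajectory,
    slots: np.ndarray,
    model: BinaryPulseDecoder,
) -> Dict[int, int]:
    """Per-slot 0/1 detections of a single trajectory (fitted decoder)."""
    return model.predict([traj], slots=slots)[traj.track_id]
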