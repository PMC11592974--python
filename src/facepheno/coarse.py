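"""Coarse-grained analysis: thresholded per-slice statistics.

For slice k the three statistics are

* mean expression intensity  Ibar_k = mean_j max(I_kj)   (max over the six
  intensity channels, mean over the L frames),
* happy count                Cbar_k = sum_j c_kj         (c_kj = 1 when the
  frame's predicted category is "happiness", else 0),
* pose range                 Pbar_k = max_j P_kj - min_j P_kj  per Euler axis.

Each statistic is binarized against a fixed threshold (>= at the boundary):
intensity "activated" when Ibar_k >= T1 (default 0.3), happy expression
"displayed" when Cbar_k >= T2 (default 10, suppressing short-term noise),
and attention "maintained" (flag 1) unless the largest per-axis pose range
reaches T3 (default pi/3), in which case attention is considered to have
deviated (flag 0).

The coarse vector Oc concatenates the three flag blocks over the K slices,
[I1..IK, C1..CK, P1..PK], giving 18 binary features for K=6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .streams import HAPPY_INDEX, LengthError, SessionRecording, SliceStream

__all__ = [
    "CoarseThresholds",
    "CoarseSliceStats",
    "mean_max_intensity",
    "count_happy",
    "happy_labels",
    "pose_range",
    "binarize_intensity",
    "binarize_happy",
    "binarize_attention",
    "slice_stats",
    "coarse_vector",
    "CoarseFeatureExtractor",
    "coarse_stats_table",
]


@dataclass(frozen=True)
class CoarseThresholds:
    """Decision thresholds of the coarse rules.

    ``attention_rule`` selects the attention reading: ``"range"`` (default)
    thresholds the within-slice per-axis *range* of the Euler angles;
    ``"instant"`` is the alternative reading that thresholds the largest
    instantaneous absolute angle.
    """

    t1: float = 0.3
    t2: int = 10
    t3: float = math.pi / 3
    attention_rule: str = "range"

    def __post_init__(self) -> None:
        if not (0.0 <= self.t1 <= 1.0):
            raise ValueError("T1 must be in [0, 1]")
        if self.t2 < 0 or int(self.t2) != self.t2:
            raise ValueError("T2 must be a non-negative integer")
        if not (0.0 < self.t3 <= math.pi):
            raise ValueError("T3 must be in (0, pi]")
        if self.attention_rule not in ("range", "instant"):
            raise ValueError("attention_rule must be 'range' or 'instant'")


@dataclass(frozen=True)
class CoarseSliceStats:
    """The three raw statistics of one slice, before thresholding."""

    mean_intensity: float
    happy_count: int
    pose_range: tuple  # (pitch, roll, yaw)


def mean_max_intensity(intensities) -> float:
    """Mean over frames of the per-frame maximum of the six intensities."""
    arr = np.asarray(intensities, dtype=float)
    if arr.size == 0:
        raise LengthError("empty slice")
    return float(arr.max(axis=1).mean())


def happy_labels(s: SliceStream) -> np.ndarray:
    """Per-frame binary recoding: 1 when the predicted category is happiness."""
    return (s.labels == HAPPY_INDEX).astype(int)


def count_happy(labels) -> int:
    """Number of happy-labelled frames (sum of the 0/1 recoded labels)."""
    arr = np.asarray(labels)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("labels must be binary (happy=1, other=0)")
    return int(arr.sum())


def pose_range(poses) -> np.ndarray:
    """Per-axis max minus min of the Euler angles over the slice."""
    arr = np.asarray(poses, dtype=float)
    if arr.size == 0:
        raise LengthError("empty slice")
    return arr.max(axis=0) - arr.min(axis=0)


def binarize_intensity(mean_intensity: float, t1: float) -> int:
    return int(mean_intensity >= t1)


def binarize_happy(happy_count: int, t2: int) -> int:
    return int(happy_count >= t2)


def binarize_attention(pose_rng, t3: float) -> int:
    """1 = attention maintained; 0 = deviated (largest axis range >= T3)."""
    return int(np.max(np.asarray(pose_rng, dtype=float)) < t3)


def slice_stats(s: SliceStream) -> CoarseSliceStats:
    return CoarseSliceStats(
        mean_intensity=mean_max_intensity(s.intensities),
        happy_count=count_happy(happy_labels(s)),
        pose_range=tuple(pose_range(s.pose)),
    )


def _attention_statistic(s: SliceStream, thresholds: CoarseThresholds) -> np.ndarray:
    if thresholds.attention_rule == "instant":
        return np.abs(s.pose).max(axis=0)
    return pose_range(s.pose)


def coarse_vector(
    session: SessionRecording, thresholds: CoarseThresholds | None = None
) -> np.ndarray:
    """The 3K binary coarse features [intensity | happy | attention] blocks."""
    th = thresholds or CoarseThresholds()
    i_flags, c_flags, p_flags = [], [], []
    for s in session.slices:
        i_flags.append(binarize_intensity(mean_max_intensity(s.intensities), th.t1))
        c_flags.append(binarize_happy(count_happy(happy_labels(s)), th.t2))
        p_flags.append(binarize_attention(_attention_statistic(s, th), th.t3))
    return np.array(i_flags + c_flags + p_flags, dtype=int)


class CoarseFeatureExtractor(TransformerMixin, BaseEstimator):
    """Stateless transformer: sessions -> (n, 3K) binary coarse features.

    Parameters mirror :class:`CoarseThresholds`.
    """

    def __init__(self, t1: float = 0.3, t2: int = 10,
                 t3: float = math.pi / 3, attention_rule: str = "range"):
        self.t1 = t1
        self.t2 = t2
        self.t3 = t3
        self.attention_rule = attention_rule

    def _thresholds(self) -> CoarseThresholds:
        return CoarseThresholds(self.t1, self.t2, self.t3, self.attention_rule)

    def fit(self, X, y=None):
        self._thresholds()  # validate parameters
        self.n_features_out_ = 3 * X[0].n_slices if len(X) else 0
        return self

    def transform(self, X) -> np.ndarray:
        th = self._thresholds()
        return np.stack([coarse_vector(s, th) for s in X])


def coarse_stats_table(
    sessions, thresholds: CoarseThresholds | None = None
) -> pd.DataFrame:
    """Per-slice statistics and flags for inspection (one row per slice)."""
    th = thresholds or CoarseThresholds()
    rows = []
    for sess in sessions:
        for s in sess.slices:
            st = slice_stats(s)
            rows.append(
                {
                    "subject_id": sess.subject_id,
                    "group": sess.group,
                    "slice": s.index,
                    "mean_intensity": st.mean_intensity,
                    "happy_count": st.happy_count,
                    "range_pitch": st.pose_range[0],
                    "range_roll": st.pose_range[1],
                    "range_yaw": st.pose_range[2],
                    "intensity_flag": binarize_intensity(st.mean_intensity, th.t1),
                    "happy_flag": binarize_happy(st.happy_count, th.t2),
                    "attention_flag": binarize_attention(
                        _attention_statistic(s, th), th.t3
                    ),
                }
            )
    return pd.DataFrame(rows)
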