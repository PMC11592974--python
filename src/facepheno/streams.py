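"""Per-frame facial-behavior streams and session structure.

A *session* is one subject watching the six emotion-eliciting stimulus
clips.  The upstream perception models (expression-intensity estimation,
7-class expression recognition, head-pose estimation) reduce every video
frame to an 11-number summary: six basic-expression intensities in [0, 1],
a 7-class category probability distribution (six basic expressions plus
neutral) with its argmax label, and three head-pose Euler angles (pitch,
roll, yaw) in radians, each within [-pi/2, pi/2].

The session is cut into ``K`` slices (one per stimulus clip, K=6 by
default) and each slice is downsampled at equal time intervals to a fixed
length ``L`` (200 frames by default), so one session is a K x L grid of
frame records.

Slices store their frames as NumPy arrays for speed; :class:`FrameRecord`
offers a validated per-frame view for callers that want one.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "EXPRESSIONS",
    "HAPPY_INDEX",
    "ANGLE_BOUND",
    "SchemaError",
    "StreamValidationError",
    "LengthError",
    "EulerPose",
    "IntensityVector",
    "CategoryDistribution",
    "FrameRecord",
    "SliceStream",
    "SessionRecording",
    "downsample_indices",
    "downsample_equal_interval",
    "split_session",
    "read_session",
    "write_session",
    "read_cohort",
    "write_cohort",
]

#: Category order used everywhere, including argmax tie-breaking
#: (alphabetical: first maximal probability wins).
CATEGORIES = ("anger", "disgust", "fear", "happiness", "neutral", "sadness", "surprise")

#: The six basic expressions with intensity estimates (no neutral).
EXPRESSIONS = ("anger", "disgust", "fear", "happiness", "sadness", "surprise")

HAPPY_INDEX = CATEGORIES.index("happiness")
HAPPY_INTENSITY_INDEX = EXPRESSIONS.index("happiness")

#: Euler angles live in [-ANGLE_BOUND, ANGLE_BOUND].
ANGLE_BOUND = math.pi / 2

GROUPS = ("ASD", "TD")

_PROB_TOL = 1e-6

CSV_COLUMNS = (
    ["subject_id", "group", "slice_index", "frame_index"]
    + [f"int_{e}" for e in EXPRESSIONS]
    + [f"p_{c}" for c in CATEGORIES]
    + ["pred_label", "pitch", "roll", "yaw"]
)


class SchemaError(ValueError):
    """A file does not match the frame-CSV schema."""


class StreamValidationError(ValueError):
    """A value violates a domain-type invariant."""


class LengthError(ValueError):
    """A sequence has the wrong length for the requested operation."""


@dataclass(frozen=True)
class EulerPose:
    """Head orientation in radians; each angle in [-pi/2, pi/2]."""

    pitch: float
    roll: float
    yaw: float

    def __post_init__(self) -> None:
        for name in ("pitch", "roll", "yaw"):
            v = getattr(self, name)
            if not (-ANGLE_BOUND <= v <= ANGLE_BOUND):
                raise StreamValidationError(
                    f"{name}={v!r} outside [-pi/2, pi/2]"
                )

    def as_array(self) -> np.ndarray:
        return np.array([self.pitch, self.roll, self.yaw], dtype=float)


@dataclass(frozen=True)
class IntensityVector:
    """Estimated intensity of the six basic expressions, each in [0, 1]."""

    anger: float
    disgust: float
    fear: float
    happiness: float
    sadness: float
    surprise: float

    def __post_init__(self) -> None:
        for name in EXPRESSIONS:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise StreamValidationError(f"intensity {name}={v!r} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, e) for e in EXPRESSIONS], dtype=float)


@dataclass(frozen=True)
class CategoryDistribution:
    """7-class expression probability distribution and its argmax label.

    The label must equal the argmax of the probabilities; ties are broken
    by the fixed order of :data:`CATEGORIES` (first maximum wins).
    """

    probabilities: tuple  # length 7, order of CATEGORIES
    label: str

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (7,):
            raise StreamValidationError("category distribution needs 7 probabilities")
        if np.any(p < 0) or np.any(p > 1):
            raise StreamValidationError("category probabilities outside [0, 1]")
        if abs(float(p.sum()) - 1.0) > _PROB_TOL:
            raise StreamValidationError(
                f"category probabilities sum to {p.sum():.8f}, not 1"
            )
        expected = CATEGORIES[int(np.argmax(p))]
        if self.label != expected:
            raise StreamValidationError(
                f"label {self.label!r} inconsistent with argmax {expected!r}"
            )

    def as_array(self) -> np.ndarray:
        return np.asarray(self.probabilities, dtype=float)


@dataclass(frozen=True)
class FrameRecord:
    """One frame's intensity vector, category distribution and pose."""

    intensity: IntensityVector
    category: CategoryDistribution
    pose: EulerPose
    frame_index: int = 0

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise StreamValidationError("frame_index must be >= 0")


def _validate_slice_arrays(intensities, probabilities, labels, pose, where=""):
    L = intensities.shape[0]
    if intensities.shape != (L, 6):
        raise StreamValidationError(f"{where}intensities must be (L, 6)")
    if probabilities.shape != (L, 7):
        raise StreamValidationError(f"{where}probabilities must be (L, 7)")
    if labels.shape != (L,):
        raise StreamValidationError(f"{where}labels must be (L,)")
    if pose.shape != (L, 3):
        raise StreamValidationError(f"{where}pose must be (L, 3)")
    bad = np.flatnonzero((intensities < 0).any(axis=1) | (intensities > 1).any(axis=1))
    if bad.size:
        raise StreamValidationError(f"{where}intensity outside [0, 1] at row {bad[0]}")
    bad = np.flatnonzero(
        (probabilities < 0).any(axis=1)
        | (probabilities > 1).any(axis=1)
        | (np.abs(probabilities.sum(axis=1) - 1.0) > _PROB_TOL)
    )
    if bad.size:
        raise StreamValidationError(
            f"{where}category probabilities invalid at row {bad[0]}"
        )
    bad = np.flatnonzero(labels != np.argmax(probabilities, axis=1))
    if bad.size:
        raise StreamValidationError(
            f"{where}label inconsistent with argmax at row {bad[0]}"
        )
    bad = np.flatnonzero((np.abs(pose) > ANGLE_BOUND).any(axis=1))
    if bad.size:
        raise StreamValidationError(
            f"{where}Euler angle outside [-pi/2, pi/2] at row {bad[0]}"
        )


@dataclass
class SliceStream:
    """One slice: ``L`` consecutive (downsampled) frames of one stimulus clip.

    Arrays are row-per-frame: ``intensities`` (L, 6) in :data:`EXPRESSIONS`
    order, ``probabilities`` (L, 7) in :data:`CATEGORIES` order, ``labels``
    (L,) integer indices into :data:`CATEGORIES`, ``pose`` (L, 3) columns
    (pitch, roll, yaw).
    """

    index: int  # 1-based slice index k in 1..K
    intensities: np.ndarray
    probabilities: np.ndarray
    labels: np.ndarray
    pose: np.ndarray

    def __post_init__(self) -> None:
        if self.index < 1:
            raise StreamValidationError("slice index must be >= 1")
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.pose = np.asarray(self.pose, dtype=float)
        _validate_slice_arrays(
            self.intensities,
            self.probabilities,
            self.labels,
            self.pose,
            where=f"slice {self.index}: ",
        )

    def __len__(self) -> int:
        return self.intensities.shape[0]

    def __eq__(self, other) -> bool:
        if not isinstance(other, SliceStream):
            return NotImplemented
        return (
            self.index == other.index
            and np.array_equal(self.intensities, other.intensities)
            and np.array_equal(self.probabilities, other.probabilities)
            and np.array_equal(self.labels, other.labels)
            and np.array_equal(self.pose, other.pose)
        )

    @classmethod
    def from_frames(cls, index: int, frames: Sequence[FrameRecord]) -> "SliceStream":
        if len(frames) == 0:
            raise LengthError("a slice needs at least one frame")
        return cls(
            index=index,
            intensities=np.stack([f.intensity.as_array() for f in frames]),
            probabilities=np.stack([f.category.as_array() for f in frames]),
            labels=np.array([CATEGORIES.index(f.category.label) for f in frames]),
            pose=np.stack([f.pose.as_array() for f in frames]),
        )

    def frames(self) -> list[FrameRecord]:
        """Materialize validated per-frame records (positional frame_index)."""
        out = []
        for j in range(len(self)):
            out.append(
                FrameRecord(
                    intensity=IntensityVector(*self.intensities[j]),
                    category=CategoryDistribution(
                        tuple(self.probabilities[j]), CATEGORIES[self.labels[j]]
                    ),
                    pose=EulerPose(*self.pose[j]),
                    frame_index=j,
                )
            )
        return out


@dataclass
class SessionRecording:
    """One subject's session: ``K`` slices of ``L`` frames plus the group label."""

    subject_id: str
    group: str  # "ASD" or "TD"
    slices: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise StreamValidationError(f"group must be one of {GROUPS}")
        idx = sorted(s.index for s in self.slices)
        if idx != list(range(1, len(self.slices) + 1)):
            raise StreamValidationError(
                f"slice indices must be 1..K exactly once, got {idx}"
            )
        self.slices = sorted(self.slices, key=lambda s: s.index)
        lengths = {len(s) for s in self.slices}
        if len(lengths) > 1:
            raise StreamValidationError(f"slices have unequal lengths {lengths}")

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def n_frames(self) -> int:
        return sum(len(s) for s in self.slices)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SessionRecording):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.group == other.group
            and self.slices == other.slices
        )


# ---------------------------------------------------------------------------
# Slicing and downsampling
# ---------------------------------------------------------------------------

def downsample_indices(M: int, L: int) -> np.ndarray:
    """Equal-interval downsampling indices: floor(j*M/L) for j = 0..L-1.

    First-of-bin convention; strictly increasing (hence duplicate-free)
    whenever ``M >= L``.
    """
    if L < 1:
        raise LengthError("L must be >= 1")
    if M < L:
        raise LengthError(f"cannot downsample {M} frames to {L}")
    return (np.arange(L) * M) // L


def downsample_equal_interval(frames: Sequence, L: int):
    """Keep ``L`` frames at equal time intervals from a length-M sequence.

    Works on any indexable sequence (e.g. a list of :class:`FrameRecord`)
    and on NumPy arrays (first axis = time).
    """
    M = len(frames)
    idx = downsample_indices(M, L)
    if isinstance(frames, np.ndarray):
        return frames[idx]
    return [frames[int(i)] for i in idx]


def split_session(
    frames: Sequence[FrameRecord],
    boundaries: Sequence[int],
    L: int,
    subject_id: str = "anonymous",
    group: str = "TD",
) -> SessionRecording:
    """Cut a full recording into K slices at ``boundaries`` and downsample each.

    ``boundaries`` are K+1 strictly increasing frame offsets aligned to the
    start times of the stimulus clips; slice k covers
    ``frames[boundaries[k-1]:boundaries[k]]``.  Frame indices are reassigned
    positionally (0..L-1) within each slice.
    """
    b = list(boundaries)
    if len(b) < 2:
        raise StreamValidationError("need at least 2 boundaries")
    if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
        raise StreamValidationError("boundaries must be strictly increasing")
    if b[0] < 0 or b[-1] > len(frames):
        raise StreamValidationError("boundaries outside the recording")
    slices = []
    for k in range(1, len(b)):
        seg = frames[b[k - 1]:b[k]]
        if len(seg) < L:
            raise LengthError(
                f"slice {k} has {len(seg)} frames, fewer than L={L}"
            )
        kept = downsample_equal_interval(seg, L)
        slices.append(SliceStream.from_frames(k, kept))
    return SessionRecording(subject_id=subject_id, group=group, slices=slices)


# ---------------------------------------------------------------------------
# Frame-CSV I/O
# ---------------------------------------------------------------------------

def _session_to_frame_table(session: SessionRecording) -> pd.DataFrame:
    rows = []
    for s in session.slices:
        L = len(s)
        block = {
            "subject_id": [session.subject_id] * L,
            "group": [session.group] * L,
            "slice_index": [s.index] * L,
            "frame_index": np.arange(L),
        }
        for j, e in enumerate(EXPRESSIONS):
            block[f"int_{e}"] = s.intensities[:, j]
        for j, c in enumerate(CATEGORIES):
            block[f"p_{c}"] = s.probabilities[:, j]
        block["pred_label"] = [CATEGORIES[i] for i in s.labels]
        block["pitch"] = s.pose[:, 0]
        block["roll"] = s.pose[:, 1]
        block["yaw"] = s.pose[:, 2]
        rows.append(pd.DataFrame(block))
    return pd.concat(rows, ignore_index=True)[list(CSV_COLUMNS)]


def write_session(session: SessionRecording, path) -> None:
    """Write one session as a frame CSV (one row per frame, 9 sig. digits)."""
    df = _session_to_frame_table(session)
    df.to_csv(path, index=False, float_format="%.9g")


def read_session(path) -> SessionRecording:
    """Read and validate a frame CSV written per the schema.

    Raises :class:`SchemaError` for missing columns or an empty file, and
    :class:`StreamValidationError` (with the offending row) for values that
    violate the domain invariants.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise SchemaError(f"{path}: no data rows")
    subjects = df["subject_id"].unique()
    if len(subjects) != 1:
        raise SchemaError(f"{path}: expected one subject, found {list(subjects)}")
    groups = df["group"].unique()
    if len(groups) != 1:
        raise SchemaError(f"{path}: expected one group, found {list(groups)}")
    label_codes = df["pred_label"].map({c: i for i, c in enumerate(CATEGORIES)})
    if label_codes.isna().any():
        row = int(label_codes.index[label_codes.isna()][0])
        raise StreamValidationError(f"{path}: unknown pred_label at row {row}")
    slices = []
    for k, sub in df.groupby("slice_index"):
        sub = sub.sort_values("frame_index")
        try:
            slices.append(
                SliceStream(
                    index=int(k),
                    intensities=sub[[f"int_{e}" for e in EXPRESSIONS]].to_numpy(),
                    probabilities=sub[[f"p_{c}" for c in CATEGORIES]].to_numpy(),
                    labels=label_codes.loc[sub.index].to_numpy(),
                    pose=sub[["pitch", "roll", "yaw"]].to_numpy(),
                )
            )
        except StreamValidationError as exc:
            raise StreamValidationError(f"{path}: {exc}") from exc
    return SessionRecording(
        subject_id=str(subjects[0]), group=str(groups[0]), slices=slices
    )


def write_cohort(sessions: Iterable[SessionRecording], out_dir, manifest_extra=None):
    """Write each session as ``<subject_id>.csv`` plus a ``manifest.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for s in sessions:
        fname = f"{s.subject_id}.csv"
        write_session(s, out / fname)
        entries.append({"subject_id": s.subject_id, "group": s.group, "file": fname})
    manifest = {"sessions": entries}
    if manifest_extra:
        manifest.update(manifest_extra)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def read_cohort(cohort_dir) -> list:
    """Read every session listed in a cohort directory's manifest."""
    root = Path(cohort_dir)
    with open(root / "manifest.json") as fh:
        manifest = json.load(fh)
    return [read_session(root / e["file"]) for e in manifest["sessions"]]
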