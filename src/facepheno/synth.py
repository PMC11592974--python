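"""Synthetic session generator with controllable ASD/TD group differences.

No public dataset of per-frame facial-behavior streams from autistic and
typically developing children exists, so the package ships a generator
that reproduces the *statistical structure* the pipeline consumes:

* attention drift — a Poisson number of yaw excursions per slice (episode
  amplitude ``drift_span``), the proxy for "does attention deviate?";
* expression-intensity activation — the happiness-intensity channel
  follows a within-slice ramp between per-slice ``intensity_base`` and
  ``intensity_peak`` envelopes (rising across slices for the default TD
  profile, mirroring cumulative emotional arousal), plus a per-slice
  subject-level envelope offset so cohorts have between-subject variance;
* happy-expression occurrence — a Poisson number of disjoint happy bouts
  of fixed length, during which the category scores favor happiness;
* category ambiguity — probabilities are a tempered softmax of latent
  scores; higher ``ambiguity_temp`` flattens the distribution without
  changing the argmax label;
* temporal dynamics — ``smooth_ramp`` keeps the generated trajectories;
  ``erratic_jitter`` applies a random within-slice permutation of frames.
  Because every coarse statistic is order-free, permutation leaves all
  coarse marginals *exactly* matched while destroying temporal structure,
  which is what makes coarse-null cohorts possible.

No claim of clinical realism is made; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from ._nn import softmax
from .streams import (
    CATEGORIES,
    HAPPY_INDEX,
    HAPPY_INTENSITY_INDEX,
    SessionRecording,
    SliceStream,
    write_cohort,
)

__all__ = [
    "GroupProfile",
    "CohortConfig",
    "generate_session",
    "generate_cohort",
    "default_profiles",
    "coarse_null_profiles",
    "expected_happy_count",
    "expected_drift_count",
    "expected_mean_intensity",
]

_NEUTRAL_INDEX = CATEGORIES.index("neutral")
DYNAMICS_STYLES = ("smooth_ramp", "erratic_jitter")


def _per_slice(value, K: int) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, K)
    if arr.size != K:
        raise ValueError(f"expected scalar or length-{K} sequence, got {arr.size}")
    return arr


@dataclass(frozen=True)
class GroupProfile:
    """Generative parameters of one group (all rates are per slice)."""

    drift_rate: float = 0.5
    drift_span: float = 1.25
    intensity_base: tuple | float = 0.05
    intensity_peak: tuple | float = 0.3
    intensity_jitter_sd: float = 0.08
    happy_bout_rate: float = 1.0
    happy_bout_len: int = 15
    happy_intensity_boost: float = 0.25
    ambiguity_temp: float = 1.0
    dynamics_style: str = "smooth_ramp"
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if min(self.drift_rate, self.happy_bout_rate) < 0:
            raise ValueError("rates must be >= 0")
        if self.drift_span < 0 or self.noise_sd < 0 or self.intensity_jitter_sd < 0:
            raise ValueError("spans and noise scales must be >= 0")
        if self.ambiguity_temp <= 0:
            raise ValueError("ambiguity_temp must be > 0")
        if self.happy_bout_len < 1:
            raise ValueError("happy_bout_len must be >= 1")
        for v in np.atleast_1d(self.intensity_base).tolist() + np.atleast_1d(
            self.intensity_peak
        ).tolist():
            if not (0.0 <= v <= 1.0):
                raise ValueError("intensity envelopes must be in [0, 1]")
        if self.dynamics_style not in DYNAMICS_STYLES:
            raise ValueError(f"dynamics_style must be one of {DYNAMICS_STYLES}")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort layout: sizes, slicing grid, seed, and the two group profiles."""

    n_asd: int = 41
    n_td: int = 40
    K: int = 6
    L: int = 200
    seed: int = 0
    asd_profile: GroupProfile = field(default_factory=lambda: default_profiles()[0])
    td_profile: GroupProfile = field(default_factory=lambda: default_profiles()[1])

    def __post_init__(self) -> None:
        if self.n_asd < 1 or self.n_td < 1:
            raise ValueError("need at least one subject per group")
        if self.K < 1 or self.L < 1:
            raise ValueError("K and L must be >= 1")


def default_profiles() -> tuple[GroupProfile, GroupProfile]:
    """The default (ASD, TD) study conditions.

    TD: rising intensity envelope across slices (cumulative arousal),
    frequent happy bouts, rare attention drift, peaked categories, smooth
    dynamics.  ASD: flat low intensity, fewer happy bouts, frequent drift,
    ambiguous (flat) categories, erratic dynamics.  Effect sizes are
    moderate by design: groups overlap on every single feature.
    """
    asd = GroupProfile(
        drift_rate=0.65,
        drift_span=1.25,
        intensity_base=0.05,
        intensity_peak=0.37,
        intensity_jitter_sd=0.08,
        happy_bout_rate=0.85,
        happy_bout_len=15,
        ambiguity_temp=2.0,
        dynamics_style="erratic_jitter",
        noise_sd=0.02,
    )
    td = GroupProfile(
        drift_rate=0.30,
        drift_span=1.25,
        intensity_base=(0.04, 0.07, 0.10, 0.13, 0.16, 0.19),
        intensity_peak=(0.28, 0.32, 0.36, 0.40, 0.44, 0.48),
        intensity_jitter_sd=0.08,
        happy_bout_rate=1.5,
        happy_bout_len=15,
        ambiguity_temp=0.8,
        dynamics_style="smooth_ramp",
        noise_sd=0.02,
    )
    return asd, td


def coarse_null_profiles() -> tuple[GroupProfile, GroupProfile]:
    """Two profiles matched in every coarse statistic, differing only in
    temporal dynamics (smooth trajectories vs their within-slice random
    permutation).  Coarse statistics are order-free, so the match is exact
    in distribution by construction; only the fine-grained encoder can
    separate such groups."""
    shared = dict(
        drift_rate=0.5,
        drift_span=1.25,
        intensity_base=0.10,
        intensity_peak=0.45,
        intensity_jitter_sd=0.08,
        happy_bout_rate=1.2,
        happy_bout_len=15,
        ambiguity_temp=1.2,
        noise_sd=0.02,
    )
    return (
        GroupProfile(dynamics_style="erratic_jitter", **shared),
        GroupProfile(dynamics_style="smooth_ramp", **shared),
    )


# -- analytic expectations (used by calibration tests) ----------------------

def expected_happy_count(profile: GroupProfile) -> float:
    """E[happy frames per slice] = bout rate x bout length (disjoint bouts)."""
    return profile.happy_bout_rate * profile.happy_bout_len


def expected_drift_count(profile: GroupProfile) -> float:
    return profile.drift_rate


def expected_mean_intensity(profile: GroupProfile, K: int = 6) -> np.ndarray:
    """Per-slice E[mean happiness-channel envelope] = (base + peak) / 2.

    A good approximation of E[Ibar_k] whenever the happiness channel
    dominates the per-frame maximum and clipping is rare.
    """
    base = _per_slice(profile.intensity_base, K)
    peak = _per_slice(profile.intensity_peak, K)
    return (base + peak) / 2.0


# -- generation --------------------------------------------------------------

def _disjoint_starts(rng: np.random.Generator, n: int, length: int, L: int):
    """Sample up to n disjoint interval starts of ``length`` within [0, L)."""
    n = min(n, L // length) if length else 0
    starts: list[int] = []
    for _ in range(n):
        for _attempt in range(200):
            s = int(rng.integers(0, L - length + 1))
            if all(abs(s - t) >= length for t in starts):
                starts.append(s)
                break
    return starts


def _generate_slice(profile: GroupProfile, k: int, K: int, L: int,
                    rng: np.random.Generator) -> SliceStream:
    base = _per_slice(profile.intensity_base, K)[k - 1]
    peak = _per_slice(profile.intensity_peak, K)[k - 1]
    ramp = np.linspace(0.0, 1.0, L)

    # Happiness-intensity channel: ramped envelope + subject/slice offset.
    offset = rng.normal(0.0, profile.intensity_jitter_sd)
    happy_int = base + (peak - base) * ramp + offset
    happy_int = happy_int + rng.normal(0.0, profile.noise_sd, L)

    # Other five intensity channels: small half-normal background.
    others = np.abs(rng.normal(0.0, 0.03, (L, 5)))

    # Happy bouts: disjoint fixed-length runs of happy-labelled frames.
    n_bouts = int(rng.poisson(profile.happy_bout_rate))
    bout_mask = np.zeros(L, dtype=bool)
    for s in _disjoint_starts(rng, n_bouts, profile.happy_bout_len, L):
        bout_mask[s:s + profile.happy_bout_len] = True
    happy_int[bout_mask] += profile.happy_intensity_boost

    intensities = np.empty((L, 6))
    intensities[:, HAPPY_INTENSITY_INDEX] = happy_int
    other_cols = [j for j in range(6) if j != HAPPY_INTENSITY_INDEX]
    intensities[:, other_cols] = others
    intensities = np.clip(intensities, 0.0, 1.0)

    # Category distribution: tempered softmax of latent scores.  The
    # happiness-vs-neutral margin (4 vs 2) dwarfs the score noise, so the
    # argmax label is happy exactly on bout frames.
    scores = np.zeros((L, 7))
    scores[:, _NEUTRAL_INDEX] = 2.0
    scores[bout_mask, HAPPY_INDEX] = 4.0
    scores += rng.normal(0.0, 0.3, scores.shape)
    probabilities = softmax(scores / profile.ambiguity_temp, axis=1)
    labels = np.argmax(probabilities, axis=1)

    # Pose: slow small wander plus Poisson drift excursions on yaw.
    t = np.arange(L)
    freq = rng.uniform(1.0, 3.0)
    phase = rng.uniform(0.0, 2 * np.pi)
    yaw = 0.04 * np.sin(2 * np.pi * freq * t / L + phase)
    pitch = 0.03 * np.sin(2 * np.pi * rng.uniform(1, 3) * t / L + rng.uniform(0, 7))
    roll = 0.02 * np.sin(2 * np.pi * rng.uniform(1, 3) * t / L + rng.uniform(0, 7))
    span_len = max(4, L // 8)
    n_drift = int(rng.poisson(profile.drift_rate))
    bump = np.sin(np.pi * np.arange(span_len) / (span_len - 1))
    for s in _disjoint_starts(rng, n_drift, span_len, L):
        yaw[s:s + span_len] += float(rng.choice((-1.0, 1.0))) * profile.drift_span * bump
    pose = np.stack([pitch, roll, yaw], axis=1)
    pose += rng.normal(0.0, profile.noise_sd, pose.shape)
    pose = np.clip(pose, -np.pi / 2, np.pi / 2)

    if profile.dynamics_style == "erratic_jitter":
        perm = rng.permutation(L)
        intensities = intensities[perm]
        probabilities = probabilities[perm]
        labels = labels[perm]
        pose = pose[perm]

    return SliceStream(index=k, intensities=intensities,
                       probabilities=probabilities, labels=labels, pose=pose)


def generate_session(profile: GroupProfile, K: int = 6, L: int = 200,
                     seed=0, subject_id: str = "synthetic",
                     group: str = "TD") -> SessionRecording:
    """One reproducible session: K slices of L validated frames."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    slices = [_generate_slice(profile, k, K, L, rng) for k in range(1, K + 1)]
    return SessionRecording(subject_id=subject_id, group=group, slices=slices)


def generate_cohort(config: CohortConfig, out_dir=None):
    """A labelled cohort plus its manifest; optionally written to disk.

    Per-session child seeds are derived deterministically from the master
    seed via a seed sequence, so the same config reproduces the cohort
    byte-for-byte.
    """
    n_total = config.n_asd + config.n_td
    child_seeds = np.random.SeedSequence(config.seed).generate_state(n_total)
    sessions, entries = [], []
    i = 0
    for group, n, profile in (("ASD", config.n_asd, config.asd_profile),
                              ("TD", config.n_td, config.td_profile)):
        for j in range(n):
            sid = f"{group}_{j + 1:03d}"
            child = int(child_seeds[i])
            sessions.append(
                generate_session(profile, config.K, config.L,
                                 seed=child, subject_id=sid, group=group)
            )
            entries.append({"subject_id": sid, "group": group, "seed": child})
            i += 1
    manifest = {
        "config": {
            "n_asd": config.n_asd, "n_td": config.n_td,
            "K": config.K, "L": config.L, "seed": config.seed,
            "asd_profile": asdict(config.asd_profile),
            "td_profile": asdict(config.td_profile),
        },
        "session_seeds": entries,
    }
    if out_dir is not None:
        write_cohort(sessions, out_dir, manifest_extra=manifest)
    return sessions, manifest
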