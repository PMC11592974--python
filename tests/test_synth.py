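"""Generator validity, seed determinism, and analytic calibration."""

import numpy as np
import pytest

from facepheno.coarse import CoarseThresholds, coarse_vector, count_happy, happy_labels
from facepheno.streams import write_session
from facepheno.synth import (
    CohortConfig,
    GroupProfile,
    coarse_null_profiles,
    default_profiles,
    expected_happy_count,
    expected_mean_intensity,
    generate_cohort,
    generate_session,
)


class TestValidityAndDeterminism:
    def test_generated_sessions_pass_all_stream_validators(self, small_profile):
        # SliceStream/SessionRecording constructors validate on build
        s = generate_session(small_profile, K=6, L=80, seed=1)
        assert s.n_frames == 480

    def test_same_seed_same_session(self, small_profile):
        a = generate_session(small_profile, K=3, L=40, seed=9)
        b = generate_session(small_profile, K=3, L=40, seed=9)
        assert a == b

    def test_cohort_files_byte_identical_across_reruns(self, tmp_path):
        cfg = CohortConfig(n_asd=2, n_td=2, L=30, seed=5)
        generate_cohort(cfg, out_dir=tmp_path / "a")
        generate_cohort(cfg, out_dir=tmp_path / "b")
        for name in ["ASD_001.csv", "TD_002.csv", "manifest.json"]:
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()

    def test_child_seeds_distinct_and_sessions_differ(self, tmp_path):
        sessions, manifest = generate_cohort(CohortConfig(n_asd=4, n_td=4,
                                                          L=30, seed=0))
        seeds = [e["seed"] for e in manifest["session_seeds"]]
        assert len(set(seeds)) == len(seeds)
        blobs = set()
        for s in sessions:
            p = tmp_path / f"{s.subject_id}.csv"
            write_session(s, p)
            blobs.add(p.read_bytes())
        assert len(blobs) == len(sessions)

    def test_cohort_size_41_plus_40(self):
        sessions, _ = generate_cohort(CohortConfig(L=20, seed=1))
        assert len(sessions) == 81
        groups = [s.group for s in sessions]
        assert groups.count("ASD") == 41 and groups.count("TD") == 40

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            GroupProfile(drift_rate=-1.0)
        with pytest.raises(ValueError):
            GroupProfile(ambiguity_temp=0.0)
        with pytest.raises(ValueError):
            GroupProfile(dynamics_style="chaotic")


class TestCoarsePatternsForcedByProfile:
    def test_no_drift_means_attention_always_maintained(self):
        profile = GroupProfile(drift_rate=0.0, intensity_base=0.1,
                               intensity_peak=0.3, happy_bout_rate=1.0)
        for seed in range(5):
            v = coarse_vector(generate_session(profile, K=6, L=60, seed=seed))
            assert np.all(v[12:] == 1)

    def test_fully_inactive_profile_pattern(self):
        profile = GroupProfile(drift_rate=0.0, intensity_base=0.0,
                               intensity_peak=0.0, happy_bout_rate=0.0,
                               intensity_jitter_sd=0.0, noise_sd=0.005)
        v = coarse_vector(generate_session(profile, K=6, L=60, seed=2))
        assert np.array_equal(v, [0] * 6 + [0] * 6 + [1] * 6)


class TestAnalyticCalibration:
    def test_happy_count_matches_rate_times_length(self):
        profile = GroupProfile(happy_bout_rate=2.0, happy_bout_len=15,
                               drift_rate=0.5)
        counts = []
        for seed in range(200):
            s = generate_session(profile, K=1, L=200, seed=seed)
            counts.append(count_happy(happy_labels(s.slices[0])))
        counts = np.array(counts)
        expected = expected_happy_count(profile)  # 30
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - expected) < 3 * se

    def test_mean_intensity_matches_envelope_mean(self):
        # happiness channel dominates: envelope well above background
        profile = GroupProfile(intensity_base=0.4, intensity_peak=0.6,
                               happy_bout_rate=0.0, drift_rate=0.0,
                               intensity_jitter_sd=0.05)
        means = []
        from facepheno.coarse import mean_max_intensity

        for seed in range(200):
            s = generate_session(profile, K=1, L=100, seed=seed)
            means.append(mean_max_intensity(s.slices[0].intensities))
        means = np.array(means)
        expected = expected_mean_intensity(profile, K=1)[0]  # 0.5
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - expected) < 3 * se

    def test_drift_episode_rate_reflected_in_attention_flags(self):
        # P(flag = 1) = P(no episode) = exp(-rate)
        profile = GroupProfile(drift_rate=0.7, drift_span=1.3)
        flags = []
        for seed in range(300):
            v = coarse_vector(generate_session(profile, K=1, L=100, seed=seed))
            flags.append(v[2])
        p_hat = np.mean(flags)
        expected = np.exp(-0.7)
        se = np.sqrt(expected * (1 - expected) / 300)
        assert abs(p_hat - expected) < 3.5 * se


class TestCoarseNullProfiles:
    def test_profiles_differ_only_in_dynamics(self):
        a, b = coarse_null_profiles()
        da, db = a.__dict__.copy(), b.__dict__.copy()
        assert da.pop("dynamics_style") != db.pop("dynamics_style")
        assert da == db

    def test_coarse_statistics_match_between_groups(self):
        """Order-free coarse statistics cannot separate the two profiles."""
        from facepheno.coarse import mean_max_intensity

        a, b = coarse_null_profiles()
        stats_a, stats_b = [], []
        for seed in range(150):
            sa = generate_session(a, K=1, L=100, seed=seed)
            sb = generate_session(b, K=1, L=100, seed=10_000 + seed)
            for s, acc in ((sa, stats_a), (sb, stats_b)):
                sl = s.slices[0]
                acc.append([
                    mean_max_intensity(sl.intensities),
                    count_happy(happy_labels(sl)),
                    float(np.max(sl.pose.max(axis=0) - sl.pose.min(axis=0))),
                ])
        stats_a, stats_b = np.array(stats_a), np.array(stats_b)
        for j in range(3):
            diff = stats_a[:, j].mean() - stats_b[:, j].mean()
            se = np.sqrt(stats_a[:, j].var(ddof=1) / 150
                         + stats_b[:, j].var(ddof=1) / 150)
            assert abs(diff) < 3 * se, f"coarse statistic {j} not matched"

    def test_default_profiles_have_rising_td_intensity_envelope(self):
        asd, td = default_profiles()
        env = expected_mean_intensity(td, K=6)
        assert np.all(np.diff(env) > 0)
        assert np.all(expected_mean_intensity(asd, K=6)
                      == expected_mean_intensity(asd, K=6)[0])
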