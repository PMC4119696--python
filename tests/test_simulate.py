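import numpy as np
import pytest
from scipy import signal as sps

from gaitsim.nonoverlap import conventional_on_disjoint, sim_nonoverlap
from gaitsim.pipeline import BEHAVIORS, behavior_similarity, person_similarity
from gaitsim.simulate import (
    GaitSimConfig,
    POINTSET_KINDS,
    generate_cohort,
    generate_pointsets,
    generate_recording,
)


class TestConfig:
    def test_defaults(self):
        cfg = GaitSimConfig()
        assert cfg.n_subjects == 20
        assert cfg.n_samples == 1000

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_subjects": 0},
            {"duration_s": -1.0},
            {"noise_sd": -0.1},
            {"stair_shared_fraction": 1.5},
            {"stride_frequency_hz": {"walking": 1.0}},
            {"behavior_variability": {b: -1.0 for b in BEHAVIORS}},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GaitSimConfig(**kwargs)

    def test_config_hash_tracks_content(self):
        a = GaitSimConfig()
        b = GaitSimConfig(seed=43)
        assert a.config_hash() == GaitSimConfig().config_hash()
        assert a.config_hash() != b.config_hash()


class TestGenerateRecording:
    def test_shape_and_channels(self, small_config):
        rec = generate_recording(small_config, 0, "walking")
        assert len(rec.channels) == 36
        assert rec.n_samples == small_config.n_samples

    def test_noiseless_determinism(self):
        cfg = GaitSimConfig(n_subjects=1, duration_s=2.0,
                            subject_variation_sd=0.0, noise_sd=0.0)
        r1 = generate_recording(cfg, 0, "stair_up")
        r2 = generate_recording(cfg, 0, "stair_up")
        for c in r1.channels:
            np.testing.assert_array_equal(r1.channels[c], r2.channels[c])

    def test_seeded_determinism_with_noise(self, small_config):
        r1 = generate_recording(small_config, 1, "walking")
        r2 = generate_recording(small_config, 1, "walking")
        for c in r1.channels:
            np.testing.assert_array_equal(r1.channels[c], r2.channels[c])

    def test_dominant_frequency_is_behavior_fundamental(self):
        cfg = GaitSimConfig(n_subjects=1, duration_s=20.0,
                            subject_variation_sd=0.0, noise_sd=0.0)
        rec = generate_recording(cfg, 0, "walking")
        x = rec.channels["waist_accelerometer_z"]
        freqs, power = sps.periodogram(x, fs=cfg.sampling_rate_hz)
        peak = freqs[int(np.argmax(power))]
        assert peak == pytest.approx(cfg.stride_frequency_hz["walking"], abs=0.06)

    def test_invalid_subject_or_behavior(self, small_config):
        with pytest.raises(ValueError):
            generate_recording(small_config, 99, "walking")
        with pytest.raises(ValueError):
            generate_recording(small_config, 0, "running")


class TestGenerateCohort:
    def test_default_shape(self, default_cohort):
        assert len(default_cohort) == 20
        for prof in default_cohort:
            assert set(prof.recordings) == set(BEHAVIORS)

    def test_bit_identical_under_same_seed(self, small_config):
        c1 = generate_cohort(small_config)
        c2 = generate_cohort(small_config)
        for p1, p2 in zip(c1, c2):
            for b in BEHAVIORS:
                for c in p1.recordings[b].channels:
                    np.testing.assert_array_equal(
                        p1.recordings[b].channels[c],
                        p2.recordings[b].channels[c],
                    )

    def test_stair_pair_ranks_highest_in_cross_behavior_means(self, default_tables):
        means = default_tables.cross_behavior_mean
        assert means["stair_up~stair_down"] > means["walking~stair_up"]
        assert means["stair_up~stair_down"] > means["walking~stair_down"]


def mean_cross_person(cfg, behavior="walking"):
    cohort = generate_cohort(cfg)
    vals = [
        person_similarity(cohort[i], cohort[j], behavior)
        for i in range(len(cohort))
        for j in range(i + 1, len(cohort))
    ]
    return float(np.mean(vals))


class TestGeneratorProperties:
    def test_noise_degrades_similarity(self):
        # at zero subject variation the only cross-subject difference is the
        # noise itself; similarity must then fall monotonically with noise_sd
        # (at nonzero variation, min-max membership rescaling confounds this:
        # heavy noise inflates the range and compresses structural differences)
        scores = [
            mean_cross_person(
                GaitSimConfig(n_subjects=4, duration_s=5.0,
                              subject_variation_sd=0.0, noise_sd=noise)
            )
            for noise in (0.0, 0.05, 0.2, 0.5)
        ]
        assert all(a >= b for a, b in zip(scores, scores[1:]))
        assert scores[0] == pytest.approx(1.0)

    def test_subject_variation_degrades_similarity(self):
        scores = [
            mean_cross_person(
                GaitSimConfig(n_subjects=4, duration_s=5.0,
                              subject_variation_sd=sv)
            )
            for sv in (0.0, 0.1, 0.3)
        ]
        assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_stair_sharing_knob_is_detectable(self):
        def stair_scores(shared):
            cfg = GaitSimConfig(n_subjects=1, stair_shared_fraction=shared,
                                subject_variation_sd=0.0, noise_sd=0.0)
            prof = generate_cohort(cfg)[0]
            return {
                pair: behavior_similarity(prof, *pair)
                for pair in (("walking", "stair_up"), ("walking", "stair_down"),
                             ("stair_up", "stair_down"))
            }

        full = stair_scores(1.0)
        none = stair_scores(0.0)
        su_sd = ("stair_up", "stair_down")
        # fully shared: the stair pair is the clear maximum (not exactly 1:
        # the generator's phase flip leaves harmonic misalignment behind)
        assert full[su_sd] == max(full.values())
        assert full[su_sd] > 0.8
        # unshared: the stair pair is no longer the maximum
        assert none[su_sd] < max(none.values())
        assert full[su_sd] > none[su_sd]


class TestGeneratePointsets:
    def test_first_partition_values(self):
        diamond, circle = generate_pointsets("disjoint_a")
        assert diamond.values == (0.5, 0.8, 0.6, 0.5, 0.4, 1.0)
        assert circle.values == (0.4, 0.6, 0.7, 0.5, 0.8, 0.6)

    def test_second_partition_published_similarity(self):
        diamond, circle = generate_pointsets("disjoint_b")
        assert round(sim_nonoverlap(diamond, circle), 3) == 0.833

    def test_partitions_tie_under_conventional_measure(self):
        assert conventional_on_disjoint(
            *generate_pointsets("disjoint_a")
        ) == conventional_on_disjoint(*generate_pointsets("disjoint_b"))

    def test_random_kinds_deterministic(self):
        for kind in ("overlapped", "random_disjoint"):
            s1 = generate_pointsets(kind, seed=5)
            s2 = generate_pointsets(kind, seed=5)
            assert s1[0].values == s2[0].values
            assert s1[1].values == s2[1].values
            s3 = generate_pointsets(kind, seed=6)
            assert s3[0].values != s1[0].values

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            generate_pointsets("bogus")

    def test_all_kinds_produce_valid_samples(self):
        for kind in POINTSET_KINDS:
            d, c = generate_pointsets(kind, seed=1)
            assert d.label == "diamond" and c.label == "circle"
            assert len(d) > 0 and len(c) > 0
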