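"""The synthetic cohort generator: determinism, planted structure, artifacts."""

import numpy as np
import pytest

from alphagate.containers import ConfigurationError
from alphagate.indexes import change_scores, region_window_mean
from alphagate.montage import TEMPORAL_REGION
from alphagate.synthetic import (
    CLINICAL_ANCHORS,
    INSTRUMENT_RANGES,
    OUTCOMES,
    SimulationConfig,
    _rng_for,
    index_change_table,
    inject_artifacts,
    make_subject_session,
    simulate_cohort,
    simulate_subject_epochs,
)
from alphagate.timefreq import alpha_power_map


class TestConfigValidation:
    def test_defaults_are_the_study_design(self):
        cfg = SimulationConfig()
        assert cfg.n_per_group == 12
        assert cfg.groups == ("PMC", "M1", "Sham")
        assert cfg.sampling_rate == 500.0
        assert cfg.n_samples == 1000  # half-open [-1, 1) at 500 Hz
        assert 0.0 in cfg.time_axis

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(epoch_window=(0.5, 1.0)),
            dict(outlier_fraction=0.6),
            dict(surge_gain=0.5),
            dict(cf_suppression_gain=0.0),
            dict(channel_names=("Cz", "Pz", "VEOG")),
            dict(planted_rho={"PMC": 1.5}),
        ],
    )
    def test_invalid_configs_refused(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**kwargs)

    def test_small_groups_refused_by_cohort(self):
        with pytest.raises(ConfigurationError):
            simulate_cohort(SimulationConfig(n_per_group=3), include_epochs=False)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = SimulationConfig(n_per_group=4, n_epochs_per_session=3,
                               artifact_rate=0.2, seed=17)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        assert a.clinical.equals(b.clinical)
        assert a.truth.latent_change == b.truth.latent_change
        for key in a.epoch_sets:
            np.testing.assert_array_equal(a.epoch_sets[key].epochs,
                                          b.epoch_sets[key].epochs)

    def test_lazy_regeneration_matches_eager(self):
        cfg = SimulationConfig(n_per_group=4, n_epochs_per_session=3,
                               artifact_rate=0.2, seed=17)
        eager = simulate_cohort(cfg)
        lazy = simulate_cohort(cfg, include_epochs=False)
        assert lazy.epoch_sets is None
        regen = make_subject_session(cfg, lazy.truth, "S02", "post")
        np.testing.assert_array_equal(regen.epochs,
                                      eager.epoch_sets[("S02", "post")].epochs)

    def test_different_seeds_differ(self):
        a = simulate_cohort(SimulationConfig(n_per_group=4, seed=1), include_epochs=False)
        b = simulate_cohort(SimulationConfig(n_per_group=4, seed=2), include_epochs=False)
        assert not a.clinical.equals(b.clinical)


class TestForwardModel:
    def test_null_model_has_no_regional_contrast(self):
        """surge_gain = 1 and cf_suppression_gain = 1: the temporal
        window mean is statistically indistinguishable from a distant
        baseline window across simulated subjects."""
        cfg = SimulationConfig(surge_gain=1.0, cf_suppression_gain=1.0,
                               n_epochs_per_session=10, artifact_rate=0.0, seed=5)
        deltas = []
        for s in range(16):
            es = simulate_subject_epochs(cfg, 0.0, "pre", _rng_for(cfg, 1, s, 0))
            pm = alpha_power_map(es, channel_names=TEMPORAL_REGION.channels)
            deltas.append(
                region_window_mean(pm, TEMPORAL_REGION, (-65, 127))
                - region_window_mean(pm, TEMPORAL_REGION, (-620, -400))
            )
        mean, se = np.mean(deltas), np.std(deltas, ddof=1) / np.sqrt(len(deltas))
        assert abs(mean) < max(3 * se, 0.35)

    def test_surge_recovery_monotone_in_gain(self):
        """Recovered temporal-window dB (relative to a pre-surge
        baseline window) increases with the planted surge gain."""
        means = {}
        for gain in (1.0, 1.5, 3.0):
            cfg = SimulationConfig(surge_gain=gain, n_epochs_per_session=10,
                                   temporal_surge_window_ms=(-200.0, 300.0),
                                   artifact_rate=0.0, seed=31)
            vals = []
            for s in range(6):
                es = simulate_subject_epochs(cfg, 0.0, "pre", _rng_for(cfg, 1, s, 0))
                pm = alpha_power_map(es, channel_names=TEMPORAL_REGION.channels)
                vals.append(
                    region_window_mean(pm, TEMPORAL_REGION, (-65, 127))
                    - region_window_mean(pm, TEMPORAL_REGION, (-620, -400))
                )
            means[gain] = np.mean(vals)
        assert means[1.0] < means[1.5] < means[3.0]
        assert means[3.0] > 5.0

    def test_cf_suppression_lowers_post_onset_alpha(self):
        from alphagate.montage import CENTRAL_FRONTAL_REGION

        means = {}
        for gain in (1.0, 0.5):
            cfg = SimulationConfig(cf_suppression_gain=gain, surge_gain=1.0,
                                   n_epochs_per_session=10, artifact_rate=0.0, seed=8)
            vals = []
            for s in range(6):
                es = simulate_subject_epochs(cfg, 0.0, "pre", _rng_for(cfg, 1, s, 0))
                pm = alpha_power_map(es, channel_names=CENTRAL_FRONTAL_REGION.channels)
                vals.append(
                    region_window_mean(pm, CENTRAL_FRONTAL_REGION, (100, 500))
                    - region_window_mean(pm, CENTRAL_FRONTAL_REGION, (-620, -300))
                )
            means[gain] = np.mean(vals)
        assert means[0.5] < means[1.0] - 1.0


class TestArtifacts:
    def test_rate_zero_is_identity(self, small_epochs):
        out, injected = inject_artifacts(small_epochs, 0.0, np.random.default_rng(0))
        assert injected == []
        np.testing.assert_array_equal(out.epochs, small_epochs.epochs)

    def test_rate_point3_contaminates_binomial_fraction(self):
        cfg = SimulationConfig(n_epochs_per_session=300, seed=2)
        es = simulate_subject_epochs(cfg, 0.0, "pre", _rng_for(cfg, 1, 0, 0),
                                     n_epochs=300)
        _, injected = inject_artifacts(es, 0.3, np.random.default_rng(4))
        # 90 +- 3 sigma binomial band
        assert 66 <= len(injected) <= 114

    def test_contamination_strictly_raises_frontal_ptp(self, small_epochs):
        dirty, injected = inject_artifacts(small_epochs, 0.5, np.random.default_rng(1))
        fp = [small_epochs.channel_names.index(c) for c in ("Fp1", "Fp2")]
        for ep in injected:
            before = np.ptp(small_epochs.epochs[ep][fp], axis=1).max()
            after = np.ptp(dirty.epochs[ep][fp], axis=1).max()
            assert after > before

    def test_blink_is_coherent_on_veog(self, small_epochs):
        dirty, injected = inject_artifacts(small_epochs, 0.5, np.random.default_rng(2))
        v = small_epochs.channel_names.index("VEOG")
        fp1 = small_epochs.channel_names.index("Fp1")
        for ep in injected:
            add_v = dirty.epochs[ep, v] - small_epochs.epochs[ep, v]
            add_f = dirty.epochs[ep, fp1] - small_epochs.epochs[ep, fp1]
            np.testing.assert_allclose(add_f, 0.6 * add_v, atol=1e-9)


class TestClinicalTable:
    def test_schema_and_ranges(self):
        cohort = simulate_cohort(SimulationConfig(n_per_group=6, seed=3),
                                 include_epochs=False)
        tab = cohort.clinical
        assert len(tab) == 2 * 18
        assert set(tab.timepoint) == {"pre", "post"}
        for o, (lo, hi) in INSTRUMENT_RANGES.items():
            assert tab[o].between(lo, hi).all()

    def test_anchored_to_published_group_statistics(self):
        """Large-n pre-scores match the published group means within
        sampling error plus the small clipping bias."""
        cohort = simulate_cohort(SimulationConfig(n_per_group=400, seed=9),
                                 include_epochs=False)
        pre = cohort.clinical[cohort.clinical.timepoint == "pre"]
        for outcome in ("sis_adl", "neadl", "wmft_strength"):
            for group in ("PMC", "M1", "Sham"):
                anchor_mean, anchor_sd, *_ = CLINICAL_ANCHORS[outcome][group]
                got = pre[pre.group == group][outcome].mean()
                tol = 3 * anchor_sd / np.sqrt(400) + 0.05 * anchor_sd
                assert abs(got - anchor_mean) < tol, (outcome, group)

    def test_group_mean_change_tracks_anchor_delta(self):
        cohort = simulate_cohort(SimulationConfig(n_per_group=400, seed=10),
                                 include_epochs=False)
        ch = change_scores(cohort.clinical, OUTCOMES)
        pmc = ch[ch.group == "PMC"]
        # low-clipping outcome: published delta +0.15
        assert pmc["wmft_strength"].mean() == pytest.approx(2.91 - 2.76, abs=0.06)

    def test_planted_correlation_visible_in_truth(self):
        cfg = SimulationConfig(n_per_group=60, seed=4,
                               planted_rho={"PMC": 0.6, "M1": 0.0, "Sham": 0.0})
        cohort = simulate_cohort(cfg, include_epochs=False)
        ch = change_scores(cohort.clinical, ["sis_adl"]).set_index("subject_id")
        pmc = [s for s in cohort.truth.subjects if cohort.truth.group_of[s] == "PMC"]
        z = np.array([cohort.truth.true_index_change_db[s] for s in pmc])
        w = ch.loc[pmc, "sis_adl"].to_numpy()
        r = np.corrcoef(z, w)[0, 1]
        assert 0.35 < r < 0.8

    def test_outlier_subjects_recorded_and_displaced(self):
        cfg = SimulationConfig(n_per_group=12, outlier_fraction=0.25, seed=6,
                               planted_rho={"PMC": 0.6, "M1": 0.6, "Sham": 0.6})
        cohort = simulate_cohort(cfg, include_epochs=False)
        assert len(cohort.truth.outlier_subjects) == 9  # 3 per group
        z_out = [abs(cohort.truth.latent_change[s])
                 for s in cohort.truth.outlier_subjects]
        z_in = [abs(cohort.truth.latent_change[s])
                for s in cohort.truth.subjects
                if s not in cohort.truth.outlier_subjects]
        assert np.mean(z_out) > np.mean(z_in)


class TestIndexChangeTable:
    def test_temporal_column_tracks_truth(self):
        cfg = SimulationConfig(n_per_group=12, seed=20)
        cohort = simulate_cohort(cfg, include_epochs=False)
        tab = index_change_table(cohort, np.random.default_rng(0),
                                 measurement_noise_db=0.0).set_index("subject_id")
        for s in cohort.truth.subjects:
            assert tab.loc[s, "temporal"] == pytest.approx(
                cohort.truth.true_index_change_db[s]
            )
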