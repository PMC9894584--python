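"""Synthetic cohort generator: HRF, generative models, determinism, SNR."""

import numpy as np
import pytest

from srmap import geometry, glm, hemo, sr_models, synth
from srmap.synth import (GroundTruth, cohort_starts, generative_row,
                         hippocampus_patterns, localizer_coactivation,
                         make_cohort, simulate_localizer, simulate_subject_full)


class TestCanonicalHrf:
    def test_zero_at_origin(self):
        assert hemo.canonical_hrf(0.0)[0] == 0.0
        assert hemo.canonical_hrf(0.0, "single")[0] == 0.0

    def test_peak_near_five_seconds(self):
        # dense-grid argmax oracle, both bases
        assert hemo.hrf_peak_time("double") == pytest.approx(5.0, abs=0.01)
        assert hemo.hrf_peak_time("single") == pytest.approx(5.0, abs=0.01)

    def test_unit_peak_normalization(self):
        t = np.arange(0, 30, 0.001)
        assert hemo.canonical_hrf(t).max() == pytest.approx(1.0, abs=1e-6)

    def test_convolution_linearity(self):
        sig1 = hemo.event_signal([3.0], [1.0], [0.0], 40.0)
        sig3 = hemo.event_signal([3.0], [3.0], [0.0], 40.0)
        assert np.allclose(sig3, 3.0 * sig1, atol=1e-12)


class TestGenerativeRow:
    def test_sr_row_discounts_successors_only(self):
        truth = GroundTruth(generative_model="SR", gamma=0.5)
        assert np.allclose(generative_row(truth, 1), [0.0, 1.0, 0.5, 0.25])

    def test_co_row_flat(self):
        truth = GroundTruth(generative_model="CO", omega=0.2)
        assert np.allclose(generative_row(truth, 2), [0.2, 0.2, 1.0, 0.2])

    def test_h0_row_stimulation_only(self):
        truth = GroundTruth(generative_model="H0")
        assert np.allclose(generative_row(truth, 0), [1.0, 0.0, 0.0, 0.0])

    def test_predecessor_suppression_representable(self):
        truth = GroundTruth(generative_model="SR", gamma=0.5,
                            predecessor_amplitude=-0.1)
        assert generative_row(truth, 2)[0] == -0.1


class TestValidation:
    @pytest.mark.parametrize("kwargs", [
        {"noise_sd": -1.0}, {"voxels_per_location": 0},
        {"generative_model": "XX"}, {"hippocampus_tuning": "radial"},
        {"stimulus_amplitude": np.inf},
    ])
    def test_invalid_truth(self, kwargs):
        with pytest.raises(ValueError):
            GroundTruth(**kwargs)


class TestSimulation:
    def test_same_seed_bit_identical(self, specs):
        truth = GroundTruth()
        a = simulate_subject_full(specs[0], truth, np.random.default_rng(5))
        b = simulate_subject_full(specs[0], truth, np.random.default_rng(5))
        assert np.array_equal(a.main["V1"].values, b.main["V1"].values)
        assert np.array_equal(a.localizer["hippocampus"].values,
                              b.localizer["hippocampus"].values)

    def test_noiseless_h0_gives_zero_omitted_betas(self, specs):
        truth = GroundTruth(generative_model="H0", noise_sd=0.0,
                            spatial_spread=0.0)
        sub = simulate_subject_full(specs[2], truth, np.random.default_rng(1),
                                    rois=("V1",))
        profile = glm.activity_profile(sub, use_true_labels=True)
        off = profile[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.0, atol=1e-9)
        assert np.allclose(np.diag(profile), 1.0, atol=1e-9)

    def test_noiseless_sr_gamma_recovered_end_to_end(self, specs):
        truth = GroundTruth(gamma=0.4, noise_sd=0.0, spatial_spread=0.0)
        sub = simulate_subject_full(specs[5], truth, np.random.default_rng(2),
                                    rois=("V1",))
        profile = glm.activity_profile(sub, use_true_labels=True)
        fit = sr_models.fit_model(profile, "SR")
        assert fit.params["gamma"] == pytest.approx(0.40, abs=0.005)

    def test_linearity_in_stimulus_amplitude(self, specs):
        base = GroundTruth(gamma=0.3, noise_sd=0.0)
        double = GroundTruth(gamma=0.3, noise_sd=0.0, stimulus_amplitude=2.0)
        p1 = glm.activity_profile(simulate_subject_full(
            specs[0], base, np.random.default_rng(3), rois=("V1",)),
            use_true_labels=True)
        p2 = glm.activity_profile(simulate_subject_full(
            specs[0], double, np.random.default_rng(3), rois=("V1",)),
            use_true_labels=True)
        assert np.allclose(p2, 2.0 * p1, atol=1e-9)


class TestLocalizerSimulation:
    def _noiseless_drive(self, tuning, spec, seed=4):
        """Recover per-location drive amplitudes from noiseless hippocampal
        localizer data by unmixing the known patterns after a GLM."""
        truth = GroundTruth(noise_sd=0.0, hippocampus_tuning=tuning,
                            pattern_amplitude=1.0)
        rng = np.random.default_rng(seed)
        layout = geometry.build_layout()
        schedule = geometry.build_localizer_schedule(layout, rng)
        patterns = hippocampus_patterns(truth, rng)
        data = simulate_localizer(truth, schedule, spec, rng,
                                  patterns=patterns, rois=("hippocampus",))
        ts = data["hippocampus"]
        X = glm.build_design_matrix(glm.localizer_events(schedule),
                                    ts.values.shape[1], tr=ts.tr)
        betas = glm.fit_glm(ts, X).betas  # condition x voxel
        drive, *_ = np.linalg.lstsq(patterns.T, betas.T, rcond=None)
        return drive.T  # condition x location amplitude

    def test_no_tuning_means_no_coactivation(self, specs):
        drive = self._noiseless_drive("none", specs[0])
        seq = specs[0].sequence_indices
        for s_pos, s_loc in enumerate(seq):
            row = drive[s_loc]
            for j_pos, j_loc in enumerate(seq):
                expected = 1.0 if j_pos == s_pos else 0.0
                assert row[j_loc] == pytest.approx(expected, abs=1e-6)

    def test_temporal_tuning_decreases_linearly_in_lag(self, specs):
        drive = self._noiseless_drive("temporal", specs[1])
        seq = specs[1].sequence_indices
        row = drive[seq[0]]
        lags = np.array([1, 2, 3])
        values = np.array([row[seq[j]] for j in (1, 2, 3)])
        assert np.allclose(values, 1.0 - 0.25 * lags, atol=1e-6)

    def test_spatial_tuning_orders_by_distance(self, specs, layout):
        drive = self._noiseless_drive("spatial", specs[3])
        seq = specs[3].sequence_indices
        # A-B at 14.0 dva coactivates less than A-C / A-D at 9.9 dva
        row = drive[seq[0]]
        assert row[seq[1]] < row[seq[2]]
        assert row[seq[1]] < row[seq[3]]

    def test_tuning_law_values(self, specs, layout):
        truth = GroundTruth(hippocampus_tuning="temporal")
        assert localizer_coactivation(truth, specs[0], layout, 1, 1) == 1.0
        assert localizer_coactivation(truth, specs[0], layout, 1, 2) == 0.75
        truth_none = GroundTruth(hippocampus_tuning="none")
        assert localizer_coactivation(truth_none, specs[0], layout, 0, 2) == 0.0


class TestCohort:
    def test_counterbalanced_starts(self):
        starts = cohort_starts(35, np.random.default_rng(0))
        counts = np.bincount(starts, minlength=8)
        assert set(counts.tolist()) <= {4, 5}
        starts8 = cohort_starts(8, np.random.default_rng(1))
        assert sorted(starts8.tolist()) == list(range(8))

    def test_same_seed_same_cohort(self):
        truth = GroundTruth()
        c1 = make_cohort(4, truth, 9, n_runs=1, rois=("V1",))
        c2 = make_cohort(4, truth, 9, n_runs=1, rois=("V1",))
        for a, b in zip(c1.subjects, c2.subjects):
            assert a.spec == b.spec
            assert np.array_equal(a.main["V1"].values, b.main["V1"].values)

    def test_rejects_single_subject(self):
        with pytest.raises(ValueError):
            make_cohort(1, GroundTruth(), 0)


class TestNoisePropagation:
    def test_beta_noise_matches_analytic_glm_propagation(self, specs):
        """Betas of pure-noise voxels must have the covariance OLS predicts:
        sd(beta_j) = sigma * sqrt((X'X)^-1_jj)."""
        truth = GroundTruth(stimulus_amplitude=0.0, noise_sd=1.0,
                            voxels_per_location=125)  # 1000 voxels
        sub = simulate_subject_full(specs[0], truth, np.random.default_rng(8),
                                    n_runs=1, rois=("V1",))
        ts = sub.main["V1"]
        X = glm.build_design_matrix(glm.main_task_events(sub.design.runs[0]),
                                    ts.values.shape[1], tr=ts.tr)
        fit = glm.fit_glm(ts, X)
        gram_inv = np.linalg.inv(X.values.T @ X.values)
        for j in range(len(X.names)):
            expected = np.sqrt(gram_inv[j, j])
            observed = fit.betas[j].std()
            assert observed == pytest.approx(expected, rel=0.10)


class TestFullPipelineModelRecovery:
    def test_generating_model_wins_bic_in_most_replicates(self):
        """simulate -> GLM -> fit recovers the generating model as the group
        BIC winner across seeded replicate cohorts at default SNR."""
        wins = {"SR": 0, "H0": 0}
        n_rep = 5
        for model in wins:
            for rep in range(n_rep):
                truth = GroundTruth(generative_model=model)
                cohort = make_cohort(8, truth, 500 + rep, rois=("V1",))
                profiles = [glm.activity_profile(s) for s in cohort.subjects]
                out = sr_models.model_comparison(profiles)
                wins[model] += out["winner"] == model
        assert wins["SR"] >= n_rep - 1
        assert wins["H0"] >= n_rep - 1
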