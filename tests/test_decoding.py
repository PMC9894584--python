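"""Preprocessing, the logistic decoder, evidence contrasts, HRF peak fit."""

import numpy as np
import pytest

from srmap import decoding, geometry, hemo
from srmap.decoding import (TrialSamples, evidence, evidence_contrast,
                            extract_trial_samples, fit_hrf_peak,
                            loo_cross_validate, preprocess, train_decoder)
from srmap.synth import GroundTruth, VoxelTimeSeries, simulate_subject_full


def _toy_samples(rng, n_per_class=8, n_voxels=16, separation=6.0, noise=1.0):
    """Well-separated 8-class samples: one mean direction per location."""
    means = separation * rng.standard_normal((8, n_voxels))
    feats, labels = [], []
    for c in range(8):
        feats.append(means[c] + noise * rng.standard_normal((n_per_class,
                                                             n_voxels)))
        labels.extend([c] * n_per_class)
    return TrialSamples(features=np.vstack(feats), labels=np.array(labels),
                        window=(3.0, 13.5))


class TestPreprocess:
    def test_z_scored_per_voxel_per_run(self, rng):
        ts = VoxelTimeSeries(values=rng.standard_normal((5, 60)) * 3 + 7,
                             tr=1.5, run_volumes=[30, 30], roi="hippocampus")
        ps = preprocess(ts)
        for sl in ps.run_slices():
            block = ps.values[:, sl]
            assert np.allclose(block.mean(axis=1), 0.0, atol=1e-6)
            assert np.allclose(block.std(axis=1), 1.0, atol=1e-6)

    def test_constant_voxel_zeroed_with_warning(self, rng):
        vals = rng.standard_normal((2, 40))
        vals[1] = 4.2
        ts = VoxelTimeSeries(values=vals, tr=1.5, run_volumes=[40],
                             roi="hippocampus")
        with pytest.warns(RuntimeWarning):
            ps = preprocess(ts)
        assert np.allclose(ps.values[1], 0.0)

    def test_run_shorter_than_window_rejected(self, rng):
        ts = VoxelTimeSeries(values=rng.standard_normal((1, 4)), tr=1.5,
                             run_volumes=[4], roi="hippocampus")
        with pytest.raises(ValueError):
            preprocess(ts)


class TestTrialSamples:
    def _series(self, rng, nvol=40):
        return decoding.PreprocessedSeries(
            values=rng.standard_normal((3, nvol)), tr=1.5, run_volumes=[nvol])

    def test_localizer_window_has_eight_volumes(self, rng):
        ps = self._series(rng)
        onset = 6.0  # on the volume grid
        s = extract_trial_samples(ps, [onset], [0], (3.0, 13.5))
        times = np.arange(40) * 1.5 - onset
        n_in = np.sum((times >= 3.0) & (times <= 13.5))
        assert n_in == 8
        expected = ps.values[:, (times >= 3.0) & (times <= 13.5)].mean(axis=1)
        assert np.allclose(s.features[0], expected)

    def test_main_task_window_has_three_volumes(self, rng):
        ps = self._series(rng)
        times = np.arange(40) * 1.5 - 9.0
        assert np.sum((times >= 3.0) & (times <= 6.0)) == 3

    def test_inclusive_zero_window(self, rng):
        ps = self._series(rng)
        s = extract_trial_samples(ps, [7.5], [0], (0.0, 0.0))
        assert np.allclose(s.features[0], ps.values[:, 5])

    def test_empty_window_rejected(self, rng):
        ps = self._series(rng)
        with pytest.raises(ValueError):
            extract_trial_samples(ps, [7.6], [0], (0.2, 0.4))


class TestDecoder:
    def test_separable_toy_trains_perfectly(self, rng):
        samples = _toy_samples(rng, noise=0.0)
        clf = train_decoder(samples)
        assert (clf.predict(samples.features) == samples.labels).all()

    def test_single_class_rejected(self, rng):
        bad = TrialSamples(features=rng.standard_normal((6, 4)),
                           labels=np.zeros(6, int), window=(3.0, 13.5))
        with pytest.raises(ValueError):
            train_decoder(bad)

    def test_duplicated_feature_column_keeps_predictions(self, rng):
        samples = _toy_samples(rng)
        clf1 = train_decoder(samples)
        doubled = TrialSamples(
            features=np.hstack([samples.features, samples.features[:, :1]]),
            labels=samples.labels, window=samples.window)
        clf2 = train_decoder(doubled)
        p1 = clf1.predict_proba(samples.features)
        p2 = clf2.predict_proba(doubled.features)
        assert np.allclose(p1, p2, atol=1e-3)

    def test_evidence_rows_sum_to_one(self, rng):
        samples = _toy_samples(rng)
        clf = train_decoder(samples)
        probs = evidence(clf, samples)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert probs.min() >= 0.0 and probs.max() <= 1.0

    def test_evidence_dimension_mismatch(self, rng):
        samples = _toy_samples(rng)
        clf = train_decoder(samples)
        bad = TrialSamples(features=samples.features[:, :-2],
                           labels=samples.labels, window=samples.window)
        with pytest.raises(ValueError):
            evidence(clf, bad)

    def test_loo_perfect_on_noiseless_separable_data(self, rng):
        assert loo_cross_validate(_toy_samples(rng, noise=0.0)) == 1.0

    def test_loo_at_chance_on_permuted_labels(self, rng):
        samples = _toy_samples(rng, noise=0.5)
        shuffled = TrialSamples(features=samples.features,
                                labels=rng.permutation(samples.labels),
                                window=samples.window)
        acc = loo_cross_validate(shuffled)
        # binomial 95% interval around 1/8 with 64 trials
        assert 0.125 - 1.96 * np.sqrt(0.125 * 0.875 / 64) - 1e-9 <= acc \
            <= 0.125 + 1.96 * np.sqrt(0.125 * 0.875 / 64) + 1e-9


class TestEvidenceContrast:
    def test_uniform_evidence_cancels(self, specs):
        probs = np.full((12, 8), 0.125)
        succ, pred = evidence_contrast(probs, np.tile([0, 1, 2, 3], 3),
                                       specs[0])
        assert succ == pytest.approx(0.0) and pred == pytest.approx(0.0)

    def test_evidence_on_next_successor(self, specs):
        # mass concentrated on the +1 successor, drawn from the other
        # sequence locations: successors rise above the control baseline,
        # predecessors fall below it
        spec = specs[0]
        probs = np.full((3, 8), 0.05)
        for row, s in zip(probs, [0, 1, 2]):
            for j in range(4):
                row[spec.sequence_indices[j]] = 0.02
            row[spec.sequence_indices[s + 1]] = 0.65
        succ, pred = evidence_contrast(probs, [0, 1, 2], spec)
        assert succ > 0 > pred


class TestTimeResolved:
    def test_transient_recovered_from_forward_skewed_cohort(self, specs):
        """A strongly forward-skewed hippocampus produces a positive
        successor-minus-predecessor transient that peaks near the HRF peak."""
        truth = GroundTruth(gamma=0.6, pattern_amplitude=0.3, noise_sd=0.5)
        curves = []
        for seed in range(4):
            sub = simulate_subject_full(specs[seed % 8], truth,
                                        np.random.default_rng(700 + seed),
                                        n_runs=2, rois=("hippocampus",))
            from srmap.pipeline import decode_subject
            r = decode_subject(sub, compute_accuracy=False)
            offsets, diff = decoding.time_resolved_evidence(
                r["model"], r["preprocessed_main"], sub.design, sub.spec)
            curves.append(diff)
        mean_curve = np.mean(curves, axis=0)
        assert offsets.size == 10
        assert np.allclose(offsets, np.arange(10) * 1.5)
        peak = fit_hrf_peak(offsets, mean_curve)
        assert peak is not None
        assert 3.0 <= peak <= 7.5
        assert mean_curve.max() > 0

    def test_offsets_grid(self, rng):
        ps = decoding.PreprocessedSeries(
            values=rng.standard_normal((4, 600)), tr=1.5, run_volumes=[600])
        offsets = np.arange(0.0, 13.5 + 1e-9, 1.5)
        assert offsets.size == 10


class TestHrfPeakFit:
    def test_recovers_canonical_peak(self):
        t = np.arange(0.0, 13.5 + 1e-9, 1.5)
        y = hemo.canonical_hrf(t)
        peak = fit_hrf_peak(t, y)
        assert peak == pytest.approx(hemo.hrf_peak_time("double"), abs=0.05)

    def test_shift_equivariance(self):
        t = np.arange(0.0, 13.5 + 1e-9, 1.5)
        y0 = hemo.canonical_hrf(t)
        y1 = hemo.canonical_hrf(np.clip(t - 1.0, 0, None))
        y1[t < 1.0] = 0.0
        assert fit_hrf_peak(t, y1) - fit_hrf_peak(t, y0) == pytest.approx(
            1.0, abs=0.05)

    def test_amplitude_scale_invariance(self):
        t = np.arange(0.0, 13.5 + 1e-9, 1.5)
        y = hemo.canonical_hrf(t)
        assert fit_hrf_peak(t, 5 * y) == pytest.approx(fit_hrf_peak(t, y),
                                                       abs=1e-6)

    def test_flat_input_means_no_transient(self):
        t = np.arange(0.0, 13.5 + 1e-9, 1.5)
        assert fit_hrf_peak(t, np.zeros_like(t)) is None

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_hrf_peak([0, 1.5, 3.0], [0, 1, 0])
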