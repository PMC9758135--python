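"""MVPA tests: extraction, normalization, FLD, cross-validation, permutations."""

import dataclasses

import numpy as np
import pytest

import preptemplate as pt
from preptemplate._exceptions import (InsufficientDataError, MappingError,
                                      ParameterError, ShapeError)
from preptemplate.containers import VoxelTimeSeries
from preptemplate.mvpa import (TrialPatternSet, _apply_znorm, _column_stats,
                               cross_decode, cv_loro, extract_trial_patterns,
                               fld_fit, fld_predict, group_permutation_test,
                               subject_permutation_null, znorm_patterns)
from preptemplate.pipeline import PipelineConfig, subject_patterns


def _toy_set(patterns, labels, run_ids=None, normalized=False,
             period="preparation"):
    patterns = np.asarray(patterns, float)
    if run_ids is None:
        run_ids = np.zeros(len(patterns), int)
    return TrialPatternSet(patterns=patterns, labels=np.asarray(labels),
                           run_ids=np.asarray(run_ids), period=period,
                           normalized=normalized)


def _gaussian_set(rng, n_per_class=30, n_vox=8, sep=0.0, n_runs=6):
    """Two-class Gaussian trial set with class-mean separation ``sep``."""
    n = 2 * n_per_class
    X = rng.standard_normal((n, n_vox))
    labels = np.array(["left", "right"]).repeat(n_per_class)
    X[labels == "left", 0] += sep
    runs = np.tile(np.arange(n_runs), int(np.ceil(n / n_runs)))[:n]
    order = rng.permutation(n)
    return _toy_set(X[order], labels[order], runs[order])


class TestExtraction:
    def test_single_trial_equals_hand_sliced_window_mean(self):
        d = pt.simulate_behavior(pt.make_attention_design(0, 10, seed=1), 1.0)
        data = np.random.default_rng(0).standard_normal((4, d.n_timepoints))
        ts = VoxelTimeSeries(data, tr=2.2, units="psc")
        tps = extract_trial_patterns(ts, d, "preparation", (2, 3))
        trial = [t for t in d.trials if t.delay >= 6.0 and t.correct][0]
        k = int(round(trial.onset / 2.2))
        np.testing.assert_allclose(tps.patterns[0], data[:, k + 2:k + 4].mean(1))

    def test_retention_counts_match_design(self):
        d = pt.simulate_behavior(pt.make_attention_design(0, 30, seed=2), 0.778,
                                 seed=3)
        data = np.zeros((2, d.n_timepoints))
        ts = VoxelTimeSeries(data, tr=2.2, units="psc")
        tps = extract_trial_patterns(ts, d, "preparation")
        expected = sum(t.delay >= 6.0 and t.correct for t in d.trials)
        assert tps.n_trials == expected

    def test_perfect_accuracy_retains_all_long_trials(self):
        d = pt.simulate_behavior(pt.make_attention_design(0, 30, seed=4), 1.0)
        ts = VoxelTimeSeries(np.zeros((2, d.n_timepoints)), tr=2.2, units="psc")
        tps = extract_trial_patterns(ts, d, "stimulus", long_delay_only=True)
        assert tps.n_trials == 24
        tps_all = extract_trial_patterns(ts, d, "stimulus", long_delay_only=False)
        assert tps_all.n_trials == 30

    def test_baseline_task_keeps_every_trial(self):
        d = pt.simulate_behavior(pt.make_baseline_design(0, 21, seed=5), 0.5, seed=6)
        ts = VoxelTimeSeries(np.zeros((2, d.n_timepoints)), tr=2.2, units="psc")
        assert extract_trial_patterns(ts, d, "baseline").n_trials == 21

    def test_period_task_consistency_enforced(self):
        d = pt.make_baseline_design(0, 11, seed=0)
        ts = VoxelTimeSeries(np.zeros((2, d.n_timepoints)), tr=2.2, units="psc")
        with pytest.raises(ParameterError):
            extract_trial_patterns(ts, d, "preparation")


class TestZnorm:
    def test_two_point_column(self):
        out = znorm_patterns(_toy_set([[1.0], [3.0]], ["left", "right"]))
        np.testing.assert_allclose(out.patterns, [[-1.0], [1.0]])

    def test_columns_standardized(self):
        rng = np.random.default_rng(0)
        out = znorm_patterns(_gaussian_set(rng))
        assert np.abs(out.patterns.mean(0)).max() < 1e-8
        np.testing.assert_allclose(out.patterns.std(0), 1.0, atol=1e-6)

    def test_idempotent_via_double_application(self):
        rng = np.random.default_rng(1)
        once = znorm_patterns(_gaussian_set(rng)).patterns
        twice = _apply_znorm(once, *_column_stats(once))
        np.testing.assert_allclose(once, twice, atol=1e-10)

    def test_constant_column_zeroed(self):
        out = znorm_patterns(_toy_set([[1.0, 5.0], [3.0, 5.0]], ["a", "b"]))
        np.testing.assert_allclose(out.patterns[:, 1], 0.0)


class TestFLD:
    def test_identity_covariance_closed_form(self):
        # residuals chosen so the pooled covariance is the identity
        base = np.array([[1.0, 0], [-1, 0], [0, 1], [0, -1]]) * np.sqrt(3 / 2)
        X = np.vstack([base, base + [2.0, 0.0]])
        labels = np.array(["a"] * 4 + ["b"] * 4)
        model = fld_fit(_toy_set(X, labels, normalized=True), lam=0.0)
        w, b = model.weights, model.bias
        assert w[1] == pytest.approx(0.0, abs=1e-12)
        # decision boundary at x1 = 1
        assert -b / w[0] == pytest.approx(1.0)

    def test_matches_hand_solved_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((8, 2))
        labels = np.array(["a", "b"] * 4)
        lam = 0.1
        model = fld_fit(_toy_set(X, labels, normalized=True), lam)
        # independent linear-solve oracle with explicit loops
        mu_a = X[labels == "a"].mean(0)
        mu_b = X[labels == "b"].mean(0)
        S = np.zeros((2, 2))
        for c, mu in (("a", mu_a), ("b", mu_b)):
            for row in X[labels == c]:
                S += np.outer(row - mu, row - mu)
        S /= 6
        S_lam = (1 - lam) * S + lam * np.trace(S) / 2 * np.eye(2)
        w = np.linalg.solve(S_lam, mu_b - mu_a)
        np.testing.assert_allclose(model.weights, w, atol=1e-10)
        assert model.bias == pytest.approx(-0.5 * w @ (mu_a + mu_b))
        assert model.class_order == ("a", "b")

    def test_identical_means_zero_weights(self):
        X = np.array([[1.0, 2], [3, 4], [1, 2], [3, 4]])
        model = fld_fit(_toy_set(X, ["a", "a", "b", "b"], normalized=True))
        np.testing.assert_allclose(model.weights, 0.0, atol=1e-12)

    def test_class_with_one_trial_rejected(self):
        with pytest.raises(InsufficientDataError):
            fld_fit(_toy_set([[1.0], [2], [3]], ["a", "a", "b"], normalized=True))

    def test_tie_predicts_negative_class(self):
        model = pt.FLDModel(weights=np.array([1.0]), bias=0.0, lam=0.0,
                            class_order=("neg", "pos"))
        assert fld_predict(model, np.array([[0.0]]))[0] == "neg"

    def test_separable_resubstitution_perfect(self):
        rng = np.random.default_rng(3)
        tps = znorm_patterns(_gaussian_set(rng, sep=8.0))
        model = fld_fit(tps)
        assert (fld_predict(model, tps.patterns) == tps.labels).all()

    def test_negating_model_flips_predictions(self):
        rng = np.random.default_rng(4)
        tps = znorm_patterns(_gaussian_set(rng, sep=1.0))
        model = fld_fit(tps)
        flipped = dataclasses.replace(model, weights=-model.weights,
                                      bias=-model.bias)
        a = fld_predict(model, tps.patterns)
        b = fld_predict(flipped, tps.patterns)
        assert (a != b).all()


class TestCvLoro:
    def test_six_runs_six_folds_each_trial_once(self):
        rng = np.random.default_rng(5)
        tps = _gaussian_set(rng, n_per_class=30, n_runs=6)
        res = cv_loro(tps)
        assert res.fold_accuracies.size == 6
        assert res.n_trials == tps.n_trials

    def test_null_data_near_chance(self):
        rng = np.random.default_rng(6)
        tps = _gaussian_set(rng, n_per_class=300, n_vox=6, sep=0.0)
        acc = cv_loro(tps).accuracy
        # binomial 99% band around 0.5 for 600 trials
        assert abs(acc - 0.5) < 2.58 * np.sqrt(0.25 / 600)

    def test_strong_separation_perfect(self):
        rng = np.random.default_rng(7)
        tps = _gaussian_set(rng, sep=10.0)
        assert cv_loro(tps).accuracy == 1.0

    def test_trial_order_permutation_invariance(self):
        rng = np.random.default_rng(8)
        tps = _gaussian_set(rng, sep=1.0)
        perm = rng.permutation(tps.n_trials)
        shuffled = _toy_set(tps.patterns[perm], tps.labels[perm],
                            tps.run_ids[perm])
        assert cv_loro(tps).accuracy == pytest.approx(cv_loro(shuffled).accuracy)

    def test_needs_two_runs(self):
        with pytest.raises(ParameterError):
            cv_loro(_toy_set([[1.0], [2]], ["a", "b"]))


class TestCrossDecode:
    def test_resubstitution_separable(self):
        rng = np.random.default_rng(9)
        tps = _gaussian_set(rng, sep=8.0)
        assert cross_decode(tps, tps).accuracy == 1.0

    def test_label_correspondence_applied(self):
        rng = np.random.default_rng(10)
        train = _gaussian_set(rng, sep=8.0)
        test = _toy_set(train.patterns,
                        np.char.add("attend_", train.labels.astype(str)),
                        train.run_ids)
        assert cross_decode(train, test).accuracy == 1.0

    def test_missing_correspondence_raises(self):
        rng = np.random.default_rng(11)
        train = _gaussian_set(rng, sep=2.0)
        test = _toy_set(train.patterns,
                        np.where(train.labels == "left", "up", "down"),
                        train.run_ids)
        with pytest.raises(MappingError):
            cross_decode(train, test)

    def test_voxel_mismatch_raises(self):
        rng = np.random.default_rng(12)
        train = _gaussian_set(rng)
        test = train.select_voxels(np.arange(3))
        with pytest.raises(ShapeError):
            cross_decode(train, test)


class TestGenerativeCrossTask:
    """Axis-overlap ground truth propagates to cross-task decodability."""

    def _subject(self, overlap):
        cfg = PipelineConfig(
            cohort=pt.CohortSpec(n_subjects=1, n_voxels=20, seed=21,
                                 behavioral_accuracy=1.0,
                                 n_baseline_trials=31),
            overlap=overlap, noise_sd=0.05,
            pattern_amplitude_prep=0.5, pattern_amplitude_stim=0.5)
        subj = pt.generate_cohort(cfg.cohort, overlap, **cfg.truth_kwargs())[0]
        return subject_patterns(subj, cfg)

    def test_orthogonal_axes_do_not_generalize_to_preparation(self):
        sp = self._subject(0.0)
        acc = cross_decode(sp.base, sp.prep).accuracy
        assert 0.3 < acc < 0.7

    def test_aligned_axes_generalize(self):
        # the 0.01 Hz high-pass removes part of the slow condition-difference
        # BOLD signal, so preparation-period generalization is clearly above
        # chance but not at ceiling even at near-zero noise
        sp = self._subject(1.0)
        assert cross_decode(sp.base, sp.prep).accuracy > 0.58
        assert cross_decode(sp.base, sp.stim).accuracy > 0.9


class TestPermutations:
    def test_null_vector_shape_and_determinism(self):
        rng = np.random.default_rng(13)
        tps = _gaussian_set(rng, n_per_class=12, n_runs=3)
        a = subject_permutation_null(tps, scheme="loro", n_perm=20, seed=42)
        b = subject_permutation_null(tps, scheme="loro", n_perm=20, seed=42)
        assert a.shape == (20,)
        np.testing.assert_array_equal(a, b)

    def test_null_mean_near_chance(self):
        rng = np.random.default_rng(14)
        tps = _gaussian_set(rng, n_per_class=60, n_vox=4, n_runs=4, sep=3.0)
        null = subject_permutation_null(tps, scheme="loro", n_perm=200, seed=0)
        assert abs(null.mean() - 0.5) < 0.02

    def test_group_p_bounds(self):
        nulls = np.full((3, 10), 0.5)
        low = group_permutation_test([0.1, 0.1, 0.1], nulls)
        high = group_permutation_test([0.9, 0.9, 0.9], nulls)
        assert low.p_value == pytest.approx(1.0)
        assert high.p_value == pytest.approx(1 / 11)

    def test_group_matches_enumeration_oracle(self):
        rng = np.random.default_rng(15)
        observed = rng.uniform(0.4, 0.8, 3)
        nulls = rng.uniform(0.3, 0.7, (3, 10))
        res = group_permutation_test(observed, nulls)
        # brute-force enumeration oracle
        group_null = np.array([np.mean([nulls[s][i] for s in range(3)])
                               for i in range(10)])
        obs = float(np.mean(observed))
        exceed = sum(1 for v in group_null if v >= obs)
        assert res.p_value == pytest.approx((1 + exceed) / 11)
        assert res.threshold_95 == pytest.approx(sorted(group_null)[int(np.ceil(9.5)) - 1])
        np.testing.assert_allclose(res.null, group_null)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ShapeError):
            group_permutation_test([0.5, 0.5], np.zeros((3, 10)))
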