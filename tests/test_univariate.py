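"""Univariate tests: time courses, window amplitudes, BSI, quadrant contrast."""

import numpy as np
import pytest

import preptemplate as pt
from preptemplate._exceptions import (DegenerateGroupingError,
                                      EmptySelectionError, ParameterError,
                                      UndefinedBSIError, WindowError)
from preptemplate.deconvolve import DeconvolutionFit, attention_fir_spec
from preptemplate.mvpa import TrialPatternSet
from preptemplate.pipeline import PipelineConfig, subject_patterns
from preptemplate.univariate import (WindowSpec, compute_bsi,
                                     condition_timecourse, quadrant_contrast,
                                     stimulus_bin_offset, window_amplitude)


def _fit_from_betas(betas):
    return DeconvolutionFit(betas=betas, fitted=np.zeros((1, 1)))


class TestConditionTimecourse:
    def test_single_voxel_single_label_passthrough(self):
        b = np.arange(12.0)[:, None]
        fit = _fit_from_betas({"a": b})
        np.testing.assert_allclose(condition_timecourse(fit, ["a"]), b[:, 0])

    def test_opposite_voxels_cancel(self):
        b = np.random.default_rng(0).standard_normal(12)
        fit = _fit_from_betas({"a": np.column_stack([b, -b])})
        np.testing.assert_allclose(condition_timecourse(fit, ["a"]), 0.0,
                                   atol=1e-12)

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(1)
        betas = {lab: rng.standard_normal((6, 5)) for lab in ("a", "b", "c")}
        fit = _fit_from_betas(betas)
        voxels = [0, 2, 4]
        got = condition_timecourse(fit, ["a", "c"], voxels)
        expected = np.zeros(6)
        for bin_ in range(6):                       # independent loop oracle
            vals = [betas[lab][bin_, v] for lab in ("a", "c") for v in voxels]
            expected[bin_] = np.mean([np.mean([betas[lab][bin_, v] for v in voxels])
                                      for lab in ("a", "c")])
        np.testing.assert_allclose(got, expected)

    def test_empty_voxel_selection_raises(self):
        fit = _fit_from_betas({"a": np.ones((4, 2))})
        with pytest.raises(EmptySelectionError):
            condition_timecourse(fit, ["a"], [])


class TestWindowAmplitude:
    def test_arithmetic_example(self):
        tc = [0.0, 0.0, 4.0, 6.0, 0.0]
        assert window_amplitude(tc, WindowSpec("trial_onset", 2, 3)) == 5.0

    def test_single_bin_window(self):
        assert window_amplitude([1.0, 7.0, 3.0], WindowSpec("trial_onset", 1, 1)) == 7.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_slice_mean_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tc = rng.standard_normal(12)
        s, e = sorted(rng.integers(0, 12, 2))
        win = WindowSpec("trial_onset", int(s), int(e))
        assert window_amplitude(tc, win) == pytest.approx(np.mean(tc[s:e + 1]))

    def test_linearity(self):
        rng = np.random.default_rng(9)
        a, b = rng.standard_normal(10), rng.standard_normal(10)
        win = WindowSpec("trial_onset", 2, 5)
        assert window_amplitude(2 * a + 3 * b, win) == pytest.approx(
            2 * window_amplitude(a, win) + 3 * window_amplitude(b, win))

    def test_out_of_range_raises(self):
        with pytest.raises(WindowError):
            window_amplitude([1.0, 2.0], WindowSpec("trial_onset", 1, 5))


def _bsi_fit(prep_level, stim_level, n_bins=12):
    """Betas with a flat preparatory level and a bump at the stimulus bins."""
    betas = {}
    for cond in ("attend_left", "attend_right"):
        for d in (6.1, 8.3):
            tc = np.zeros(n_bins)
            tc[1:4] = prep_level
            k = stimulus_bin_offset(d, 2.2)
            tc[k + 1:k + 4] = stim_level
            betas[f"{cond}_{d}"] = tc[:, None]
    return _fit_from_betas(betas)


class TestBSI:
    def test_stimulus_bin_offsets(self):
        assert stimulus_bin_offset(6.1, 2.2) == 3
        assert stimulus_bin_offset(8.3, 2.2) == 4

    def test_equal_peaks_give_unity(self):
        res = compute_bsi(_bsi_fit(0.7, 0.7), 2.2)
        assert res.value == pytest.approx(1.0)

    def test_ratio_recovered_from_constructed_betas(self):
        res = compute_bsi(_bsi_fit(0.3, 1.0), 2.2)
        assert res.value == pytest.approx(0.3)

    def test_scale_invariance(self):
        a = compute_bsi(_bsi_fit(0.25, 0.9), 2.2)
        fit = _bsi_fit(0.25, 0.9)
        for lab in fit.betas:
            fit.betas[lab] = fit.betas[lab] * 7.3
        b = compute_bsi(fit, 2.2)
        assert a.value == pytest.approx(b.value)

    def test_nonpositive_stimulus_peak_raises(self):
        with pytest.raises(UndefinedBSIError):
            compute_bsi(_bsi_fit(0.2, -0.5), 2.2)

    def test_zero_preparatory_truth_gives_near_zero_bsi(self, noiseless_cfg):
        cfg = PipelineConfig(cohort=noiseless_cfg.cohort, overlap=0.0,
                             noise_sd=0.0, mean_amplitude_prep=0.0,
                             pattern_amplitude_prep=0.0)
        subj = pt.generate_cohort(cfg.cohort, 0.0, **cfg.truth_kwargs())[0]
        sp = subject_patterns(subj, cfg)
        res = compute_bsi(sp.att_fit, sp.tr)
        # FIR truncation leaves a small residue; no preparatory signal
        assert abs(res.value) < 0.03

    def test_generative_recovery_within_documented_bias_bound(
            self, noiseless_patterns):
        # sustained preparation, amplitude ratio 0.3: the convolution oracle
        # puts the recovered BSI at ~0.19 (the preparatory response peaks
        # after stimulus onset, and its leak inflates the stimulus peak)
        res = compute_bsi(noiseless_patterns.att_fit, noiseless_patterns.tr)
        assert res.value == pytest.approx(0.19, abs=0.03)
        assert abs(res.value - 0.3) < 0.12    # documented HRF-overlap bound

    def test_transient_preparation_recovers_ratio_closely(self, noiseless_cfg):
        cfg = PipelineConfig(cohort=noiseless_cfg.cohort, overlap=0.0,
                             noise_sd=0.0, prep_sustained=False)
        subj = pt.generate_cohort(cfg.cohort, 0.0, **cfg.truth_kwargs())[0]
        sp = subject_patterns(subj, cfg)
        res = compute_bsi(sp.att_fit, sp.tr)
        assert abs(res.value - 0.3) < 0.05


def _pattern_set(patterns, labels):
    return TrialPatternSet(patterns=np.asarray(patterns, float),
                           labels=np.asarray(labels),
                           run_ids=np.zeros(len(labels), int),
                           period="preparation")


class TestQuadrantContrast:
    QMAP8 = np.array(["UL", "UR", "LL", "LR"] * 2)

    def _uniform_subjects(self, rng, n_subj=4, offset=0.0):
        sets, qmaps = [], []
        for _ in range(n_subj):
            base = rng.standard_normal((6, 1)) + np.zeros((6, 8))
            labels = ["attend_left", "attend_right"] * 3
            sets.append(_pattern_set(base, labels))
            qmaps.append(self.QMAP8)
        return sets, qmaps

    def test_spatially_uniform_signal_null(self, rng):
        sets, qmaps = self._uniform_subjects(rng)
        res = quadrant_contrast(sets, qmaps, "upper_two")
        np.testing.assert_allclose(res.attended_means, res.unattended_means,
                                   atol=1e-12)

    def test_injected_bias_detected_in_noiseless_cohort(self):
        spec = pt.CohortSpec(n_subjects=12, n_voxels=16, seed=31,
                             n_attention_runs=2, behavioral_accuracy=1.0,
                             n_baseline_trials=4)
        cfg = PipelineConfig(cohort=spec, overlap=0.0, noise_sd=0.0,
                             quadrant_bias=0.5)
        cohort = pt.generate_cohort(spec, 0.0, **cfg.truth_kwargs())
        sets, qmaps = [], []
        for subj in cohort:
            sp = subject_patterns(subj, cfg)
            sets.append(sp.prep_full)
            qmaps.append(subj.truth.quadrant_map[sp.kept])
        res = quadrant_contrast(sets, qmaps, "upper_two")
        assert (res.attended_means - res.unattended_means).mean() > 0.1
        assert res.ttest.p < 0.05

    def test_label_swap_flips_contrast_sign(self, rng):
        patterns = rng.standard_normal((8, 8))
        labels = np.array(["attend_left", "attend_right"] * 4)
        swapped = np.where(labels == "attend_left", "attend_right", "attend_left")
        sets = [_pattern_set(patterns, labels), _pattern_set(patterns + 1, labels)]
        sets_sw = [_pattern_set(patterns, swapped), _pattern_set(patterns + 1, swapped)]
        qmaps = [self.QMAP8, self.QMAP8]
        a = quadrant_contrast(sets, qmaps, "upper_two")
        b = quadrant_contrast(sets_sw, qmaps, "upper_two")
        np.testing.assert_allclose(a.attended_means - a.unattended_means,
                                   -(b.attended_means - b.unattended_means))

    def test_type_i_error_calibrated_under_null(self):
        # 200 null cohorts of 6 subjects; rejection rate at alpha=.05 should
        # sit inside the binomial 99% band
        rng = np.random.default_rng(77)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            sets, qmaps = [], []
            for _s in range(6):
                patterns = rng.standard_normal((10, 8))
                labels = ["attend_left", "attend_right"] * 5
                sets.append(_pattern_set(patterns, labels))
                qmaps.append(self.QMAP8)
            res = quadrant_contrast(sets, qmaps, "diagonal_four")
            rejections += res.ttest.p < 0.05
        band = 2.58 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rejections / n_rep - 0.05) < band

    def test_empty_quadrant_raises(self):
        qmap = np.array(["UL"] * 8)
        sets = [_pattern_set(np.zeros((2, 8)), ["attend_left", "attend_right"])]
        with pytest.raises(DegenerateGroupingError):
            quadrant_contrast(sets, [qmap], "upper_two")

    def test_unknown_hypothesis_rejected(self):
        with pytest.raises(ParameterError):
            quadrant_contrast([], [], "sideways")
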