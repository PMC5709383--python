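"""ROI extraction, epoching, per-timepoint regression, and peak selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import gaussian_filter1d

from vmchoice import bold_sim as bs
from vmchoice import timecourse as tc


def smooth_null_courses(rng, n_sessions=6, n_points=65, sigma=4.0):
    """Null beta time courses with HRF-scale temporal smoothness."""
    return gaussian_filter1d(rng.standard_normal((n_sessions, n_points)), sigma, axis=1)


class TestRoiMask:
    def test_radius_zero_is_center_voxel(self, rng):
        grid = rng.standard_normal((5, 5, 5, 20))
        series = tc.extract_roi(grid, tc.RoiMask(center=(2, 2, 2), radius=0))
        np.testing.assert_array_equal(series.values, grid[2, 2, 2])

    def test_radius_two_sphere_has_33_voxels(self):
        mask = tc.RoiMask(center=(5, 5, 5), radius=2)
        assert len(mask.voxels((11, 11, 11))) == 33

    def test_uniform_field_mean_equals_any_voxel(self):
        grid = np.ones((7, 7, 7, 10)) * np.arange(10)
        series = tc.extract_roi(grid, tc.RoiMask(center=(3, 3, 3), radius=2))
        np.testing.assert_allclose(series.values, grid[0, 0, 0])

    def test_out_of_grid_mask_raises(self):
        with pytest.raises(tc.MaskError):
            tc.extract_roi(np.zeros((3, 3, 3, 5)), tc.RoiMask(center=(10, 10, 10)))


class TestEpochUpsample:
    def test_linear_ramp_interpolated_exactly(self):
        series = bs.BoldSeries(values=2.0 * np.arange(100), tr=2.28)
        epochs = tc.epoch_upsample(series, [60.0, 100.0], window=(-2, 14), step=0.25)
        for i, ev in enumerate([60.0, 100.0]):
            expected = 2.0 * (ev + epochs.times) / 2.28
            np.testing.assert_allclose(epochs.data[i], expected, atol=1e-10)

    def test_hrf_shaped_series_reconstructed(self):
        # series that is exactly the HRF response at each event
        onsets = np.array([30.0, 80.0, 130.0])  # TR-aligned: identical sampling
        series = bs.convolve_events(onsets, 1.0, tr=2.0, n_volumes=90)
        epochs = tc.epoch_upsample(series, onsets, window=(-2, 14), step=0.25)
        for row in epochs.data[1:]:
            np.testing.assert_allclose(row, epochs.data[0], atol=1e-6)

    def test_edge_events_dropped_with_warning(self):
        series = bs.BoldSeries(values=np.zeros(50), tr=2.0)
        with pytest.warns(UserWarning, match="dropped"):
            epochs = tc.epoch_upsample(series, [1.0, 50.0, 99.5], window=(-2, 14))
        assert epochs.dropped == [0, 2]
        assert epochs.n_trials == 1

    def test_jittered_events_recover_hrf_peak_time(self, rng):
        # event onsets jittered against the TR grid; the mean epoch should
        # peak within one upsample step of the HRF peak
        onsets = np.cumsum(rng.uniform(12, 16, 60)) + 5
        series = bs.convolve_events(onsets, 1.0, tr=2.28)
        epochs = tc.epoch_upsample(series, onsets, window=(-2, 10), step=0.25)
        kernel = bs.gamma_hrf(bs.HRFParams())
        hrf_peak = (np.argmax(kernel) + 0.5) * 0.1
        mean_peak = epochs.times[np.argmax(epochs.data.mean(axis=0))]
        assert abs(mean_peak - hrf_peak) <= 0.25 + 0.1

    def test_baseline_subtraction(self):
        series = bs.BoldSeries(values=np.ones(50) * 5.0, tr=2.0)
        epochs = tc.epoch_upsample(series, [40.0], baseline=(-2.0, 0.0))
        np.testing.assert_allclose(epochs.data, 0.0, atol=1e-12)

    def test_epoch_then_average_commutes_with_average_then_epoch(self):
        rng = np.random.default_rng(4)
        sessions = [bs.BoldSeries(values=rng.standard_normal(100), tr=2.0)
                    for _ in range(3)]
        events = [20.0, 60.0, 120.0]
        mean_series = bs.BoldSeries(
            values=np.mean([s.values for s in sessions], axis=0), tr=2.0)
        a = np.mean([tc.epoch_upsample(s, events).data for s in sessions], axis=0)
        b = tc.epoch_upsample(mean_series, events).data
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestTimepointRegression:
    def test_planted_negative_diff_peaks_near_hrf_peak(self, rng):
        n = 80
        onsets = np.cumsum(rng.uniform(11, 14, n)) + 5
        diff_z = rng.standard_normal(n)
        diff_z = (diff_z - diff_z.mean()) / diff_z.std()
        bold = bs.generate_linear_roi(onsets, diff_z, np.zeros(n),
                                      betas=bs.LinearBetas(decision=1.0, diff=-1.0,
                                                           sum=0, outcome=0),
                                      noise_model=bs.NoiseModel(white_sd=0.003,
                                                                ar_sd=0, drift_amp=0),
                                      rng=rng)
        epochs = tc.epoch_upsample(bold, onsets, window=(-2, 10))
        X = pd.DataFrame({"diff_z": diff_z[epochs.trial_index]})
        tb = tc.timepoint_regression(epochs, X)
        course = tb.series("diff_z")
        peak_time = epochs.times[np.argmin(course)]
        assert course.min() < 0
        assert 1.5 <= peak_time <= 4.5  # near the 2.25 s HRF mode / 3 s mean

    def test_permuted_labels_null_centered(self, rng):
        n = 60
        onsets = np.cumsum(rng.uniform(11, 14, n)) + 5
        diff_z = rng.standard_normal(n)
        bold = bs.generate_linear_roi(onsets, diff_z, np.zeros(n),
                                      betas=bs.LinearBetas(decision=1.0, diff=-1.0,
                                                           sum=0, outcome=0))
        epochs = tc.epoch_upsample(bold, onsets, window=(0, 6))
        peak_col = np.argmax(np.abs(
            tc.timepoint_regression(epochs, pd.DataFrame(
                {"diff_z": diff_z[epochs.trial_index]})).series("diff_z")))
        signs = []
        for _ in range(500):
            perm = rng.permutation(diff_z[epochs.trial_index])
            tb = tc.timepoint_regression(epochs, pd.DataFrame({"diff_z": perm}))
            signs.append(np.sign(tb.series("diff_z")[peak_col]))
        # sign test: permuted betas symmetric around zero
        pos = np.sum(np.array(signs) > 0)
        from scipy import stats
        assert stats.binomtest(int(pos), 500, 0.5).pvalue > 0.01

    def test_joint_recovery_with_correlated_rt_regressor(self, rng):
        n = 120
        onsets = np.cumsum(rng.uniform(11, 13, n)) + 5
        diff_z = rng.standard_normal(n)
        rt = 0.5 * diff_z + np.sqrt(1 - 0.25) * rng.standard_normal(n)  # r ~ 0.5
        amp = 1.0 - 0.8 * diff_z + 0.4 * rt
        bold = bs.convolve_events(onsets, amp, tr=2.28)
        bold.values += rng.normal(0, 0.002, bold.n_volumes)
        epochs = tc.epoch_upsample(bold, onsets, window=(0, 6))
        X = pd.DataFrame({"diff_z": diff_z[epochs.trial_index],
                          "rt": rt[epochs.trial_index]})
        tb = tc.timepoint_regression(epochs, X)
        k = np.argmax(np.abs(tb.series("diff_z")))
        beta = tb.series("diff_z")[k]
        se = tb.ses[k, tb.names.index("diff_z")]
        assert beta < 0 and abs(beta) > 2 * se

    def test_too_few_trials_raises(self):
        epochs = tc.EpochedTimecourse(data=np.zeros((2, 5)), times=np.arange(5.0),
                                      trial_index=np.arange(2), dropped=[])
        with pytest.raises(ValueError, match="fewer trials"):
            tc.timepoint_regression(epochs, pd.DataFrame({"a": [1, 2], "b": [3, 4]}))


class TestPeakSelection:
    def test_identical_sessions_select_same_timepoint(self):
        course = np.sin(np.linspace(0, np.pi, 30))
        courses = np.tile(course, (4, 1))
        res = tc.loo_peak_stat(courses, mode="max", permutation=False)
        assert len(set(res.indices)) == 1

    def test_requires_three_sessions(self):
        with pytest.raises(ValueError):
            tc.loo_peak_stat(np.zeros((2, 10)))

    def test_loo_less_anticonservative_than_insample_and_permutation_nominal(self):
        # under a smooth-noise null: naive t on LOO values is inflated but
        # below the circular in-sample rate; the sign-flip permutation p is
        # nominal (scientific core of the selection-bias control)
        rng = np.random.default_rng(314)
        n_sims = 400
        rej_loo_naive = rej_loo_perm = rej_insample = 0
        for _ in range(n_sims):
            courses = smooth_null_courses(rng, n_sessions=8)
            res = tc.loo_peak_stat(courses, mode="abs")
            rej_loo_naive += res.p < 0.05
            rej_loo_perm += res.perm_p < 0.05
            rej_insample += tc.insample_peak_stat(courses, mode="abs").p < 0.05
        assert rej_insample > rej_loo_naive > 0
        assert rej_insample / n_sims > 0.08
        assert abs(rej_loo_perm / n_sims - 0.05) < 0.025

    def test_loo_estimate_unbiased_while_insample_inflated(self):
        # LOO held-out values have mean ~0 under the null; in-sample |values|
        # at the selected peak are biased away from zero
        rng = np.random.default_rng(271)
        loo_means, ins_abs, all_abs = [], [], []
        for _ in range(400):
            courses = smooth_null_courses(rng)
            loo_means.append(tc.loo_peak_stat(courses, mode="abs",
                                              permutation=False).values.mean())
            ins_abs.append(np.abs(tc.insample_peak_stat(courses, "abs").values.mean()))
            all_abs.append(np.abs(courses.mean()))
        assert abs(np.mean(loo_means)) < 0.05
        assert np.mean(ins_abs) > 3 * np.mean(all_abs)

    def test_planted_negative_effect_detected(self, rng):
        t = np.linspace(-2, 14, 65)
        bump = -0.8 * np.exp(-0.5 * ((t - 3.0) / 1.5) ** 2)
        courses = bump + smooth_null_courses(rng) * 0.3
        res = tc.loo_peak_stat(courses, mode="abs")
        assert res.t < 0 and res.perm_p < 0.05

    def test_spatial_variant_same_fold_logic(self, rng):
        # flattened per-session voxel maps run through the same selector
        maps = rng.standard_normal((5, 27))
        maps[:, 13] += 3.0  # consistent spatial peak
        res = tc.loo_peak_stat(maps, mode="max", permutation=False)
        assert set(res.indices) == {13}


class TestTrialPeaks:
    def test_single_sample_window(self):
        epochs = tc.EpochedTimecourse(data=np.arange(12.0).reshape(3, 4),
                                      times=np.array([0.0, 2.0, 4.0, 6.0]),
                                      trial_index=np.arange(3), dropped=[])
        peaks = tc.trial_peaks(epochs, window=(2.0, 2.0))
        np.testing.assert_array_equal(peaks, epochs.data[:, 1])

    def test_window_outside_epoch_raises(self):
        epochs = tc.EpochedTimecourse(data=np.zeros((3, 4)),
                                      times=np.array([0.0, 1.0, 2.0, 3.0]),
                                      trial_index=np.arange(3), dropped=[])
        with pytest.raises(ValueError):
            tc.trial_peaks(epochs, window=(10.0, 12.0))

    def test_cell_ordering_matches_planted_effects(self, rng):
        # negative chosen-value and positive unchosen-value amplitudes:
        # among HV-chosen trials, the HV-vs-CV cell peaks highest
        values = {"HV": 0.9, "CV": 0.75, "LV": 0.6, "UNREW": 0.1}
        chosen = rng.choice(["HV", "CV"], 120)
        unchosen_pool = {"HV": ["CV", "LV", "UNREW"], "CV": ["LV", "UNREW"]}
        unchosen = np.array([rng.choice(unchosen_pool[c]) for c in chosen])
        amp = np.array([1.0 - 1.5 * values[c] + 1.5 * values[u]
                        for c, u in zip(chosen, unchosen)])
        onsets = np.cumsum(rng.uniform(11, 13, 120)) + 5
        bold = bs.convolve_events(onsets, amp, tr=2.28)
        epochs = tc.epoch_upsample(bold, onsets, window=(-2, 8))
        labels = pd.DataFrame({"chosen": chosen[epochs.trial_index],
                               "unchosen": unchosen[epochs.trial_index]})
        cells = tc.trial_peak_analysis(epochs, labels)
        hv = cells[cells["chosen"] == "HV"].set_index("unchosen")["mean"]
        assert hv["CV"] > hv["LV"] > hv["UNREW"]
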