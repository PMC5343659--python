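import numpy as np
import pytest
from scipy import stats

from optotherm.synth import CalibrationSeries, CameraModel, render_thermal_movie
from optotherm.thermal import (
    compare_frequencies,
    delta_maps,
    fit_calibration,
    fit_dose_model,
    hottest_roi,
    max_delta_t,
    roi_timecourse,
)


def make_series(grey, temp):
    return CalibrationSeries(
        times_s=np.arange(len(grey), dtype=float),
        grey_levels=np.asarray(grey, dtype=float),
        reference_temperatures_c=np.asarray(temp, dtype=float),
    )


class TestFitCalibration:
    def test_identity(self):
        s = make_series([40.0, 30.0, 20.0], [40.0, 30.0, 20.0])
        fit = fit_calibration(s)
        assert fit.slope_c_per_grey == pytest.approx(1.0)
        assert fit.intercept_c == pytest.approx(0.0, abs=1e-12)

    def test_recovers_camera_gain_and_offset(self):
        """grey = 2·T + 100 inverts to T = 0.5·grey − 50."""
        temp = np.linspace(60, 40, 50)
        s = make_series(2.0 * temp + 100.0, temp)
        fit = fit_calibration(s)
        assert fit.slope_c_per_grey == pytest.approx(0.5, abs=1e-3)
        assert fit.intercept_c == pytest.approx(-50.0, abs=1e-3)
        assert fit.residual_rms_c < 1e-9

    def test_two_points_interpolate_exactly(self):
        s = make_series([100.0, 200.0], [30.0, 20.0])
        fit = fit_calibration(s)
        assert fit.apply(np.array([150.0]))[0] == pytest.approx(25.0)

    def test_constant_grey_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            fit_calibration(make_series([5.0, 5.0, 5.0], [30.0, 29.0, 28.0]))


class TestDeltaMaps:
    def test_constant_movie_gives_zero(self):
        movie = np.full((30, 4, 4), 29.0)
        times = np.arange(30) / 3.0 - 5.0
        assert np.allclose(delta_maps(movie, times, 5.0), 0.0)

    def test_step_change_recovered(self):
        times = np.arange(60) / 3.0 - 10.0
        movie = np.where(times[:, None, None] >= 0, 30.0, 29.0) * np.ones((60, 3, 3))
        d = delta_maps(movie, times)
        assert np.allclose(d[times >= 0], 1.0)
        assert np.allclose(d[times < 0], 0.0)

    def test_round_trip_through_camera(self):
        """Rendered movie → ΔT maps recovers ground truth within noise."""
        cam = CameraModel(noise_sd_c=0.08)
        times = np.arange(90) / 3.0 - 10.0
        true = np.where(times[:, None, None] >= 0, 0.5, 0.0) * np.ones((90, 20, 20))
        rec = render_thermal_movie(true, cam, times_s=times, seed=5)
        movie_c = cam.to_temperature(rec.grey)
        d = delta_maps(movie_c, times)
        # per-pixel noise 0.08 °C; frame-mean error ~ 0.08/sqrt(400)
        assert d[times >= 0].mean() == pytest.approx(0.5, abs=0.01)

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            delta_maps(np.zeros((5, 2, 2)), np.arange(5.0), 10.0)


class TestHottestRoi:
    def test_centered_on_hot_spot(self):
        stack = np.zeros((3, 40, 40))
        stack[1, 25, 11] = 5.0
        mask = hottest_roi(stack, pixel_pitch_mm=0.05)
        rr, cc = np.nonzero(mask)
        assert round(rr.mean()) == 25 and round(cc.mean()) == 11

    def test_area_is_one_square_millimeter(self):
        stack = np.zeros((1, 80, 80))
        stack[0, 40, 40] = 1.0
        mask = hottest_roi(stack, pixel_pitch_mm=0.05, area_mm2=1.0)
        assert mask.sum() * 0.05**2 == pytest.approx(1.0, rel=0.05)

    def test_tie_breaks_to_lowest_index(self):
        stack = np.zeros((1, 30, 30))
        stack[0, 5, 5] = 1.0
        stack[0, 20, 20] = 1.0
        mask = hottest_roi(stack, pixel_pitch_mm=0.2)
        rr, cc = np.nonzero(mask)
        assert round(rr.mean()) == 5 and round(cc.mean()) == 5

    def test_smoothing_resists_single_pixel_noise(self):
        """A broad warm blob beats an isolated slightly-hotter pixel."""
        stack = np.zeros((1, 60, 60))
        stack[0, 28:33, 28:33] = 1.0
        stack[0, 5, 5] = 1.3  # isolated outlier
        mask = hottest_roi(stack, pixel_pitch_mm=0.05)
        rr, cc = np.nonzero(mask)
        assert abs(rr.mean() - 30) < 3 and abs(cc.mean() - 30) < 3

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            hottest_roi(np.zeros((0, 4, 4)), 0.05)


class TestRoiTimecourse:
    def test_uniform_frames_pass_through(self):
        vals = np.array([0.1, 0.2, 0.3])
        stack = vals[:, None, None] * np.ones((3, 4, 4))
        tc = roi_timecourse(stack, np.ones((4, 4), bool), np.array([0.0, 1.0, 2.0]))
        assert np.allclose(tc.dT_c, vals)

    def test_ramp_binning(self):
        """0→1 ramp over 80 s at 3 fps: ten 8-s bins with means
        (8j + 23/6) / 80."""
        times = np.arange(240) / 3.0
        vals = times / 80.0
        stack = vals[:, None, None] * np.ones((240, 2, 2))
        tc = roi_timecourse(stack, np.ones((2, 2), bool), times, bin_s=8.0)
        expected = (8.0 * np.arange(10) + 23.0 / 6.0) / 80.0
        assert np.allclose(tc.binned_dT_c, expected)
        assert len(tc.binned_dT_c) == 10

    def test_binning_preserves_overall_mean(self):
        rng = np.random.default_rng(0)
        vals = rng.random(240)
        stack = vals[:, None, None] * np.ones((240, 2, 2))
        tc = roi_timecourse(stack, np.ones((2, 2), bool), np.arange(240) / 3.0)
        # equal-count bins: mean of bin means equals the overall mean
        assert tc.binned_dT_c.mean() == pytest.approx(vals.mean())

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="ROI"):
            roi_timecourse(np.zeros((3, 2, 2)), np.zeros((2, 2), bool), np.arange(3.0))


class TestMaxDeltaT:
    def test_monotone_rise_peaks_in_last_stim_bin(self):
        times = np.arange(-30, 330) / 3.0
        vals = np.clip(times / 90.0, 0, 1) * np.where(times < 90, 1.0, 0.0)
        stack = vals[:, None, None] * np.ones((len(times), 2, 2))
        tc = roi_timecourse(stack, np.ones((2, 2), bool), times)
        m = max_delta_t(tc, stim_s=90.0)
        last_stim_bin = tc.binned_dT_c[
            (tc.binned_times_s >= 0) & (tc.binned_times_s < 90)
        ][-1]
        assert m == pytest.approx(last_stim_bin)

    def test_all_zero(self):
        tc = roi_timecourse(
            np.zeros((30, 2, 2)), np.ones((2, 2), bool), np.arange(30) / 3.0
        )
        assert max_delta_t(tc) == 0.0


class TestFitDoseModel:
    def test_exact_line(self):
        x = np.array([20.0, 40.0, 60.0, 120.0])
        model = fit_dose_model(x, 0.004 * x + 0.01)
        assert model.r_squared == pytest.approx(1.0)
        assert model.slope == pytest.approx(0.004)
        assert model.predict([100.0])[0] == pytest.approx(0.41)

    def test_two_printed_pairs(self):
        """(60, 0.2 °C) and (180, 0.8 °C): slope 0.005 °C per unit dose,
        intercept −0.1 °C."""
        model = fit_dose_model([60.0, 180.0], [0.2, 0.8])
        assert model.slope == pytest.approx(0.005)
        assert model.intercept == pytest.approx(-0.1)

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_dose_model([60.0, 60.0], [0.2, 0.3])


class TestCompareFrequencies:
    def make_tcs(self, values_per_trial):
        out = []
        for vals in values_per_trial:
            vals = np.asarray(vals, dtype=float)
            stack = vals[:, None, None] * np.ones((len(vals), 2, 2))
            # one frame per 8 s so each frame is its own bin
            out.append(
                roi_timecourse(stack, np.ones((2, 2), bool),
                               np.arange(len(vals)) * 8.0)
            )
        return out

    def test_identical_sets_not_significant(self):
        a = self.make_tcs([[0.1, 0.2]] * 5)
        res = compare_frequencies(a, self.make_tcs([[0.1, 0.2]] * 5))
        assert np.all(res["p_value"] == 1.0)
        assert not res["significant"].any()

    def test_uniform_sign_differences_exact_p(self):
        """n = 5 all-positive differences: exact two-sided p = 2/32."""
        a = self.make_tcs([[0.5 + 0.01 * i] for i in range(5)])
        b = self.make_tcs([[0.1 + 0.01 * i] for i in range(5)])
        res = compare_frequencies(a, b)
        assert res["p_value"][0] == pytest.approx(0.0625)
        # one-sided oracle for the same configuration: 1/32
        one_sided = stats.wilcoxon(
            np.arange(1.0, 6.0), alternative="greater", method="exact"
        ).pvalue
        assert one_sided == pytest.approx(1.0 / 32.0)

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_frequencies(self.make_tcs([[0.1]] * 3), self.make_tcs([[0.1]] * 4))


class TestNullMovieHasNoSpuriousHeating:
    def test_binned_null_movie_consistent_with_zero(self):
        cam = CameraModel(noise_sd_c=0.08)
        times = np.arange(330) / 3.0 - 10.0
        true = np.zeros((330, 30, 30))
        rec = render_thermal_movie(true, cam, times_s=times, seed=21)
        movie_c = cam.to_temperature(rec.grey)
        d = delta_maps(movie_c, times)
        roi = hottest_roi(d, pixel_pitch_mm=0.05)
        tc = roi_timecourse(d, roi, times)
        n_px = roi.sum()
        n_frames = int(8 * 3)
        se = 0.08 / np.sqrt(n_px * n_frames)
        # the hottest-ROI search biases the mean upward slightly; 3·SE on
        # each bin with a small allowance for the selection effect
        assert np.all(np.abs(tc.binned_dT_c) < 5 * se + 0.01)
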