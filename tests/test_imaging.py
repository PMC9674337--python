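"""dF/F pipeline, ROI metrics, and the CoM retinotopy test."""

import numpy as np
import pytest
from skimage.measure import regionprops

from loomlab import imaging as im
from loomlab import synthetic as syn


@pytest.fixture()
def structured_movie():
    """Static textured movie (registration needs spatial structure)."""
    rng = np.random.default_rng(11)
    base = rng.uniform(100.0, 400.0, size=(48, 56))
    frames = np.repeat(base[None], 8, axis=0)
    return im.FluorMovie(frames.copy(), frame_rate=5.0,
                         timeline=im.Timeline(stim_start=1.0, stim_end=1.2))


class TestPreprocess:
    def test_injected_shifts_recovered_exactly(self, structured_movie):
        frames = structured_movie.frames.copy()
        true_shifts = np.array([[0, 0], [2, -1], [-2, 2], [1, 1],
                                [0, -2], [-1, 0], [2, 2], [-2, -2]])
        for k, (dy, dx) in enumerate(true_shifts):
            frames[k] = np.roll(frames[k], (dy, dx), axis=(0, 1))
        moved = im.FluorMovie(frames, 5.0,
                              timeline=structured_movie.timeline)
        reg, shifts = im.register_translation(
            moved, reference=structured_movie.frames[0])
        np.testing.assert_array_equal(shifts, -true_shifts)
        np.testing.assert_allclose(reg.frames, structured_movie.frames)

    def test_static_movie_zero_shifts(self, structured_movie):
        _, shifts = im.register_translation(structured_movie)
        assert np.all(shifts == 0)

    def test_median_filter_removes_single_pixel_outliers(self,
                                                         structured_movie):
        frames = structured_movie.frames.copy()
        frames[3, 20, 20] += 5000.0
        noisy = im.FluorMovie(frames, 5.0,
                              timeline=structured_movie.timeline)
        clean = im.preprocess_movie(noisy)
        reference = im.preprocess_movie(structured_movie)
        # the outlier leaves no trace: filtering the contaminated movie
        # equals filtering the clean one at that pixel
        assert (clean.frames[3, 20, 20]
                == pytest.approx(reference.frames[3, 20, 20]))

    def test_constant_frame_unchanged_by_filter(self):
        frames = np.full((3, 20, 20), 7.0)
        movie = im.FluorMovie(frames, 5.0,
                              timeline=im.Timeline(stim_start=0.4,
                                                   stim_end=0.5))
        out = im.preprocess_movie(movie)
        np.testing.assert_allclose(out.frames, 7.0)


class TestDff:
    def _movie(self, frames):
        return im.FluorMovie(np.asarray(frames, float), frame_rate=5.0,
                             timeline=im.Timeline(stim_start=2.0,
                                                  stim_end=6.0))

    def test_constant_movie_gives_zero(self):
        movie = self._movie(np.full((40, 8, 8), 300.0))
        np.testing.assert_allclose(im.compute_dff(movie), 0.0, atol=1e-12)

    def test_50_percent_step(self):
        frames = np.full((40, 8, 8), 200.0)
        frames[15:] = 300.0
        dff = im.compute_dff(self._movie(frames))
        np.testing.assert_allclose(dff[:10], 0.0, atol=1e-12)
        np.testing.assert_allclose(dff[15:], 0.5, atol=1e-12)

    def test_linear_detrend_recovers_step_within_1_percent(self):
        t = np.arange(60) / 5.0
        drift = 50.0 * t                       # counts/s baseline drift
        frames = 400.0 + drift[:, None, None] + np.zeros((60, 6, 6))
        frames[20:] += 120.0                   # true step: dF/F = 0.3
        dff = im.compute_dff(self._movie(frames), detrend="linear")
        step = dff[25:].mean()
        assert step == pytest.approx(120.0 / 400.0, rel=0.01)

    def test_gain_invariance(self):
        rng = np.random.default_rng(0)
        frames = rng.uniform(100, 200, size=(30, 5, 5))
        a = im.compute_dff(self._movie(frames))
        b = im.compute_dff(self._movie(frames * 3.7))
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_zero_baseline_pixels_masked(self):
        frames = np.full((30, 4, 4), 100.0)
        frames[:, 0, 0] = 0.0
        dff = im.compute_dff(self._movie(frames))
        assert np.isnan(dff[:, 0, 0]).all()
        assert np.isfinite(dff[:, 1:, :]).all()


class TestRoiMetrics:
    def _dff_from_trace(self, trace):
        return np.asarray(trace, float)[:, None, None] * np.ones((1, 4, 4))

    def test_gaussian_bump_peak_and_time(self):
        t = np.arange(60) / 5.0
        trace = 0.8 * np.exp(-0.5 * ((t - 4.0) / 0.6) ** 2)
        dff = self._dff_from_trace(trace)
        roi = im.ROI(np.ones((4, 4), bool), "field A")
        tl = im.Timeline(stim_start=2.0, stim_end=6.0, flash_time=8.0)
        met = im.roi_peak_metrics(dff, roi, tl, frame_rate=5.0)
        assert met["loom_peak"] == pytest.approx(0.8, rel=1e-3)
        assert met["loom_peak_time"] == pytest.approx(4.0, abs=0.2)

    def test_flat_trace_zero_flash_peak(self):
        dff = self._dff_from_trace(np.zeros(60))
        roi = im.ROI(np.ones((4, 4), bool))
        tl = im.Timeline(stim_start=2.0, stim_end=6.0, flash_time=8.0)
        met = im.roi_peak_metrics(dff, roi, tl)
        assert met["flash_peak"] == 0.0

    def test_flash_peak_is_post_max_minus_pre_min(self):
        # dip of depth b before the flash, bump of amplitude a after
        t = np.arange(80) / 5.0
        trace = np.zeros(80)
        trace[(t >= 7.2) & (t <= 8.0)] = -0.2          # pre-flash dip
        trace[(t > 8.0) & (t <= 9.0)] = 0.5            # post-flash bump
        dff = self._dff_from_trace(trace)
        tl = im.Timeline(stim_start=2.0, stim_end=6.0, flash_time=8.0)
        met = im.roi_peak_metrics(dff, im.ROI(np.ones((4, 4), bool)), tl)
        assert met["flash_peak"] == pytest.approx(0.7)

    def test_window_outside_recording_is_error(self):
        dff = self._dff_from_trace(np.zeros(10))
        tl = im.Timeline(stim_start=30.0, stim_end=40.0)
        with pytest.raises(ValueError):
            im.roi_peak_metrics(dff, im.ROI(np.ones((4, 4), bool)), tl)


class TestPeakTimeRange:
    tl = im.Timeline(stim_start=1.0, stim_end=9.0)

    def _bump(self, center, n=60, rate=5.0):
        t = np.arange(n) / rate
        return np.exp(-0.5 * ((t - center) / 0.4) ** 2)

    def test_identical_traces_zero_range(self):
        traces = [self._bump(4.0)] * 5
        assert im.peak_time_range(traces, self.tl) == 0.0

    def test_two_bumps_apart(self):
        traces = [self._bump(4.0), self._bump(4.8)]
        assert im.peak_time_range(traces, self.tl) == pytest.approx(
            0.8, abs=0.21)

    def test_sweep_range_matches_injected_duration(self):
        # 5 subregions peaking sequentially across 2 s
        centers = np.linspace(3.0, 5.0, 5)
        traces = [self._bump(c) for c in centers]
        assert im.peak_time_range(traces, self.tl) == pytest.approx(
            2.0, abs=0.21)

    def test_needs_two_subregions(self):
        with pytest.raises(ValueError):
            im.peak_time_range([self._bump(3.0)], self.tl)


class TestCoM:
    def test_single_bright_pixel(self):
        dff = np.zeros((3, 10, 12))
        dff[:, 4, 7] = 1.0
        traj = im.com_trajectory(dff, np.ones((10, 12), bool),
                                 pixel_size=0.9)
        np.testing.assert_allclose(traj.xy_um,
                                   np.tile([7 * 0.9, 4 * 0.9], (3, 1)))

    def test_two_equal_pixels_midpoint(self):
        dff = np.zeros((1, 8, 8))
        dff[0, 2, 2] = dff[0, 6, 6] = 2.0
        traj = im.com_trajectory(dff, np.ones((8, 8), bool), pixel_size=1.0)
        np.testing.assert_allclose(traj.xy_um[0], [4.0, 4.0])

    def test_negative_values_clipped_for_weighting(self):
        dff = np.zeros((1, 8, 8))
        dff[0, 1, 1] = 1.0
        dff[0, 6, 6] = -5.0          # must not drag the centroid
        traj = im.com_trajectory(dff, np.ones((8, 8), bool), pixel_size=1.0)
        np.testing.assert_allclose(traj.xy_um[0], [1.0, 1.0])

    def test_matches_skimage_weighted_centroid(self):
        rng = np.random.default_rng(5)
        frame = rng.uniform(0.0, 1.0, size=(20, 24))
        mask = np.zeros((20, 24), bool)
        mask[4:16, 6:20] = True
        traj = im.com_trajectory(frame[None], mask, pixel_size=1.0)
        img = np.where(mask, frame, 0.0)
        prop = regionprops(mask.astype(int), intensity_image=img)[0]
        cy, cx = prop.centroid_weighted
        np.testing.assert_allclose(traj.xy_um[0], [cx, cy], rtol=1e-9)

    def test_translation_equivariance(self):
        dff = np.zeros((1, 30, 30))
        dff[0, 8:12, 8:12] = np.random.default_rng(2).uniform(
            0.2, 1.0, (4, 4))
        mask = np.zeros((30, 30), bool)
        mask[5:15, 5:15] = True
        t1 = im.com_trajectory(dff, mask, pixel_size=1.0)
        shifted = np.roll(dff, (7, 9), axis=(1, 2))
        t2 = im.com_trajectory(shifted, np.roll(mask, (7, 9), axis=(0, 1)),
                               pixel_size=1.0)
        np.testing.assert_allclose(t2.xy_um[0] - t1.xy_um[0], [9.0, 7.0])

    def test_all_zero_window_warns_empty(self):
        dff = np.zeros((3, 6, 6))
        with pytest.warns(UserWarning):
            traj = im.com_trajectory(dff, np.ones((6, 6), bool))
        assert not traj.valid.any()


@pytest.fixture(scope="module")
def sweep():
    spec = syn.SyntheticMovieSpec(noise_sigma=0.0, n_frames=40, seed=3)
    movie, truth = syn.gen_field_movie(spec)
    dff = im.compute_dff(movie)
    return dff, truth


class TestShuffleNull:

    def test_per_frame_mass_conserved(self, sweep):
        dff, truth = sweep
        mask = truth["mask"]
        nulls = im.shuffle_null_trajectory(dff, mask, n_shuffles=1, seed=0)
        assert len(nulls) == 1 and nulls[0].shuffled

    def test_same_seed_identical_ensemble(self, sweep):
        dff, truth = sweep
        a = im.shuffle_null_trajectory(dff, truth["mask"], 3, seed=9)
        b = im.shuffle_null_trajectory(dff, truth["mask"], 3, seed=9)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.xy_um, tb.xy_um)

    def test_shuffled_spread_much_smaller_than_sweep(self, sweep):
        dff, truth = sweep
        mask = truth["mask"]
        traj = im.com_trajectory(dff, mask)
        nulls = im.shuffle_null_trajectory(dff, mask, n_shuffles=20, seed=1)
        null_spread = np.median([t.spread_um() for t in nulls])
        assert traj.spread_um() > 3.0 * null_spread
        assert im.outside_null_band(traj, nulls)


class TestPositionCorrelation:
    def _traj(self, xy):
        xy = np.asarray(xy, float)
        return im.CoMTrajectory(xy_um=xy, valid=np.ones(len(xy), bool),
                                frame_indices=np.arange(len(xy)))

    def test_affine_relation_gives_unit_correlation(self):
        pos = np.linspace(0.0, 1.0, 20)
        traj = self._traj(np.column_stack([3.0 * pos + 1.0,
                                           -2.0 * pos + 5.0]))
        res = im.position_correlation(traj, pos)
        np.testing.assert_allclose(np.abs(res.r), 1.0, atol=1e-12)

    def test_constant_com_reported_degenerate_zero(self):
        traj = self._traj(np.tile([2.0, 2.0], (10, 1)))
        res = im.position_correlation(traj, np.linspace(0, 1, 10))
        assert res.r[0] == 0.0 and res.degenerate.all()

    def test_too_few_frames_is_error(self):
        traj = self._traj([[0, 0], [1, 1]])
        with pytest.raises(ValueError):
            im.position_correlation(traj, np.array([0.0, 1.0]))

    def test_noisy_retinotopic_movie_recovers_high_correlation(self):
        spec = syn.SyntheticMovieSpec(noise_sigma=0.10, n_frames=40, seed=8)
        movie, truth = syn.gen_field_movie(spec)
        dff = im.compute_dff(movie)
        frames = truth["stim_frames"]
        traj = im.com_trajectory(dff, truth["mask"],
                                 frame_window=(frames[0], frames[-1] + 1))
        res = im.position_correlation(traj, truth["stimulus_positions"])
        assert np.max(np.abs(res.r)) > 0.9
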