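"""Segmentation: averaging, enhancement, crop, gated peaks, thickness maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selfrefocm.dm_segmentation import (
    GateStatus,
    PeakSet,
    PipelineParams,
    SegmentationGates,
    crop_posterior,
    detect_layer_peaks,
    dm_thickness,
    enhance_frame,
    sliding_average,
    stroma_thickness,
    summarize_map,
    thickness_map,
)
from selfrefocm.ocm_forward import AxialCalibration

from conftest import make_flat_phantom, make_volume

CAL = AxialCalibration()


def gaussian_profile(centers_px, amps, n=120, sigma=1.2):
    x = np.arange(n)
    prof = np.zeros(n)
    for c, a in zip(centers_px, amps):
        prof += a * np.exp(-((x - c) ** 2) / (2 * sigma**2))
    return prof


class TestSlidingAverage:
    @given(n=st.integers(5, 40), w=st.integers(1, 5))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_frame_count_conservation(self, n, w):
        out = sliding_average(np.random.default_rng(0).random((n, 4, 3)), w)
        assert out.shape[0] == n - w + 1

    def test_500_frames_give_496(self):
        vol = np.zeros((500, 6, 4))
        assert sliding_average(vol, 5).shape[0] == 496

    def test_window_equal_frames_gives_pixelwise_mean(self):
        rng = np.random.default_rng(1)
        vol = rng.random((5, 3, 3))
        out = sliding_average(vol, 5)
        assert out.shape[0] == 1
        np.testing.assert_allclose(out[0], vol.mean(axis=0))

    def test_identity_on_constant_volume(self):
        vol = np.full((10, 4, 4), 2.5)
        np.testing.assert_allclose(sliding_average(vol, 5), np.full((6, 4, 4), 2.5))

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            sliding_average(np.zeros((3, 2, 2)), 5)


class TestEnhanceFrame:
    def test_zero_saturation_is_median_filter_only(self):
        rng = np.random.default_rng(2)
        img = rng.random((20, 20))
        img[0, 0], img[11, 7] = 0.0, 1.0  # pin the range to [0, 1]
        from scipy.ndimage import median_filter

        np.testing.assert_allclose(
            enhance_frame(img, saturation=0.0), median_filter(img, size=(3, 3), mode="reflect")
        )

    def test_salt_pixel_removed(self):
        img = np.zeros((15, 15))
        img[7, 7] = 100.0
        out = enhance_frame(img, saturation=0.0)
        assert out[7, 7] == 0.0

    def test_ramp_quantiles_clip_tails(self):
        img = np.tile(np.linspace(0, 1, 200)[:, None], (1, 20))
        out = enhance_frame(img, saturation=0.01)
        assert np.mean(out == 0.0) >= 0.009
        assert np.mean(out == 1.0) >= 0.009
        middle = out[5:-5, 10]
        assert np.all(np.diff(middle) >= 0)

    def test_constant_image_returns_zeros(self):
        out = enhance_frame(np.full((10, 10), 3.3))
        assert np.all(out == 0.0)


class TestCropPosterior:
    def test_endothelium_within_first_gate_of_top(self):
        ph = make_flat_phantom(3.0, nx=16, ny=6)
        vol = make_volume(ph)
        avg = sliding_average(vol.data, 5)
        cropped = crop_posterior(avg[0], CAL)
        assert cropped.valid
        for a in range(16):
            peaks = detect_layer_peaks(cropped.data[:, a], calib=CAL)
            assert peaks.endothelium_px is not None
            assert peaks.endothelium_px * CAL.um_per_pixel_tissue <= 10.0

    def test_all_zero_frame_invalid(self):
        cropped = crop_posterior(np.zeros((100, 8)), CAL)
        assert not cropped.valid

    def test_debris_shadow_invalidates_only_affected_columns(self):
        ph = make_flat_phantom(4.0, nx=20, ny=7)
        vol = make_volume(ph)
        shadow = vol.data.copy()
        shadow[:, :, 5:9] = 0.0  # opaque debris casts a dark shadow
        tm = thickness_map(shadow, calib=CAL)
        # interior of the shadow is invalid; the 3x3 median filter may blend
        # signal across the single boundary column on each side
        assert np.all(np.isnan(tm.values_um[:, 6:8]))
        assert np.isfinite(tm.values_um[:, :4]).all()
        assert np.isfinite(tm.values_um[:, 10:]).all()


class TestDetectLayerPeaks:
    def test_two_peak_profile_valid_with_8px_separation(self):
        prof = gaussian_profile([5, 13], [1.0, 0.6])
        ps = detect_layer_peaks(prof, calib=CAL)
        assert ps.gate_status is GateStatus.valid
        assert (ps.stroma_dm_px - ps.endothelium_px) == 8
        assert dm_thickness(ps, CAL) == pytest.approx(2.796424)

    def test_first_peak_beyond_10um_gated_out(self):
        deep = int(round(12.0 / CAL.um_per_pixel_tissue))
        prof = gaussian_profile([deep, deep + 8], [1.0, 0.6])
        ps = detect_layer_peaks(prof, calib=CAL)
        assert ps.gate_status is GateStatus.first_out_of_gate

    def test_second_peak_beyond_7um_gated_out(self):
        prof = gaussian_profile([5, 30], [1.0, 0.6])  # 25 px = 8.74 µm
        ps = detect_layer_peaks(prof, calib=CAL)
        assert ps.gate_status is GateStatus.second_out_of_gate

    def test_single_peak_reports_missing_second(self):
        ps = detect_layer_peaks(gaussian_profile([6], [1.0]), calib=CAL)
        assert ps.gate_status is GateStatus.no_second_peak

    def test_gate_soundness_fuzz(self):
        """No accepted pair violates the gates on 1000 random profiles."""
        rng = np.random.default_rng(42)
        gates = SegmentationGates()
        for _ in range(1000):
            prof = rng.random(80)
            ps = detect_layer_peaks(prof, gates, CAL)
            if ps.is_valid:
                assert ps.endothelium_px * CAL.um_per_pixel_tissue <= 10.0
                thick = dm_thickness(ps, CAL)
                assert 0 < thick <= 7.0


class TestThickness:
    def test_dm_thickness_values(self):
        ps = PeakSet(5, 25, None, GateStatus.valid)
        assert dm_thickness(ps, CAL) == pytest.approx(20 * 0.349553)
        bad = PeakSet(5, None, None, GateStatus.no_second_peak)
        assert np.isnan(dm_thickness(bad, CAL))

    def test_stroma_thickness_values(self):
        ps = PeakSet(5, 13, 138, GateStatus.valid)
        assert stroma_thickness(ps, CAL) == pytest.approx(125 * 0.349553)
        assert np.isnan(stroma_thickness(PeakSet(5, 13, None, GateStatus.valid), CAL))


class TestThicknessMap:
    def test_map_shape_and_quantization(self, small_selfref_volume):
        tm = thickness_map(small_selfref_volume)
        n_frames = small_selfref_volume.n_frames
        assert tm.values_um.shape == (n_frames - 4, small_selfref_volume.n_ascans)
        finite = tm.values_um[np.isfinite(tm.values_um)]
        ratios = finite / CAL.um_per_pixel_tissue
        np.testing.assert_allclose(ratios, np.round(ratios), atol=1e-9)

    def test_gate_bounds_on_map(self, small_selfref_volume):
        tm = thickness_map(small_selfref_volume)
        finite = tm.values_um[np.isfinite(tm.values_um)]
        assert finite.size > 0
        assert np.all(finite > 0) and np.all(finite <= 7.0)

    def test_evaluation_order_independence(self, small_selfref_volume):
        """Per-column detection gives the same answer whatever order the
        A-scans are visited in (parallelizable contract)."""
        avg = sliding_average(small_selfref_volume.data, 5)
        cropped = crop_posterior(avg[0], CAL)
        cropped.data = enhance_frame(cropped.data)
        n = cropped.data.shape[1]
        forward = [dm_thickness(detect_layer_peaks(cropped.data[:, a], calib=CAL), CAL)
                   for a in range(n)]
        perm = np.random.default_rng(0).permutation(n)
        permuted = {a: dm_thickness(detect_layer_peaks(cropped.data[:, a], calib=CAL), CAL)
                    for a in perm}
        np.testing.assert_array_equal(forward, [permuted[a] for a in range(n)])
        # and two full runs are bit-identical
        np.testing.assert_array_equal(
            thickness_map(small_selfref_volume).values_um,
            thickness_map(small_selfref_volume).values_um,
        )

    def test_pure_noise_volume_yields_empty_map(self):
        rng = np.random.default_rng(7)
        noise = rng.random((8, 300, 10)) * 1e-3
        tm = thickness_map(noise, calib=CAL)
        mean, sd, frac = summarize_map(tm)
        assert frac < 0.2
        if frac == 0:
            assert np.isnan(mean)

    def test_noiseless_recovery_well_resolved(self, calib):
        for t in (2.8, 4.5, 6.0):
            ph = make_flat_phantom(t, nx=48, ny=10, seed=5)
            tm = thickness_map(make_volume(ph))
            mean, _, frac = summarize_map(tm)
            assert frac > 0.7
            assert abs(mean - ph.dm_thickness_um.mean()) <= 0.35

    def test_map_mean_monotone_in_true_thickness(self):
        """Thicker DM never yields a thinner map (resolved regime)."""
        means = []
        for t in (2.5, 3.5, 4.5, 5.5, 6.5):
            ph = make_flat_phantom(t, nx=48, ny=10, seed=9)
            means.append(summarize_map(thickness_map(make_volume(ph)))[0])
        assert all(b >= a for a, b in zip(means, means[1:]))

    def test_stroma_layer_recovery(self):
        ph = make_flat_phantom(4.0, nx=16, ny=6, stroma_um=44.0, stroma_sd=0.5)
        tm = thickness_map(make_volume(ph), layer="stroma")
        mean, _, frac = summarize_map(tm)
        assert frac > 0.9
        assert abs(mean - ph.stroma_thickness_um.mean()) <= 2 * CAL.um_per_pixel_tissue

    def test_volume_too_short_rejected(self):
        with pytest.raises(ValueError):
            thickness_map(np.zeros((3, 50, 4)), PipelineParams(avg_window=5), calib=CAL)


class TestSummarize:
    def test_constant_map(self):
        assert summarize_map(np.full((4, 4), 2.0)) == (2.0, 0.0, 1.0)

    def test_mixed_nan_map(self):
        mean, sd, frac = summarize_map(np.array([[2.0, np.nan], [4.0, np.nan]]))
        assert mean == 3.0 and frac == 0.5
        assert sd == pytest.approx(np.std([2.0, 4.0], ddof=1))

    def test_all_nan_map(self):
        mean, sd, frac = summarize_map(np.full((3, 3), np.nan))
        assert np.isnan(mean) and np.isnan(sd) and frac == 0.0
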