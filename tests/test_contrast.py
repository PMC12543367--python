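"""Unit tests for speckle contrast, noise correction, and hemodynamic indices."""

import math

import numpy as np
import pytest

from scoskit import synthetic as syn
from scoskit.contrast import (
    CameraCalibration,
    ChannelLayout,
    ChannelRegion,
    FrameStack,
    bfi_from_contrast,
    bvi_from_intensity,
    compute_dark_calibration,
    compute_hemo_series,
    noise_corrected_contrast,
    normalize_trace,
    raw_contrast,
    split_channels,
)
from scoskit.exceptions import (
    CalibrationError,
    DegenerateTraceError,
    InvalidParameterError,
    LayoutError,
)


def make_stack(frames, **kw):
    defaults = dict(frame_rate_hz=65.0, exposure_s=0.008, bit_depth=16)
    defaults.update(kw)
    return FrameStack(frames=np.asarray(frames, dtype=np.uint16), **defaults)


class TestFrameStack:
    def test_duration_from_metadata(self):
        stack = make_stack(np.zeros((1560, 4, 4)))
        assert stack.duration_s == pytest.approx(24.0)

    def test_rejects_single_frame(self):
        with pytest.raises(InvalidParameterError):
            make_stack(np.zeros((1, 4, 4)))

    def test_rejects_counts_above_bit_depth(self):
        frames = np.full((3, 2, 2), 5000, dtype=np.int32)
        with pytest.raises(InvalidParameterError):
            FrameStack(frames=frames, frame_rate_hz=65.0, exposure_s=0.008, bit_depth=12)

    def test_rejects_float_frames(self):
        with pytest.raises(InvalidParameterError):
            FrameStack(
                frames=np.zeros((3, 2, 2), dtype=float),
                frame_rate_hz=65.0,
                exposure_s=0.008,
            )


class TestChannelLayout:
    def test_overlapping_regions_rejected(self):
        with pytest.raises(LayoutError):
            ChannelLayout(
                regions=(
                    ChannelRegion(1, 0.6, 0, 4, 0, 4),
                    ChannelRegion(2, 1.0, 2, 6, 2, 6),
                )
            )

    def test_sd_distance_must_increase_with_channel_id(self):
        with pytest.raises(LayoutError):
            ChannelLayout(
                regions=(
                    ChannelRegion(1, 1.0, 0, 4, 0, 4),
                    ChannelRegion(2, 0.6, 0, 4, 4, 8),
                )
            )

    def test_region_outside_frame_rejected(self):
        layout = ChannelLayout(regions=(ChannelRegion(1, 0.6, 0, 16, 0, 16),))
        stack = make_stack(np.zeros((2, 8, 8)))
        with pytest.raises(LayoutError):
            split_channels(stack, layout)


class TestSplitChannels:
    def test_full_frame_region_yields_all_pixels(self):
        stack = make_stack(np.arange(2 * 8 * 8).reshape(2, 8, 8) % 100)
        layout = ChannelLayout(regions=(ChannelRegion(1, 0.6, 0, 8, 0, 8),))
        ens = split_channels(stack, layout)
        assert ens[1].shape == (2, 64)

    def test_two_disjoint_regions_on_8x8(self):
        stack = make_stack(np.zeros((3, 8, 8)))
        layout = ChannelLayout(
            regions=(
                ChannelRegion(1, 0.6, 0, 4, 0, 4),
                ChannelRegion(2, 1.0, 4, 8, 4, 8),
            )
        )
        ens = split_channels(stack, layout)
        assert ens[1].shape == (3, 16)
        assert ens[2].shape == (3, 16)

    def test_seven_default_regions_give_synchronized_series(self):
        cfg = syn.SyntheticCohortConfig(region_shape=(8, 8))
        stack = make_stack(np.zeros((2, *cfg.frame_shape)))
        ens = split_channels(stack, cfg.layout())
        assert sorted(ens) == [1, 2, 3, 4, 5, 6, 7]
        assert all(v.shape == (2, 64) for v in ens.values())


class TestDarkCalibration:
    def test_constant_dark_frames(self):
        dark = make_stack(np.full((5, 6, 6), 100))
        calib = compute_dark_calibration(dark, gain=1.0, conversion_factor=0.46)
        assert calib.dark_offset == pytest.approx(100.0)
        assert calib.dark_variance == pytest.approx(0.0)

    def test_read_noise_variance_recovered(self):
        noise = syn.NoiseModel(read_sigma=2.0, dark_offset=100.0)
        dark = syn.synthesize_dark_frames(noise, n_frames=100, frame_shape=(40, 40), seed=3)
        calib = compute_dark_calibration(dark, gain=1.0, conversion_factor=0.46)
        # quantization adds ~1/12 to the Gaussian variance
        assert calib.dark_variance == pytest.approx(4.0 + 1.0 / 12.0, abs=0.1)
        assert calib.dark_offset == pytest.approx(100.0, abs=0.05)

    def test_gamma_unit(self):
        dark = make_stack(np.full((3, 4, 4), 50))
        calib = compute_dark_calibration(dark, gain=1.0, conversion_factor=0.46)
        assert calib.gamma == pytest.approx(2.1739, abs=1e-4)
        assert round(calib.gamma, 2) == 2.17

    def test_single_frame_insufficient(self):
        frames = np.zeros((2, 4, 4), dtype=np.uint16)
        dark = make_stack(frames)
        object.__setattr__(dark, "frames", frames[:1])
        with pytest.raises(CalibrationError):
            compute_dark_calibration(dark, gain=1.0, conversion_factor=0.46)

    def test_per_channel_variant(self):
        frames = np.zeros((4, 4, 8), dtype=np.uint16)
        frames[:, :, :4] = 10
        frames[:, :, 4:] = 20
        dark = make_stack(frames)
        layout = ChannelLayout(
            regions=(
                ChannelRegion(1, 0.6, 0, 4, 0, 4),
                ChannelRegion(2, 1.0, 0, 4, 4, 8),
            )
        )
        calibs = compute_dark_calibration(dark, 1.0, 0.46, layout=layout)
        assert calibs[1].dark_offset == pytest.approx(10.0)
        assert calibs[2].dark_offset == pytest.approx(20.0)


class TestCameraCalibration:
    def test_gamma_computed_from_gain_and_cf(self):
        calib = CameraCalibration(gain=1.0, conversion_factor=0.46)
        assert calib.gamma == pytest.approx(1.0 / 0.46)

    def test_inconsistent_gamma_rejected(self):
        with pytest.raises(CalibrationError):
            CameraCalibration(gain=1.0, conversion_factor=0.46, gamma=2.0)

    def test_negative_dark_variance_rejected(self):
        with pytest.raises(CalibrationError):
            CameraCalibration(gain=1.0, conversion_factor=0.46, dark_variance=-1.0)


class TestRawContrast:
    def test_constant_ensemble_has_zero_contrast(self):
        mu, var, k, valid = raw_contrast(np.array([50, 50, 50, 50]), offset=0.0)
        assert (mu, var, k) == (50.0, 0.0, 0.0)
        assert valid

    def test_hand_computed_example(self):
        mu, var, k, valid = raw_contrast(np.array([2, 4, 6, 8]), offset=0.0)
        assert mu == pytest.approx(5.0)
        assert var == pytest.approx(20.0 / 3.0)
        assert k == pytest.approx(0.26667, abs=1e-5)

    def test_gamma_ensemble_moment_identity(self, rng):
        # var/mean^2 of a gamma distribution equals 1/shape
        ensemble = rng.gamma(4.0, 25.0, size=100_000)
        _, _, k, _ = raw_contrast(ensemble)
        assert k == pytest.approx(0.25, rel=0.02)

    def test_offset_shifts_mean_not_variance(self):
        ens = np.array([102.0, 104.0, 106.0, 108.0])
        mu, var, k, _ = raw_contrast(ens, offset=100.0)
        assert mu == pytest.approx(5.0)
        assert var == pytest.approx(20.0 / 3.0)

    def test_nonpositive_mean_flags_invalid(self):
        mu, var, k, valid = raw_contrast(np.array([1, 2, 3]), offset=10.0)
        assert not valid
        assert math.isnan(k)

    def test_empty_and_singleton_rejected(self):
        with pytest.raises(InvalidParameterError):
            raw_contrast(np.array([]))
        with pytest.raises(InvalidParameterError):
            raw_contrast(np.array([5.0]))


class TestNoiseCorrectedContrast:
    def test_zero_noise_is_identity(self):
        calib = CameraCalibration(gain=0.0, conversion_factor=1.0, dark_variance=0.0)
        k_adj, valid = noise_corrected_contrast(100.0, 0.25, calib)
        assert valid
        assert k_adj == pytest.approx(0.25)

    def test_noise_floor_flags_invalid(self):
        # shot noise 2.1739/5 = 0.43478 exceeds the raw contrast 0.26667
        calib = CameraCalibration(gain=1.0, conversion_factor=0.46)
        k_adj, valid = noise_corrected_contrast(5.0, 0.26667, calib)
        assert not valid
        assert math.isnan(k_adj)

    def test_poisson_only_frames_corrected_to_zero(self):
        noise = syn.NoiseModel(read_sigma=0.0, dark_offset=0.0)
        stack = syn.synthesize_noise_only_frames(
            1000.0, noise, n_frames=400, frame_shape=(48, 48), seed=9
        )
        ens = stack.frames.reshape(stack.n_frames, -1)
        mu, _, k_raw, _ = raw_contrast(ens)
        assert np.mean(k_raw) == pytest.approx(noise.gamma / 1000.0, rel=0.05)
        calib = CameraCalibration(gain=1.0, conversion_factor=0.46, dark_variance=1 / 12)
        k_adj = k_raw - calib.gamma / mu - calib.dark_variance / mu**2
        se = np.std(k_adj, ddof=1) / np.sqrt(len(k_adj))
        assert abs(np.mean(k_adj)) < 3 * se

    def test_quantization_term_optional(self):
        with_q = CameraCalibration(
            gain=1.0, conversion_factor=1.0, include_quantization=True
        )
        without_q = CameraCalibration(gain=1.0, conversion_factor=1.0)
        k_with, _ = noise_corrected_contrast(10.0, 0.5, with_q)
        k_without, _ = noise_corrected_contrast(10.0, 0.5, without_q)
        assert k_without - k_with == pytest.approx(1.0 / (12.0 * 100.0))

    def test_adjusted_never_exceeds_raw(self, rng):
        calib = CameraCalibration(gain=1.0, conversion_factor=0.46, dark_variance=4.0)
        mu = rng.uniform(10, 1000, size=200)
        k_raw = rng.uniform(0.0, 0.5, size=200)
        k_adj, valid = noise_corrected_contrast(mu, k_raw, calib)
        assert np.all(k_adj[valid] <= k_raw[valid])


class TestBfi:
    @pytest.mark.parametrize("k, expected", [(0.25, 4.0), (1.0, 1.0)])
    def test_reciprocal(self, k, expected):
        assert bfi_from_contrast(k) == pytest.approx(expected)

    def test_invalid_propagates(self):
        bfi = bfi_from_contrast(np.array([0.25, np.nan]), np.array([True, False]))
        assert bfi[0] == pytest.approx(4.0)
        assert math.isnan(bfi[1])

    def test_flow_doubling_in_asymptotic_regime(self):
        # exposure >> tau_c: K^2 ~ beta*tau_c/T so BFI scales with flow
        t_exp = 0.008
        k1 = syn.speckle_visibility(t_exp, 1e-4, beta=1.0)
        k2 = syn.speckle_visibility(t_exp, 5e-5, beta=1.0)
        ratio = (1.0 / k2) / (1.0 / k1)
        assert ratio == pytest.approx(2.0, rel=0.01)


class TestNormalizeTrace:
    def test_three_point_example(self):
        out = normalize_trace(np.array([2.0, 4.0, 6.0]))
        np.testing.assert_allclose(out, [0.0, 0.5, 1.0])

    def test_idempotent(self, rng):
        trace = rng.normal(size=50)
        once = normalize_trace(trace)
        twice = normalize_trace(once)
        np.testing.assert_allclose(once, twice)

    def test_invalid_samples_excluded_and_unfilled(self):
        trace = np.array([2.0, 100.0, 6.0])
        out = normalize_trace(trace, valid=np.array([True, False, True]))
        assert math.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], [0.0, 1.0])

    def test_degenerate_trace_raises(self):
        with pytest.raises(DegenerateTraceError):
            normalize_trace(np.array([3.0, 3.0, 3.0]))


class TestBvi:
    def test_zero_at_baseline(self):
        t = np.arange(10.0)
        mu = np.full(10, 250.0)
        bvi, i0 = bvi_from_intensity(t, mu)
        assert i0 == pytest.approx(250.0)
        np.testing.assert_allclose(bvi, 0.0)

    def test_log_method_closed_form(self):
        t = np.array([0.0, 1.0, 8.0])
        mu = np.array([100.0, 100.0, 50.0])
        bvi, i0 = bvi_from_intensity(t, mu)
        assert i0 == pytest.approx(100.0)
        assert bvi[2] == pytest.approx(math.log10(2.0), abs=1e-9)

    def test_linear_taylor_coefficient(self):
        t = np.array([0.0, 1.0, 8.0])
        mu = np.array([1000.0, 1000.0, 990.0])
        log_bvi, _ = bvi_from_intensity(t, mu, method="log")
        lin_bvi, _ = bvi_from_intensity(t, mu, method="linear")
        assert log_bvi[2] == pytest.approx(0.0043648, abs=1e-6)
        assert lin_bvi[2] == pytest.approx(0.0043429, abs=1e-6)

    def test_as_printed_coefficient_available(self):
        t = np.array([0.0, 1.0, 8.0])
        mu = np.array([1000.0, 1000.0, 990.0])
        bvi, _ = bvi_from_intensity(t, mu, method="linear", linear_coefficient=2.0)
        assert bvi[2] == pytest.approx(2.0 * 10.0 / 1000.0, abs=1e-9)

    def test_linear_log_agreement_for_small_changes(self, rng):
        t = np.linspace(0, 20, 200)
        mu = 1000.0 * (1.0 + 0.019 * np.sin(t))  # strictly below 2% swings
        mu[t < 7] = 1000.0
        log_bvi, _ = bvi_from_intensity(t, mu, method="log")
        lin_bvi, _ = bvi_from_intensity(t, mu, method="linear")
        changed = np.abs(log_bvi) > 1e-6
        rel = np.abs(lin_bvi[changed] - log_bvi[changed]) / np.abs(log_bvi[changed])
        assert np.max(rel) < 0.01

    def test_empty_baseline_raises(self):
        t = np.arange(10.0) + 8.0
        mu = np.full(10, 10.0)
        with pytest.raises(InvalidParameterError):
            bvi_from_intensity(t, mu, baseline_window_s=7.0)


class TestHemoSeries:
    def test_nbfi_attains_bounds_and_bvi_baseline(self, small_occlusion_config,
                                                  small_occlusion_subject):
        cfg = small_occlusion_config
        stack, _ = small_occlusion_subject
        hemo = compute_hemo_series(stack, cfg.layout(), cfg.noise.true_calibration())
        for ch in hemo.channels:
            vals = ch.nbfi[ch.valid]
            assert vals.min() == pytest.approx(0.0)
            assert vals.max() == pytest.approx(1.0)
            assert np.all(ch.k_adj_sq[ch.valid] <= ch.k_raw_sq[ch.valid])

    def test_round_trip_through_frame(self, small_occlusion_config,
                                      small_occlusion_subject):
        cfg = small_occlusion_config
        stack, _ = small_occlusion_subject
        hemo = compute_hemo_series(stack, cfg.layout(), cfg.noise.true_calibration())
        from scoskit.contrast import HemoSeries

        df = hemo.to_frame(subject=0)
        back = HemoSeries.from_frame(df, hemo.frame_rate_hz, hemo.exposure_s)
        for a, b in zip(hemo.channels, back.channels):
            np.testing.assert_allclose(a.nbfi, b.nbfi)
            np.testing.assert_allclose(a.bvi, b.bvi)
            assert a.baseline_i0 == pytest.approx(b.baseline_i0)
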