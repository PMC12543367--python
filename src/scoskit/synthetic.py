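"""Synthetic two-layer (scalp/brain) speckle-camera simulator with ground truth.

Generates multi-channel 16-bit frame stacks that emulate a seven-fiber
speckle-contrast acquisition: a pulsatile two-compartment flow model with an
optional scalp-occlusion window drives a per-channel decorrelation rate; the
camera-integrated speckle visibility sets the true squared contrast
``K_true^2``; pixel photoelectrons are drawn from a gamma ensemble with shape
``1/K_true^2`` (speckle statistics) optionally compounded with Poisson
detection (shot noise), then scaled to counts, offset, read-noise blurred,
quantized and clipped.

Pixels are statistically independent: spatial speckle correlation (the real
system's s/p = 0.3 sampling) is folded into the coherence factor ``beta``
rather than simulated as a correlated field — the analysis pipeline uses only
first and second ensemble moments, which this reproduces exactly.

Default suppression fractions and sensitivity profiles are exercise
parameters for testing the pipeline; they are NOT physiological estimates
(the observable channel ratios confound suppression depth and layer
sensitivity, so no such estimate is implied).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .contrast import CameraCalibration, ChannelLayout, ChannelRegion, FrameStack
from .exceptions import InvalidParameterError, SaturationWarning

__all__ = [
    "ANSI_SKIN_LIMIT_MW_PER_MM2",
    "LASER_POWER_MW",
    "SPOT_DIAMETER_MM",
    "SPECKLE_TO_PIXEL_RATIO",
    "DEFAULT_SD_DISTANCES_CM",
    "DEFAULT_OCCLUSION_WINDOW_S",
    "METHODS_OCCLUSION_WINDOW_S",
    "irradiance_mw_per_mm2",
    "speckle_density_per_pixel",
    "ChannelSpec",
    "NoiseModel",
    "SyntheticCohortConfig",
    "GroundTruth",
    "default_channels",
    "generate_cardiac_waveform",
    "simulate_layer_flows",
    "simulate_layer_volumes",
    "mix_channels",
    "speckle_visibility",
    "synthesize_frames",
    "synthesize_dark_frames",
    "synthesize_noise_only_frames",
    "expected_segment_ratios",
    "flow_ratio_during_pre",
]

# Illumination-safety bookkeeping (device-level constants used by the
# acceptance arithmetic): 830 nm skin exposure limit and the emulated source.
ANSI_SKIN_LIMIT_MW_PER_MM2 = 3.63
LASER_POWER_MW = 60.0
SPOT_DIAMETER_MM = 5.0
#: One-dimensional speckle-to-pixel length ratio of the emulated optics.
SPECKLE_TO_PIXEL_RATIO = 0.3

DEFAULT_SD_DISTANCES_CM = (0.6, 1.0, 1.3, 1.6, 2.0, 2.3, 2.6)
DEFAULT_OCCLUSION_WINDOW_S = (8.0, 16.0)
#: Alternative preset (some protocol descriptions give 8-17 s).
METHODS_OCCLUSION_WINDOW_S = (8.0, 17.0)

_DEFAULT_SCALP_SENSITIVITY = (0.90, 0.75, 0.60, 0.45, 0.30, 0.20, 0.10)
#: Intensity fall-off length with S-D distance (cm); scaled so the farthest
#: default channel sits near, but above, the dark-noise floor.
_INTENSITY_RHO0_CM = 0.55


def irradiance_mw_per_mm2(
    power_mw: float = LASER_POWER_MW, spot_diameter_mm: float = SPOT_DIAMETER_MM
) -> float:
    """Average irradiance of a beam spread over a circular spot."""
    if power_mw <= 0 or spot_diameter_mm <= 0:
        raise InvalidParameterError("power and spot diameter must be positive")
    radius = spot_diameter_mm / 2.0
    return power_mw / (math.pi * radius**2)


def speckle_density_per_pixel(ratio: float = SPECKLE_TO_PIXEL_RATIO) -> float:
    """Areal speckle density implied by a 1-D speckle-to-pixel length ratio."""
    if ratio <= 0:
        raise InvalidParameterError("speckle-to-pixel ratio must be positive")
    return ratio**2


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChannelSpec:
    """One fiber channel: geometry, layer sensitivities, baseline brightness."""

    sd_distance_cm: float
    scalp_sensitivity: float
    brain_sensitivity: float
    mean_counts: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.scalp_sensitivity <= 1.0):
            raise InvalidParameterError("scalp_sensitivity must lie in [0, 1]")
        if not (0.0 <= self.brain_sensitivity <= 1.0):
            raise InvalidParameterError("brain_sensitivity must lie in [0, 1]")
        if abs(self.scalp_sensitivity + self.brain_sensitivity - 1.0) > 1e-9:
            raise InvalidParameterError(
                "scalp_sensitivity + brain_sensitivity must equal 1 (normalized mixing)"
            )
        if self.mean_counts <= 0:
            raise InvalidParameterError("mean_counts must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise parameters (counts unless noted).

    ``shot_noise=False`` removes Poisson detection entirely (pure gamma
    speckle ensemble) — used for "noiseless" oracle cohorts, in which case
    :meth:`true_calibration` reports gamma = 0 so no shot term is subtracted.

    ``speckle_sampling`` selects the speckle ensemble: ``"gamma"`` (default)
    draws independent gamma variates with shape ``1/K^2``; ``"deterministic"``
    emits a two-point ensemble ``mu_e * (1 +- K)`` whose first two moments
    equal the targets exactly — the noiseless high-count limit used by the
    closed-form ratio-oracle tests (requires ``shot_noise=False``).
    """

    read_sigma: float = 2.0
    dark_offset: float = 100.0
    conversion_factor: float = 0.46  # e-/count
    gain: float = 1.0
    bit_depth: int = 16
    shot_noise: bool = True
    speckle_sampling: str = "gamma"

    def __post_init__(self) -> None:
        if self.read_sigma < 0:
            raise InvalidParameterError("read_sigma must be non-negative")
        if self.speckle_sampling not in ("gamma", "deterministic"):
            raise InvalidParameterError(
                f"unknown speckle_sampling {self.speckle_sampling!r}"
            )
        if self.speckle_sampling == "deterministic" and self.shot_noise:
            raise InvalidParameterError(
                "deterministic speckle sampling requires shot_noise=False"
            )
        if self.conversion_factor <= 0:
            raise InvalidParameterError("conversion_factor must be positive")
        if self.gain <= 0:
            raise InvalidParameterError("gain must be positive")
        if self.bit_depth not in (8, 10, 12, 14, 16):
            raise InvalidParameterError(f"unsupported bit depth {self.bit_depth}")

    @property
    def gamma(self) -> float:
        return self.gain / self.conversion_factor

    @property
    def saturation(self) -> int:
        return 2**self.bit_depth - 1

    def true_calibration(self, include_quantization: bool = False) -> CameraCalibration:
        """The calibration that exactly matches this generator's noise model."""
        dark_var = self.read_sigma**2
        if self.read_sigma > 0:
            dark_var += 1.0 / 12.0  # quantization of the dark counts
        if self.shot_noise:
            return CameraCalibration(
                gain=self.gain,
                conversion_factor=self.conversion_factor,
                dark_offset=self.dark_offset,
                dark_variance=dark_var,
                include_quantization=include_quantization,
            )
        # gamma = gain/CF must be 0 when no Poisson stage exists
        return CameraCalibration(
            gain=0.0,
            conversion_factor=1.0,
            dark_offset=self.dark_offset,
            dark_variance=dark_var,
            include_quantization=include_quantization,
        )


def default_channels(
    sd_distances_cm: Sequence[float] = DEFAULT_SD_DISTANCES_CM,
    scalp_sensitivities: Sequence[float] = _DEFAULT_SCALP_SENSITIVITY,
    far_channel_counts: float = 30.0,
    rho0_cm: float = _INTENSITY_RHO0_CM,
) -> tuple[ChannelSpec, ...]:
    """Default 7-channel profile: monotone sensitivities and an exponential
    intensity fall-off placing the farthest channel near the noise floor."""
    sd = np.asarray(sd_distances_cm, float)
    ws = np.asarray(scalp_sensitivities, float)
    if sd.shape != ws.shape:
        raise InvalidParameterError("sd_distances and sensitivities length mismatch")
    source = far_channel_counts / math.exp(-sd[-1] / rho0_cm)
    counts = source * np.exp(-sd / rho0_cm)
    return tuple(
        ChannelSpec(
            sd_distance_cm=float(d),
            scalp_sensitivity=float(w),
            brain_sensitivity=float(1.0 - w),
            mean_counts=float(c),
        )
        for d, w, c in zip(sd, ws, counts)
    )


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Full description of a synthetic cohort acquisition.

    ``heart_rate_hz`` may be a scalar (shared by all subjects) or a sequence
    of length ``n_subjects``. ``occlusion_window_s=None`` denotes a control
    recording (non-occlusive press).
    """

    n_subjects: int = 1
    seed: int = 0
    duration_s: float = 24.0
    frame_rate_hz: float = 65.0
    exposure_s: float = 0.008
    channels: tuple[ChannelSpec, ...] = field(default_factory=default_channels)
    heart_rate_hz: float | tuple[float, ...] = 1.0
    pulsatility: float = 0.1
    occlusion_window_s: tuple[float, float] | None = DEFAULT_OCCLUSION_WINDOW_S
    scalp_suppression: float = 0.35
    volume_suppression: float = 0.7
    beta: float = 0.5
    noise: NoiseModel = field(default_factory=NoiseModel)
    ramp_s: float = 0.5
    tau_c_baseline_s: float = 1e-3
    volume_pulsatility: float = 0.04
    bvi_scale: float = 0.05
    region_shape: tuple[int, int] = (48, 48)
    hyperemia_overshoot: float = 0.0
    hyperemia_tau_s: float = 2.0

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)) or isinstance(self.seed, bool):
            raise InvalidParameterError(f"seed must be an integer, got {self.seed!r}")
        if self.n_subjects < 1:
            raise InvalidParameterError("n_subjects must be >= 1")
        if self.duration_s <= 0 or self.frame_rate_hz <= 0 or self.exposure_s <= 0:
            raise InvalidParameterError("duration, frame rate, exposure must be positive")
        if not (0.0 < self.beta <= 1.0):
            raise InvalidParameterError("beta must lie in (0, 1]")
        if not (0.0 <= self.pulsatility < 1.0):
            raise InvalidParameterError("pulsatility must lie in [0, 1)")
        if not (0.0 <= self.scalp_suppression <= 1.0):
            raise InvalidParameterError("scalp_suppression must lie in [0, 1]")
        if not (0.0 <= self.volume_suppression <= 1.0):
            raise InvalidParameterError("volume_suppression must lie in [0, 1]")
        object.__setattr__(self, "channels", tuple(self.channels))
        if not self.channels:
            raise InvalidParameterError("at least one channel is required")
        sds = [c.sd_distance_cm for c in self.channels]
        if any(b <= a for a, b in zip(sds, sds[1:])):
            raise InvalidParameterError("channel sd_distance_cm must strictly increase")
        ws = [c.scalp_sensitivity for c in self.channels]
        wb = [c.brain_sensitivity for c in self.channels]
        if len(ws) > 1 and (
            any(b >= a for a, b in zip(ws, ws[1:]))
            or any(b < a for a, b in zip(wb, wb[1:]))
        ):
            warnings.warn(
                "scalp sensitivity is not strictly decreasing (or brain sensitivity "
                "not non-decreasing) with S-D distance",
                UserWarning,
                stacklevel=2,
            )
        if self.occlusion_window_s is not None:
            t0, t1 = self.occlusion_window_s
            if not (0.0 <= t0 < t1 <= self.duration_s):
                raise InvalidParameterError(
                    "occlusion window must lie inside [0, duration_s]"
                )
            if t1 - t0 < 2 * self.ramp_s:
                raise InvalidParameterError(
                    "occlusion window shorter than twice the edge ramp"
                )
        hr = self.heart_rate_hz
        if isinstance(hr, (list, tuple, np.ndarray)):
            hr = tuple(float(h) for h in hr)
            object.__setattr__(self, "heart_rate_hz", hr)
            if len(hr) != self.n_subjects:
                raise InvalidParameterError(
                    "heart_rate_hz sequence must have length n_subjects"
                )
            if any(h <= 0 for h in hr):
                raise InvalidParameterError("heart rates must be positive")
        elif hr <= 0:
            raise InvalidParameterError("heart_rate_hz must be positive")

    # -- derived quantities ------------------------------------------------

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def frame_shape(self) -> tuple[int, int]:
        rows, cols = self.region_shape
        return rows, cols * self.n_channels

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames, dtype=float) / self.frame_rate_hz

    def subject_heart_rate(self, subject_index: int) -> float:
        hr = self.heart_rate_hz
        if isinstance(hr, tuple):
            return hr[subject_index]
        return float(hr)

    def scalp_weights(self) -> np.ndarray:
        return np.array([c.scalp_sensitivity for c in self.channels])

    def brain_weights(self) -> np.ndarray:
        return np.array([c.brain_sensitivity for c in self.channels])

    def layout(self) -> ChannelLayout:
        """Side-by-side channel rectangles, channel ids 1..n."""
        rows, cols = self.region_shape
        regions = [
            ChannelRegion(
                channel_id=i + 1,
                sd_distance_cm=c.sd_distance_cm,
                row0=0,
                row1=rows,
                col0=i * cols,
                col1=(i + 1) * cols,
            )
            for i, c in enumerate(self.channels)
        ]
        return ChannelLayout(regions=tuple(regions))

    def control(self) -> "SyntheticCohortConfig":
        """The matched control configuration (no occlusion window)."""
        return replace(self, occlusion_window_s=None)

    def subject_rng(self, subject_index: int) -> np.random.Generator:
        if not (0 <= subject_index < self.n_subjects):
            raise InvalidParameterError(
                f"subject_index {subject_index} outside cohort of {self.n_subjects}"
            )
        return np.random.default_rng([int(self.seed), int(subject_index)])


@dataclass
class GroundTruth:
    """Analytically known per-channel quantities for one synthetic subject."""

    subject_index: int
    channel_ids: np.ndarray
    sd_distances_cm: np.ndarray
    t: np.ndarray
    k_true_sq: np.ndarray      # (n_channels, n_frames), in (0, beta]
    bfi_true: np.ndarray       # proportional to composite flow
    bvi_true: np.ndarray       # log10 attenuation
    expected_ratio_mean_ba: np.ndarray
    expected_ratio_mean_ca: np.ndarray

    def to_frame(self, subject: int | None = None) -> pd.DataFrame:
        parts = []
        for i, cid in enumerate(self.channel_ids):
            parts.append(
                pd.DataFrame(
                    {
                        "channel": int(cid),
                        "t": self.t,
                        "k_true_sq": self.k_true_sq[i],
                        "bfi_true": self.bfi_true[i],
                        "bvi_true": self.bvi_true[i],
                    }
                )
            )
        out = pd.concat(parts, ignore_index=True)
        out.insert(0, "subject", self.subject_index if subject is None else subject)
        return out

    def ratios_to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": self.subject_index,
                "channel": self.channel_ids.astype(int),
                "sd_distance_cm": self.sd_distances_cm,
                "expected_ratio_mean_ba": self.expected_ratio_mean_ba,
                "expected_ratio_mean_ca": self.expected_ratio_mean_ca,
            }
        )


# ---------------------------------------------------------------------------
# Forward-model building blocks
# ---------------------------------------------------------------------------

_REF_GRID = np.linspace(0.0, 1.0, 4096, endpoint=False)


def _cardiac_shape(
    phase: np.ndarray,
    systolic_width: float,
    dicrotic_phase: float,
    dicrotic_amplitude: float,
    dicrotic_width: float,
) -> np.ndarray:
    """Raw periodic pulse shape: systolic Gaussian + dicrotic bump, wrapped."""
    centers = (0.15, 0.15 + dicrotic_phase)
    amps = (1.0, dicrotic_amplitude)
    widths = (systolic_width, dicrotic_width)
    out = np.zeros_like(phase)
    for c, a, w in zip(centers, amps, widths):
        for k in (-1.0, 0.0, 1.0):
            out += a * np.exp(-0.5 * ((phase - c + k) / w) ** 2)
    return out


def generate_cardiac_waveform(
    heart_rate_hz: float,
    pulsatility: float,
    t,
    systolic_width: float = 0.10,
    dicrotic_phase: float = 0.35,
    dicrotic_amplitude: float = 0.25,
    dicrotic_width: float = 0.12,
) -> np.ndarray:
    """Unit-mean periodic cardiac waveform sampled at times ``t``.

    The shape is a systolic peak plus a dicrotic bump (two wrapped Gaussians
    per cycle), renormalized so the cycle mean is exactly 1 and the
    peak-to-trough span equals ``2 * pulsatility``. ``pulsatility = 0`` gives
    a constant 1.
    """
    if heart_rate_hz <= 0:
        raise InvalidParameterError("heart_rate_hz must be positive")
    if not (0.0 <= pulsatility < 1.0):
        raise InvalidParameterError("pulsatility must lie in [0, 1)")
    t = np.asarray(t, dtype=np.float64)
    if pulsatility == 0.0:
        return np.ones_like(t)
    shape_args = (systolic_width, dicrotic_phase, dicrotic_amplitude, dicrotic_width)
    ref = _cardiac_shape(_REF_GRID, *shape_args)
    mean, lo, hi = ref.mean(), ref.min(), ref.max()
    phase = np.mod(t * heart_rate_hz, 1.0)
    g = _cardiac_shape(phase, *shape_args)
    # zero-mean, span-2 normalized modulation
    h = 2.0 * (g - mean) / (hi - lo)
    return 1.0 + pulsatility * h


def _raised_cosine_window(
    t: np.ndarray, window: tuple[float, float], depth_factor: float, ramp_s: float
) -> np.ndarray:
    """Multiplicative factor: 1 outside the window, ``depth_factor`` in the
    plateau, raised-cosine ramps of ``ramp_s`` just inside each edge."""
    t0, t1 = window
    r = np.zeros_like(t)
    if ramp_s > 0:
        down = (t >= t0) & (t < t0 + ramp_s)
        r[down] = 0.5 * (1.0 - np.cos(np.pi * (t[down] - t0) / ramp_s))
        up = (t > t1 - ramp_s) & (t <= t1)
        r[up] = 0.5 * (1.0 - np.cos(np.pi * (t1 - t[up]) / ramp_s))
    plateau = (t >= t0 + ramp_s) & (t <= t1 - ramp_s)
    r[plateau] = 1.0
    return 1.0 + (depth_factor - 1.0) * r


def simulate_layer_flows(
    config: SyntheticCohortConfig, subject_index: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scalp and brain flow-index traces for one subject.

    Both layers share the subject's cardiac modulation; only the scalp layer
    is multiplied by the occlusion factor (the brain trace is unaffected by
    the occlusion window). Returns ``(t, scalp_flow, brain_flow)``.
    """
    t = config.times()
    hr = config.subject_heart_rate(subject_index)
    card = generate_cardiac_waveform(hr, config.pulsatility, t)
    brain = card.copy()
    scalp = card.copy()
    if config.occlusion_window_s is not None:
        scalp = scalp * _raised_cosine_window(
            t, config.occlusion_window_s, config.scalp_suppression, config.ramp_s
        )
        if config.hyperemia_overshoot > 0:
            t1 = config.occlusion_window_s[1]
            post = t > t1
            scalp[post] *= 1.0 + config.hyperemia_overshoot * np.exp(
                -(t[post] - t1) / config.hyperemia_tau_s
            )
    return t, scalp, brain


def simulate_layer_volumes(
    config: SyntheticCohortConfig, subject_index: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scalp and brain blood-volume traces (relative, baseline mean 1)."""
    t = config.times()
    hr = config.subject_heart_rate(subject_index)
    card = generate_cardiac_waveform(hr, config.volume_pulsatility, t)
    brain = card.copy()
    scalp = card.copy()
    if config.occlusion_window_s is not None:
        scalp = scalp * _raised_cosine_window(
            t, config.occlusion_window_s, config.volume_suppression, config.ramp_s
        )
    return t, scalp, brain


def mix_channels(
    config: SyntheticCohortConfig, scalp_flow: np.ndarray, brain_flow: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Linear two-compartment mixing into per-channel composite flow.

    ``composite[ch] = w_scalp[ch] * scalp + w_brain[ch] * brain``; the
    decorrelation rate is ``1/tau_c = composite / tau_c_baseline_s`` (a global
    proportionality, so baseline tau_c equals the configured value at
    composite flow 1). Returns ``(composite, decorrelation_rate_hz)``.
    """
    ws = config.scalp_weights()[:, None]
    wb = config.brain_weights()[:, None]
    composite = ws * scalp_flow[None, :] + wb * brain_flow[None, :]
    rate = composite / config.tau_c_baseline_s
    return composite, rate


def speckle_visibility(exposure_s, tau_c_s, beta: float = 1.0):
    """Camera-integrated squared speckle contrast.

    ``K_true^2 = beta * (exp(-2x) - 1 + 2x) / (2 x^2)`` with
    ``x = exposure / tau_c``; strictly decreasing in ``x`` with limit ``beta``
    as ``x -> 0``. A series expansion is used for small ``x`` for numerical
    stability.
    """
    if beta <= 0 or beta > 1:
        raise InvalidParameterError("beta must lie in (0, 1]")
    exposure = np.asarray(exposure_s, dtype=np.float64)
    tau = np.asarray(tau_c_s, dtype=np.float64)
    if np.any(exposure <= 0) or np.any(tau <= 0):
        raise InvalidParameterError("exposure and tau_c must be positive")
    x = exposure / tau
    small = x < 1e-4
    safe = np.where(small, 1.0, x)
    exact = (np.expm1(-2.0 * safe) + 2.0 * safe) / (2.0 * safe**2)
    taylor = 1.0 - (2.0 / 3.0) * x + (1.0 / 3.0) * x**2
    out = beta * np.where(small, taylor, exact)
    if np.isscalar(exposure_s) and np.isscalar(tau_c_s):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Frame synthesis
# ---------------------------------------------------------------------------

_CHUNK_FRAMES = 200  # time-axis chunking to bound peak memory


def _true_signals(config: SyntheticCohortConfig, subject_index: int):
    """Noise-free per-channel k_true^2, composite flow and bvi_true."""
    t, scalp, brain = simulate_layer_flows(config, subject_index)
    composite, _ = mix_channels(config, scalp, brain)
    tau_c = config.tau_c_baseline_s / composite
    k_true_sq = speckle_visibility(config.exposure_s, tau_c, config.beta)
    _, v_scalp, v_brain = simulate_layer_volumes(config, subject_index)
    ws = config.scalp_weights()[:, None]
    wb = config.brain_weights()[:, None]
    composite_vol = ws * v_scalp[None, :] + wb * v_brain[None, :]
    bvi_true = config.bvi_scale * (composite_vol - 1.0)
    return t, composite, k_true_sq, bvi_true


def synthesize_frames(
    config: SyntheticCohortConfig, subject_index: int
) -> tuple[FrameStack, GroundTruth]:
    """Render one subject's frame stack and its ground truth.

    Per frame and channel region, photoelectron means follow
    ``mu_e(t) = mu_e0 * 10**(-bvi_true(t))`` with the speckle ensemble drawn
    from a gamma distribution of shape ``1/K_true^2(t)``; Poisson detection,
    count conversion, dark offset, Gaussian read noise, rounding and clipping
    follow. Identical (config, subject, seed) gives bit-identical stacks.
    """
    rng = config.subject_rng(subject_index)
    noise = config.noise
    t, composite, k_true_sq, bvi_true = _true_signals(config, subject_index)
    nt = config.n_frames
    rows, cols = config.region_shape
    npix = rows * cols
    frames = np.empty((nt, *config.frame_shape), dtype=np.uint16)
    ceiling = noise.saturation
    count_scale = noise.gain / noise.conversion_factor

    for i, ch in enumerate(config.channels):
        mu_counts = ch.mean_counts * np.power(10.0, -bvi_true[i])
        mu_e = mu_counts / count_scale
        shape_t = 1.0 / k_true_sq[i]
        scale_t = mu_e * k_true_sq[i]
        col0 = i * cols
        for start in range(0, nt, _CHUNK_FRAMES):
            stop = min(start + _CHUNK_FRAMES, nt)
            n = stop - start
            if noise.speckle_sampling == "deterministic":
                # moment-exact two-point ensemble mu_e * (1 +- K); npix even
                sign = np.where(np.arange(npix) % 2 == 0, 1.0, -1.0)
                k = np.sqrt(k_true_sq[i][start:stop, None])
                lam = mu_e[start:stop, None] * (1.0 + k * sign[None, :])
            else:
                lam = rng.gamma(
                    shape_t[start:stop, None], scale_t[start:stop, None], size=(n, npix)
                )
            electrons = rng.poisson(lam).astype(np.float64) if noise.shot_noise else lam
            counts = electrons * count_scale + noise.dark_offset
            if noise.read_sigma > 0:
                counts += rng.normal(0.0, noise.read_sigma, size=(n, npix))
            np.rint(counts, out=counts)
            np.clip(counts, 0, ceiling, out=counts)
            frames[start:stop, :, col0 : col0 + cols] = counts.astype(
                np.uint16
            ).reshape(n, rows, cols)

    saturated = np.mean(frames == ceiling)
    if saturated > 0.01:
        warnings.warn(
            f"{saturated:.1%} of synthesized pixels are saturated at {ceiling}",
            SaturationWarning,
            stacklevel=2,
        )

    stack = FrameStack(
        frames=frames,
        frame_rate_hz=config.frame_rate_hz,
        exposure_s=config.exposure_s,
        bit_depth=noise.bit_depth,
    )
    ratio_ba, ratio_ca = expected_segment_ratios(config, subject_index)
    truth = GroundTruth(
        subject_index=subject_index,
        channel_ids=np.arange(1, config.n_channels + 1),
        sd_distances_cm=np.array([c.sd_distance_cm for c in config.channels]),
        t=t,
        k_true_sq=k_true_sq,
        bfi_true=composite,
        bvi_true=bvi_true,
        expected_ratio_mean_ba=ratio_ba,
        expected_ratio_mean_ca=ratio_ca,
    )
    return stack, truth


def synthesize_dark_frames(
    noise: NoiseModel,
    n_frames: int,
    frame_shape: tuple[int, int] = (48, 336),
    seed: int = 0,
    frame_rate_hz: float = 65.0,
    exposure_s: float = 0.008,
) -> FrameStack:
    """Dark stack: offset + Gaussian read noise, quantized and clipped."""
    if n_frames < 2:
        raise InvalidParameterError("need at least 2 dark frames")
    rng = np.random.default_rng(seed)
    counts = np.full((n_frames, *frame_shape), float(noise.dark_offset))
    if noise.read_sigma > 0:
        counts += rng.normal(0.0, noise.read_sigma, size=counts.shape)
    np.rint(counts, out=counts)
    np.clip(counts, 0, noise.saturation, out=counts)
    return FrameStack(
        frames=counts.astype(np.uint16),
        frame_rate_hz=frame_rate_hz,
        exposure_s=exposure_s,
        bit_depth=noise.bit_depth,
    )


def synthesize_noise_only_frames(
    mean_counts: float,
    noise: NoiseModel,
    n_frames: int,
    frame_shape: tuple[int, int] = (48, 48),
    seed: int = 0,
    frame_rate_hz: float = 65.0,
    exposure_s: float = 0.008,
) -> FrameStack:
    """Shot + read noise stack with no speckle component (constant photon mean).

    The per-pixel variance is purely Poisson (gamma-free), so the
    noise-adjusted contrast of such stacks should be statistically
    indistinguishable from zero.
    """
    if n_frames < 2:
        raise InvalidParameterError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    count_scale = noise.gain / noise.conversion_factor
    mu_e = mean_counts / count_scale
    electrons = rng.poisson(mu_e, size=(n_frames, *frame_shape)).astype(np.float64)
    counts = electrons * count_scale + noise.dark_offset
    if noise.read_sigma > 0:
        counts += rng.normal(0.0, noise.read_sigma, size=counts.shape)
    np.rint(counts, out=counts)
    np.clip(counts, 0, noise.saturation, out=counts)
    return FrameStack(
        frames=counts.astype(np.uint16),
        frame_rate_hz=frame_rate_hz,
        exposure_s=exposure_s,
        bit_depth=noise.bit_depth,
    )


# ---------------------------------------------------------------------------
# Closed-form oracle
# ---------------------------------------------------------------------------


def flow_ratio_during_pre(scalp_weight: float, scalp_suppression: float) -> float:
    """Ramp-free algebraic during/pre composite-flow ratio: 1 - w(1 - s)."""
    return 1.0 - scalp_weight * (1.0 - scalp_suppression)


def expected_segment_ratios(
    config: SyntheticCohortConfig,
    subject_index: int = 0,
    segments: tuple[float, float, float, float] | None = None,
    on: str = "nbfi",
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form per-channel during/pre and post/pre segment ratios.

    Evaluates the generator's deterministic composite-flow formula on the
    acquisition time grid — no speckle ensemble, no camera noise — and
    integrates it over the three segments. With ``on="nbfi"`` (default) the
    flow is first mapped through the visibility function to BFI and min-max
    normalized over the record, mirroring exactly what the analysis pipeline
    computes on ideal data; ``on="flow"`` returns plain composite-flow
    ratios (ramp-free closed form ``1 - w(1 - s)``).

    Control configurations (no occlusion window) return ratios identically 1.
    """
    if on not in ("nbfi", "flow"):
        raise InvalidParameterError(f"unknown ratio basis {on!r}")
    n_ch = config.n_channels
    if config.occlusion_window_s is None:
        ones = np.ones(n_ch)
        return ones, ones.copy()
    if segments is None:
        t0, t1 = config.occlusion_window_s
        segments = (0.0, t0, t1, config.duration_s)
    s0, s1, s2, s3 = segments
    t, scalp, brain = simulate_layer_flows(config, subject_index)
    composite, _ = mix_channels(config, scalp, brain)
    if on == "flow":
        traces = composite
    else:
        tau_c = config.tau_c_baseline_s / composite
        k2 = speckle_visibility(config.exposure_s, tau_c, config.beta)
        bfi = 1.0 / k2
        lo = bfi.min(axis=1, keepdims=True)
        hi = bfi.max(axis=1, keepdims=True)
        traces = (bfi - lo) / (hi - lo)
    mask_a = (t >= s0) & (t < s1)
    mask_b = (t >= s1) & (t < s2)
    mask_c = (t >= s2) & (t <= s3)
    mean_a = traces[:, mask_a].mean(axis=1)
    mean_b = traces[:, mask_b].mean(axis=1)
    mean_c = traces[:, mask_c].mean(axis=1)
    return mean_b / mean_a, mean_c / mean_a
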