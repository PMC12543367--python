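"""Speckle contrast and hemodynamic-index extraction from camera frame stacks.

This module converts 16-bit multi-frame image stacks, segmented into
fiber-channel regions, into per-channel time series of:

* raw squared speckle contrast ``K_raw^2 = var(I) / mean(I)^2`` over the
  spatial pixel ensemble of each channel region,
* noise-adjusted squared contrast
  ``K_adj^2 = K_raw^2 - K_shot^2 - K_quant^2 - K_cam^2`` with
  ``K_shot^2 = gamma / mu``, ``K_quant^2 = 1 / (12 mu^2)`` (optional) and
  ``K_cam^2 = dark_variance / mu^2``,
* blood flow index ``BFI = 1 / K_adj^2`` and its min-max normalization nBFI,
* blood volume index ``BVI = log10(I0 / mu(t))`` (or its linear
  approximation) and its normalization nBVI.

All noise arithmetic is carried out in analog-to-digital units (camera
counts). One contrast value is produced per frame per channel, over the whole
channel region. Frames whose offset-subtracted mean is non-positive, or whose
adjusted contrast falls at or below ``FLOOR_EPSILON``, are flagged invalid
rather than raising: downstream statistics skip them and report the fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    CalibrationError,
    DegenerateTraceError,
    InvalidParameterError,
    LayoutError,
)

__all__ = [
    "FLOOR_EPSILON",
    "FrameStack",
    "ChannelRegion",
    "ChannelLayout",
    "CameraCalibration",
    "ChannelContrast",
    "ContrastSeries",
    "ChannelHemo",
    "HemoSeries",
    "split_channels",
    "compute_dark_calibration",
    "raw_contrast",
    "noise_corrected_contrast",
    "bfi_from_contrast",
    "normalize_trace",
    "bvi_from_intensity",
    "compute_contrast_series",
    "compute_hemo_series",
]

#: Adjusted squared contrast at or below this value is treated as noise-floored
#: and flagged invalid (the papers in this area give no rule for the regime
#: where photon counts approach the camera noise floor).
FLOOR_EPSILON = 1e-6

#: Default linear-BVI coefficient: first-order Taylor coefficient of
#: log10(I0/mu) around mu = I0.
LINEAR_BVI_COEFFICIENT = 1.0 / math.log(10.0)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrameStack:
    """Time-ordered stack of integer camera frames with acquisition metadata.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, rows, cols)`` with integer counts in
        ``[0, 2**bit_depth - 1]``.
    frame_rate_hz
        Acquisition rate in frames per second.
    exposure_s
        Camera exposure time per frame, in seconds.
    bit_depth
        ADC bit depth; 16 for the cameras targeted here.
    """

    frames: np.ndarray
    frame_rate_hz: float
    exposure_s: float
    bit_depth: int = 16

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise InvalidParameterError(
                f"frames must be 3-D (time, rows, cols); got ndim={frames.ndim}"
            )
        if frames.shape[0] < 2:
            raise InvalidParameterError("a frame stack needs at least 2 frames")
        if not np.issubdtype(frames.dtype, np.integer):
            raise InvalidParameterError(
                f"frames must hold integer counts; got dtype {frames.dtype}"
            )
        if self.frame_rate_hz <= 0:
            raise InvalidParameterError("frame_rate_hz must be positive")
        if self.exposure_s <= 0:
            raise InvalidParameterError("exposure_s must be positive")
        ceiling = 2**self.bit_depth - 1
        if frames.min() < 0 or frames.max() > ceiling:
            raise InvalidParameterError(
                f"counts outside [0, {ceiling}] for bit_depth={self.bit_depth}"
            )
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    def times(self) -> np.ndarray:
        """Frame timestamps in seconds from record start."""
        return np.arange(self.n_frames, dtype=float) / self.frame_rate_hz


@dataclass(frozen=True)
class ChannelRegion:
    """A rectangular pixel region for one fiber channel.

    Coordinates are 0-based, half-open: rows ``[row0, row1)``, columns
    ``[col0, col1)``.
    """

    channel_id: int
    sd_distance_cm: float
    row0: int
    row1: int
    col0: int
    col1: int

    def __post_init__(self) -> None:
        if self.row0 >= self.row1 or self.col0 >= self.col1:
            raise LayoutError(
                f"channel {self.channel_id}: empty rectangle "
                f"({self.row0}:{self.row1}, {self.col0}:{self.col1})"
            )
        if self.row0 < 0 or self.col0 < 0:
            raise LayoutError(f"channel {self.channel_id}: negative coordinates")
        if self.sd_distance_cm <= 0:
            raise LayoutError(f"channel {self.channel_id}: non-positive S-D distance")

    @property
    def n_pixels(self) -> int:
        return (self.row1 - self.row0) * (self.col1 - self.col0)

    def overlaps(self, other: "ChannelRegion") -> bool:
        return (
            self.row0 < other.row1
            and other.row0 < self.row1
            and self.col0 < other.col1
            and other.col0 < self.col1
        )


@dataclass(frozen=True)
class ChannelLayout:
    """Set of pairwise-disjoint channel regions with increasing S-D distance."""

    regions: tuple[ChannelRegion, ...]

    def __post_init__(self) -> None:
        regions = tuple(self.regions)
        if not regions:
            raise LayoutError("layout must contain at least one region")
        ids = [r.channel_id for r in regions]
        if len(set(ids)) != len(ids):
            raise LayoutError("duplicate channel ids in layout")
        ordered = sorted(regions, key=lambda r: r.channel_id)
        sds = [r.sd_distance_cm for r in ordered]
        if any(b <= a for a, b in zip(sds, sds[1:])):
            raise LayoutError("sd_distance_cm must strictly increase with channel_id")
        for i, a in enumerate(ordered):
            for b in ordered[i + 1 :]:
                if a.overlaps(b):
                    raise LayoutError(
                        f"regions for channels {a.channel_id} and {b.channel_id} overlap"
                    )
        object.__setattr__(self, "regions", tuple(ordered))

    def validate_for(self, frame_shape: tuple[int, int]) -> None:
        """Raise :class:`LayoutError` if any region exceeds the frame bounds."""
        rows, cols = frame_shape
        for r in self.regions:
            if r.row1 > rows or r.col1 > cols:
                raise LayoutError(
                    f"channel {r.channel_id} rectangle exceeds frame bounds "
                    f"{frame_shape}"
                )

    @property
    def channel_ids(self) -> tuple[int, ...]:
        return tuple(r.channel_id for r in self.regions)

    @property
    def sd_distances_cm(self) -> tuple[float, ...]:
        return tuple(r.sd_distance_cm for r in self.regions)


@dataclass(frozen=True)
class CameraCalibration:
    """Camera noise calibration, expressed in analog-to-digital units.

    ``gamma = gain / conversion_factor`` converts the electron-domain shot
    noise into count units (``K_shot^2 = gamma / mu``). ``dark_offset`` and
    ``dark_variance`` come from dark-frame statistics. ``gamma`` may be passed
    explicitly, but must then agree with ``gain / conversion_factor`` to
    within 1e-12.
    """

    gain: float
    conversion_factor: float
    dark_offset: float = 0.0
    dark_variance: float = 0.0
    include_quantization: bool = False
    gamma: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.conversion_factor <= 0:
            raise CalibrationError("conversion_factor must be positive")
        if self.dark_variance < 0:
            raise CalibrationError("dark_variance must be non-negative")
        expected = self.gain / self.conversion_factor
        if self.gamma is None:
            object.__setattr__(self, "gamma", expected)
        elif abs(self.gamma - expected) > 1e-12:
            raise CalibrationError(
                f"gamma={self.gamma} inconsistent with gain/conversion_factor={expected}"
            )


# ---------------------------------------------------------------------------
# Series containers
# ---------------------------------------------------------------------------


@dataclass
class ChannelContrast:
    """Per-frame contrast quantities for one channel."""

    channel_id: int
    sd_distance_cm: float
    t: np.ndarray
    mu: np.ndarray          # mean counts after dark-offset subtraction
    var: np.ndarray         # unbiased spatial variance of raw counts
    k_raw_sq: np.ndarray
    k_adj_sq: np.ndarray
    valid: np.ndarray       # bool per frame

    @property
    def invalid_fraction(self) -> float:
        return 1.0 - float(np.mean(self.valid))


@dataclass
class ContrastSeries:
    channels: list[ChannelContrast]
    frame_rate_hz: float
    exposure_s: float

    def channel(self, channel_id: int) -> ChannelContrast:
        for ch in self.channels:
            if ch.channel_id == channel_id:
                return ch
        raise KeyError(f"no channel {channel_id}")


@dataclass
class ChannelHemo:
    """Per-frame hemodynamic indices for one channel."""

    channel_id: int
    sd_distance_cm: float
    t: np.ndarray
    mu: np.ndarray
    k_raw_sq: np.ndarray
    k_adj_sq: np.ndarray
    valid: np.ndarray
    bfi: np.ndarray
    nbfi: np.ndarray
    bvi: np.ndarray
    nbvi: np.ndarray
    baseline_i0: float

    @property
    def invalid_fraction(self) -> float:
        return 1.0 - float(np.mean(self.valid))


@dataclass
class HemoSeries:
    """Per-channel BFI/nBFI/BVI/nBVI time series for one recording."""

    channels: list[ChannelHemo]
    frame_rate_hz: float
    exposure_s: float
    measurement_period_s: float

    def channel(self, channel_id: int) -> ChannelHemo:
        for ch in self.channels:
            if ch.channel_id == channel_id:
                return ch
        raise KeyError(f"no channel {channel_id}")

    @property
    def channel_ids(self) -> list[int]:
        return [ch.channel_id for ch in self.channels]

    def to_frame(self, subject: int | None = None) -> pd.DataFrame:
        """Tidy long-format table (one row per channel per frame)."""
        parts = []
        for ch in self.channels:
            df = pd.DataFrame(
                {
                    "channel": ch.channel_id,
                    "sd_distance_cm": ch.sd_distance_cm,
                    "t": ch.t,
                    "mu": ch.mu,
                    "k_raw_sq": ch.k_raw_sq,
                    "k_adj_sq": ch.k_adj_sq,
                    "bfi": ch.bfi,
                    "nbfi": ch.nbfi,
                    "bvi": ch.bvi,
                    "nbvi": ch.nbvi,
                    "valid": ch.valid.astype(int),
                    "baseline_i0": ch.baseline_i0,
                }
            )
            parts.append(df)
        out = pd.concat(parts, ignore_index=True)
        if subject is not None:
            out.insert(0, "subject", subject)
        return out

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        frame_rate_hz: float,
        exposure_s: float,
    ) -> "HemoSeries":
        channels = []
        for cid, sub in df.groupby("channel", sort=True):
            sub = sub.sort_values("t")
            channels.append(
                ChannelHemo(
                    channel_id=int(cid),
                    sd_distance_cm=float(sub["sd_distance_cm"].iloc[0]),
                    t=sub["t"].to_numpy(float),
                    mu=sub["mu"].to_numpy(float),
                    k_raw_sq=sub["k_raw_sq"].to_numpy(float),
                    k_adj_sq=sub["k_adj_sq"].to_numpy(float),
                    valid=sub["valid"].to_numpy().astype(bool),
                    bfi=sub["bfi"].to_numpy(float),
                    nbfi=sub["nbfi"].to_numpy(float),
                    bvi=sub["bvi"].to_numpy(float),
                    nbvi=sub["nbvi"].to_numpy(float),
                    baseline_i0=float(sub["baseline_i0"].iloc[0]),
                )
            )
        t = channels[0].t
        duration = float(t[-1] - t[0]) + 1.0 / frame_rate_hz
        return cls(
            channels=channels,
            frame_rate_hz=frame_rate_hz,
            exposure_s=exposure_s,
            measurement_period_s=duration,
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def split_channels(stack: FrameStack, layout: ChannelLayout) -> dict[int, np.ndarray]:
    """Extract per-channel pixel ensembles from every frame.

    Returns a mapping ``channel_id -> array (n_frames, n_pixels)``. The pixel
    count per channel is constant over time by construction.
    """
    layout.validate_for(stack.frame_shape)
    out: dict[int, np.ndarray] = {}
    for r in layout.regions:
        block = stack.frames[:, r.row0 : r.row1, r.col0 : r.col1]
        out[r.channel_id] = block.reshape(stack.n_frames, -1)
    return out


def compute_dark_calibration(
    dark: FrameStack,
    gain: float,
    conversion_factor: float,
    include_quantization: bool = False,
    layout: ChannelLayout | None = None,
):
    """Estimate dark offset and dark variance from a dark frame stack.

    The offset is the mean of all dark pixels; the variance is the pooled
    (temporal + spatial) unbiased variance of all dark counts. With a
    ``layout``, a per-channel mapping ``channel_id -> CameraCalibration`` is
    returned instead of a single global calibration.
    """
    if dark.n_frames < 2:
        raise CalibrationError("dark calibration needs at least 2 dark frames")

    def _calib(values: np.ndarray) -> CameraCalibration:
        flat = values.astype(np.float64).ravel()
        return CameraCalibration(
            gain=gain,
            conversion_factor=conversion_factor,
            dark_offset=float(flat.mean()),
            dark_variance=float(flat.var(ddof=1)),
            include_quantization=include_quantization,
        )

    if layout is None:
        return _calib(dark.frames)
    ensembles = split_channels(dark, layout)
    return {cid: _calib(vals) for cid, vals in ensembles.items()}


def raw_contrast(ensemble: np.ndarray, offset: float = 0.0):
    """Raw squared speckle contrast of a pixel ensemble.

    ``ensemble`` is either 1-D (one frame) or 2-D ``(n_frames, n_pixels)``;
    the statistics are taken along the last axis. The dark offset is
    subtracted from the mean only (an additive shift leaves the variance
    unchanged). Frames with non-positive offset-subtracted mean are flagged
    invalid and their contrast set to NaN.

    Returns
    -------
    mu, var, k_raw_sq, valid
        Arrays (or scalars for 1-D input) of the offset-subtracted mean,
        unbiased spatial variance, squared contrast, and validity flag.
    """
    ens = np.asarray(ensemble, dtype=np.float64)
    if ens.size == 0:
        raise InvalidParameterError("empty pixel ensemble")
    if ens.shape[-1] < 2:
        raise InvalidParameterError("pixel ensemble needs at least 2 pixels")
    mu = ens.mean(axis=-1) - offset
    var = ens.var(axis=-1, ddof=1)
    valid = mu > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        k_raw_sq = np.where(valid, var / np.square(mu), np.nan)
    if ens.ndim == 1:
        return float(mu), float(var), float(k_raw_sq), bool(valid)
    return mu, var, k_raw_sq, valid


def noise_corrected_contrast(
    mu,
    k_raw_sq,
    calib: CameraCalibration,
    floor_epsilon: float = FLOOR_EPSILON,
):
    """Subtract shot, quantization, and camera noise from raw contrast.

    ``K_adj^2 = K_raw^2 - gamma/mu - [1/(12 mu^2)] - dark_variance/mu^2``.
    The quantization term is applied only when the calibration's
    ``include_quantization`` flag is set (16-bit acquisition renders it
    negligible). Values at or below ``floor_epsilon``, or with ``mu <= 0``,
    are flagged invalid (NaN), not raised.

    Returns ``(k_adj_sq, valid)``.
    """
    mu_arr = np.asarray(mu, dtype=np.float64)
    kr = np.asarray(k_raw_sq, dtype=np.float64)
    scalar = mu_arr.ndim == 0
    mu_arr = np.atleast_1d(mu_arr)
    kr = np.atleast_1d(kr)
    positive = mu_arr > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        k_shot = calib.gamma / mu_arr
        k_cam = calib.dark_variance / np.square(mu_arr)
        k_quant = (
            1.0 / (12.0 * np.square(mu_arr)) if calib.include_quantization else 0.0
        )
        k_adj = kr - k_shot - k_quant - k_cam
    valid = positive & np.isfinite(k_adj) & (k_adj > floor_epsilon)
    k_adj = np.where(valid, k_adj, np.nan)
    if scalar:
        return float(k_adj[0]), bool(valid[0])
    return k_adj, valid


def bfi_from_contrast(k_adj_sq, valid=None):
    """Blood flow index ``BFI = 1 / K_adj^2`` (invalid frames propagate as NaN)."""
    k = np.asarray(k_adj_sq, dtype=np.float64)
    scalar = k.ndim == 0
    k = np.atleast_1d(k)
    if valid is None:
        valid = np.isfinite(k) & (k > FLOOR_EPSILON)
    else:
        valid = np.atleast_1d(np.asarray(valid, bool)) & np.isfinite(k)
    with np.errstate(divide="ignore", invalid="ignore"):
        bfi = np.where(valid, 1.0 / k, np.nan)
    if scalar:
        return float(bfi[0])
    return bfi


def normalize_trace(trace, valid=None) -> np.ndarray:
    """Min-max normalize a trace to [0, 1] over its valid samples.

    Invalid samples are excluded from the min/max and left as NaN in the
    output. The mapping is affine and order-preserving; applying it twice is
    the identity. Raises :class:`DegenerateTraceError` when fewer than two
    distinct valid values exist.
    """
    x = np.asarray(trace, dtype=np.float64)
    if valid is None:
        valid = np.isfinite(x)
    else:
        valid = np.asarray(valid, bool) & np.isfinite(x)
    if np.count_nonzero(valid) < 2:
        raise DegenerateTraceError("need at least 2 valid samples to normalize")
    lo = x[valid].min()
    hi = x[valid].max()
    if hi == lo:
        raise DegenerateTraceError("degenerate trace: max equals min")
    out = np.full_like(x, np.nan)
    out[valid] = (x[valid] - lo) / (hi - lo)
    return out


def bvi_from_intensity(
    t,
    mu,
    baseline_window_s: float = 7.0,
    method: str = "log",
    linear_coefficient: float = LINEAR_BVI_COEFFICIENT,
    valid=None,
):
    """Blood volume index from the channel mean-intensity series.

    ``I0`` is the mean of ``mu`` over the baseline window (default: first
    7 s of the record). ``method="log"`` gives ``BVI = log10(I0 / mu(t))``;
    ``method="linear"`` gives ``coefficient * (I0 - mu(t)) / I0`` — the
    first-order expansion of the log form has coefficient ``1/ln(10)``
    (the default), while some sources print a coefficient of 2.

    Returns ``(bvi, i0)``; frames with non-positive ``mu`` get NaN.
    """
    t = np.asarray(t, dtype=np.float64)
    mu_arr = np.asarray(mu, dtype=np.float64)
    if method not in ("log", "linear"):
        raise InvalidParameterError(f"unknown BVI method {method!r}")
    if valid is None:
        valid = np.isfinite(mu_arr) & (mu_arr > 0)
    else:
        valid = np.asarray(valid, bool) & np.isfinite(mu_arr) & (mu_arr > 0)
    in_baseline = (t < baseline_window_s) & valid
    if not np.any(in_baseline):
        raise InvalidParameterError(
            f"no valid frames in the first {baseline_window_s} s baseline window"
        )
    i0 = float(mu_arr[in_baseline].mean())
    out = np.full_like(mu_arr, np.nan)
    if method == "log":
        out[valid] = np.log10(i0 / mu_arr[valid])
    else:
        out[valid] = linear_coefficient * (i0 - mu_arr[valid]) / i0
    return out, i0


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def compute_contrast_series(
    stack: FrameStack,
    layout: ChannelLayout,
    calib: CameraCalibration,
    floor_epsilon: float = FLOOR_EPSILON,
) -> ContrastSeries:
    """Frame stack -> per-channel raw and noise-adjusted contrast series."""
    ensembles = split_channels(stack, layout)
    t = stack.times()
    channels = []
    for region in layout.regions:
        ens = ensembles[region.channel_id]
        mu, var, k_raw, valid_raw = raw_contrast(ens, offset=calib.dark_offset)
        k_adj, valid = noise_corrected_contrast(mu, k_raw, calib, floor_epsilon)
        channels.append(
            ChannelContrast(
                channel_id=region.channel_id,
                sd_distance_cm=region.sd_distance_cm,
                t=t,
                mu=mu,
                var=var,
                k_raw_sq=k_raw,
                k_adj_sq=k_adj,
                valid=valid_raw & valid,
            )
        )
    return ContrastSeries(
        channels=channels,
        frame_rate_hz=stack.frame_rate_hz,
        exposure_s=stack.exposure_s,
    )


def compute_hemo_series(
    stack: FrameStack,
    layout: ChannelLayout,
    calib: CameraCalibration,
    baseline_window_s: float = 7.0,
    bvi_method: str = "log",
    linear_coefficient: float = LINEAR_BVI_COEFFICIENT,
    floor_epsilon: float = FLOOR_EPSILON,
) -> HemoSeries:
    """Frame stack -> per-channel BFI/nBFI/BVI/nBVI series.

    The min/max for nBFI and nBVI are taken over the full measurement period
    (the whole record), using valid frames only. The BVI uses the channel-
    region mean intensity, with its baseline over the first
    ``baseline_window_s`` seconds.
    """
    cs = compute_contrast_series(stack, layout, calib, floor_epsilon)
    channels = []
    for ch in cs.channels:
        bfi = bfi_from_contrast(ch.k_adj_sq, ch.valid)
        nbfi = normalize_trace(bfi, ch.valid)
        intensity_valid = ch.mu > 0
        bvi, i0 = bvi_from_intensity(
            ch.t,
            ch.mu,
            baseline_window_s=baseline_window_s,
            method=bvi_method,
            linear_coefficient=linear_coefficient,
            valid=intensity_valid,
        )
        nbvi = normalize_trace(bvi, intensity_valid)
        channels.append(
            ChannelHemo(
                channel_id=ch.channel_id,
                sd_distance_cm=ch.sd_distance_cm,
                t=ch.t,
                mu=ch.mu,
                k_raw_sq=ch.k_raw_sq,
                k_adj_sq=ch.k_adj_sq,
                valid=ch.valid,
                bfi=bfi,
                nbfi=nbfi,
                bvi=bvi,
                nbvi=nbvi,
                baseline_i0=i0,
            )
        )
    return HemoSeries(
        channels=channels,
        frame_rate_hz=stack.frame_rate_hz,
        exposure_s=stack.exposure_s,
        measurement_period_s=stack.duration_s,
    )
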