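"""Spectral and beat-level cardiac analytics on hemodynamic time series.

Heart-rate extraction from the one-sided power spectrum, a frequency-domain
SNR with a 10 dB usability threshold, beat detection on a band-passed trace,
phase-normalized beat averaging per occlusion segment, and per-channel
amplitude-ratio curves for flow (nBFI) and volume (nBVI) traces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .contrast import HemoSeries
from .exceptions import InvalidParameterError, SpectralError
from .hemodynamics import SEGMENTS, SegmentDefinition

__all__ = [
    "SNR_THRESHOLD_DB",
    "SpectralSummary",
    "CardiacWaveform",
    "power_spectrum",
    "estimate_heart_rate",
    "snr_db",
    "spectral_summary",
    "detect_beats",
    "average_waveform",
    "segment_waveforms",
    "amplitude_ratio_curve",
]

#: Usability threshold on the frequency-domain SNR of a flow trace.
SNR_THRESHOLD_DB = 10.0

DEFAULT_HEART_RATE_BAND_HZ = (0.7, 3.0)
DEFAULT_SIGNAL_HALFWIDTH_HZ = 0.2
DEFAULT_NOISE_BAND_HZ = (3.0, 10.0)


@dataclass
class SpectralSummary:
    heart_rate_hz: float
    snr_db: float
    freqs: np.ndarray
    psd: np.ndarray


@dataclass
class CardiacWaveform:
    """Beat-averaged waveform on a common phase grid (fraction of cycle)."""

    phase: np.ndarray
    values: np.ndarray
    n_beats: int

    @property
    def amplitude_i(self) -> float:
        """Peak-to-trough amplitude of the averaged waveform."""
        return float(np.max(self.values) - np.min(self.values))


def _fill_invalid(values: np.ndarray, valid: np.ndarray) -> tuple[np.ndarray, float]:
    """Linearly interpolate invalid samples; returns (filled, invalid fraction)."""
    filled = np.asarray(values, float).copy()
    frac = 1.0 - float(np.mean(valid))
    if frac > 0:
        idx = np.arange(len(filled))
        filled[~valid] = np.interp(idx[~valid], idx[valid], filled[valid])
    return filled, frac


def power_spectrum(
    values,
    frame_rate_hz: float,
    valid=None,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided power spectral density with the mean removed beforehand.

    Invalid samples are linearly interpolated (their fraction is logged via a
    warning when above 10%). Requires at least 64 valid samples.
    """
    values = np.asarray(values, float)
    if valid is None:
        valid = np.isfinite(values)
    else:
        valid = np.asarray(valid, bool) & np.isfinite(values)
    if np.count_nonzero(valid) < 64:
        raise SpectralError("need at least 64 valid samples for a spectrum")
    filled, frac = _fill_invalid(values, valid)
    if frac > 0.10:
        warnings.warn(
            f"{frac:.1%} of samples interpolated before FFT", UserWarning, stacklevel=2
        )
    # Hann window: a boxcar's leakage floor scales with signal power, which
    # would contaminate the SNR noise band for strongly pulsatile traces
    freqs, psd = sps.periodogram(
        filled, fs=frame_rate_hz, detrend="constant", window="hann"
    )
    return freqs, psd


def estimate_heart_rate(
    freqs: np.ndarray,
    psd: np.ndarray,
    band_hz: tuple[float, float] = DEFAULT_HEART_RATE_BAND_HZ,
) -> float:
    """Frequency of maximum in-band power; ties break toward lower frequency."""
    freqs = np.asarray(freqs, float)
    psd = np.asarray(psd, float)
    mask = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not np.any(mask) or not np.any(psd[mask] > 0):
        raise SpectralError(f"no in-band power in {band_hz} Hz")
    sub_f = freqs[mask]
    sub_p = psd[mask]
    return float(sub_f[np.argmax(sub_p)])  # argmax returns the first (lowest f)


def snr_db(
    freqs: np.ndarray,
    psd: np.ndarray,
    heart_rate_hz: float,
    signal_halfwidth_hz: float = DEFAULT_SIGNAL_HALFWIDTH_HZ,
    noise_band_hz: tuple[float, float] = DEFAULT_NOISE_BAND_HZ,
) -> float:
    """Frequency-domain SNR of a pulsatile trace, in decibels.

    Signal power is the total PSD power within ``+-signal_halfwidth_hz`` of
    the cardiac peak; the noise floor is the median PSD level over
    ``noise_band_hz`` scaled to the same bandwidth.
    """
    freqs = np.asarray(freqs, float)
    psd = np.asarray(psd, float)
    sig = np.abs(freqs - heart_rate_hz) <= signal_halfwidth_hz
    noise = (freqs >= noise_band_hz[0]) & (freqs <= noise_band_hz[1])
    if not np.any(sig) or not np.any(noise):
        raise SpectralError("signal or noise band empty on this frequency grid")
    p_signal = float(np.sum(psd[sig]))
    noise_level = float(np.median(psd[noise]))
    if noise_level <= 0 or noise_level < 1e-12 * float(psd.max()):
        # numerically zero floor: a noiseless (or purely periodic) input
        raise SpectralError("zero noise floor (degenerate noiseless input)")
    p_noise = noise_level * np.count_nonzero(sig)
    return 10.0 * np.log10(p_signal / p_noise)


def spectral_summary(
    values,
    frame_rate_hz: float,
    valid=None,
    band_hz: tuple[float, float] = DEFAULT_HEART_RATE_BAND_HZ,
) -> SpectralSummary:
    freqs, psd = power_spectrum(values, frame_rate_hz, valid)
    hr = estimate_heart_rate(freqs, psd, band_hz)
    return SpectralSummary(
        heart_rate_hz=hr, snr_db=snr_db(freqs, psd, hr), freqs=freqs, psd=psd
    )


def detect_beats(
    values,
    frame_rate_hz: float,
    heart_rate_hz: float,
    valid=None,
) -> np.ndarray:
    """Beat onset times (seconds) on a band-passed trace.

    The trace is band-pass filtered around [0.5 HR, 3 HR], systolic peaks are
    picked with a minimum separation of 0.6/HR, and each beat onset is the
    local minimum preceding its peak.
    """
    if heart_rate_hz <= 0:
        raise InvalidParameterError("heart_rate_hz must be positive")
    values = np.asarray(values, float)
    if valid is None:
        valid = np.isfinite(values)
    else:
        valid = np.asarray(valid, bool) & np.isfinite(values)
    if np.count_nonzero(valid) < 8:
        return np.empty(0)
    filled, _ = _fill_invalid(values, valid)
    if np.ptp(filled) == 0:
        return np.empty(0)  # constant trace: zero beats
    nyq = frame_rate_hz / 2.0
    lo = 0.5 * heart_rate_hz
    hi = min(3.0 * heart_rate_hz, 0.95 * nyq)
    if lo >= hi:
        raise InvalidParameterError("heart rate incompatible with sampling rate")
    sos = sps.butter(2, [lo, hi], btype="bandpass", fs=frame_rate_hz, output="sos")
    filtered = sps.sosfiltfilt(sos, filled)
    min_sep = max(1, int(round(0.6 / heart_rate_hz * frame_rate_hz)))
    peaks, _ = sps.find_peaks(filtered, distance=min_sep)
    if peaks.size < 2:
        return np.empty(0)
    # onset of each beat = local minimum between consecutive peaks; the
    # stretch before the first peak is skipped (filtfilt edge transients
    # there systematically misplace a minimum at the record start)
    onsets = []
    for prev, p in zip(peaks[:-1], peaks[1:]):
        onsets.append(prev + int(np.argmin(filtered[prev : p + 1])))
    return np.unique(onsets) / frame_rate_hz


def average_waveform(
    t,
    values,
    onsets: np.ndarray,
    n_phase_bins: int = 100,
    min_beats: int = 3,
    window: tuple[float, float] | None = None,
    heart_rate_hz: float | None = None,
) -> CardiacWaveform | None:
    """Phase-normalized beat average.

    Each beat (the interval between consecutive onsets) is resampled onto a
    common phase grid and averaged. Beats are kept only if fully inside
    ``window`` (when given) and, when ``heart_rate_hz`` is given, if their
    duration lies within [0.5, 1.5] cardiac periods (drift/detection-outlier
    rejection). Returns None when fewer than ``min_beats`` usable beats exist.
    """
    t = np.asarray(t, float)
    values = np.asarray(values, float)
    onsets = np.asarray(onsets, float)
    if onsets.size < 2:
        return None
    phase = (np.arange(n_phase_bins) + 0.5) / n_phase_bins
    beats = []
    for start, stop in zip(onsets[:-1], onsets[1:]):
        if window is not None and (start < window[0] or stop > window[1]):
            continue
        if heart_rate_hz is not None:
            period = 1.0 / heart_rate_hz
            if not (0.7 * period <= stop - start <= 1.3 * period):
                continue
        mask = (t >= start) & (t <= stop)
        tb = t[mask]
        vb = values[mask]
        ok = np.isfinite(vb)
        if np.count_nonzero(ok) < 4:
            continue
        resampled = np.interp(
            start + phase * (stop - start), tb[ok], vb[ok]
        )
        beats.append(resampled)
    if len(beats) < min_beats:
        return None
    avg = np.mean(beats, axis=0)
    return CardiacWaveform(phase=phase, values=avg, n_beats=len(beats))


def segment_waveforms(
    t,
    values,
    frame_rate_hz: float,
    heart_rate_hz: float,
    seg: SegmentDefinition,
    valid=None,
    n_phase_bins: int = 100,
    min_beats: int = 3,
) -> dict[str, CardiacWaveform | None]:
    """Beat-averaged waveform per occlusion segment (beats detected once on
    the full trace, then assigned to the segment that fully contains them)."""
    onsets = detect_beats(values, frame_rate_hz, heart_rate_hz, valid)
    windows = {
        "a": (seg.start_s, seg.occl_start_s),
        "b": (seg.occl_start_s, seg.occl_end_s),
        "c": (seg.occl_end_s, seg.end_s),
    }
    return {
        name: average_waveform(
            t,
            values,
            onsets,
            n_phase_bins=n_phase_bins,
            min_beats=min_beats,
            window=win,
            heart_rate_hz=heart_rate_hz,
        )
        for name, win in windows.items()
    }


def amplitude_ratio_curve(
    hemo: HemoSeries,
    seg: SegmentDefinition,
    heart_rate_hz: float | None = None,
    n_phase_bins: int = 100,
    min_beats: int = 3,
) -> pd.DataFrame:
    """Per-channel cardiac-amplitude ratios for flow (nBFI) and volume (nBVI).

    The heart rate is estimated from the first channel's nBFI spectrum unless
    supplied. Channels whose segment waveforms cannot be formed get NaN ratios
    and a warning.
    """
    if heart_rate_hz is None:
        ref = hemo.channels[0]
        summary = spectral_summary(ref.nbfi, hemo.frame_rate_hz, ref.valid)
        heart_rate_hz = summary.heart_rate_hz
    rows = []
    for ch in hemo.channels:
        row: dict[str, float] = {
            "channel": ch.channel_id,
            "sd_distance_cm": ch.sd_distance_cm,
            "heart_rate_hz": heart_rate_hz,
        }
        for trace_name, label in (("nbfi", "flow"), ("nbvi", "vol")):
            values = getattr(ch, trace_name)
            wfs = segment_waveforms(
                ch.t,
                values,
                hemo.frame_rate_hz,
                heart_rate_hz,
                seg,
                valid=np.isfinite(values),
                n_phase_bins=n_phase_bins,
                min_beats=min_beats,
            )
            amps = {
                name: (wf.amplitude_i if wf is not None else float("nan"))
                for name, wf in wfs.items()
            }
            if any(np.isnan(list(amps.values()))):
                warnings.warn(
                    f"channel {ch.channel_id}: insufficient beats for {label} "
                    "waveform in at least one segment",
                    UserWarning,
                    stacklevel=2,
                )
            for name in SEGMENTS:
                row[f"amp_{name}_{label}"] = amps[name]
            row[f"amp_ratio_ba_{label}"] = (
                amps["b"] / amps["a"] if amps["a"] else float("nan")
            )
            row[f"amp_ratio_ca_{label}"] = (
                amps["c"] / amps["a"] if amps["a"] else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)
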