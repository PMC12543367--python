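"""Occlusion-window segmentation and depth-sensitivity ratio statistics.

Splits per-channel nBFI (or nBVI) traces into pre / during / post occlusion
segments, computes per-segment means and unbiased standard deviations, their
during/pre and post/pre ratios as a function of source-detector distance,
aggregates across subjects, and estimates the S-D distance at which the
occlusion ratio curve converges to the control curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .contrast import HemoSeries
from .exceptions import InvalidParameterError, SegmentationError

__all__ = [
    "SEGMENTS",
    "SegmentDefinition",
    "segment_trace",
    "segment_stats",
    "ratio_metrics",
    "subject_ratio_curve",
    "group_aggregate",
    "convergence_distance",
]

SEGMENTS = ("a", "b", "c")


@dataclass(frozen=True)
class SegmentDefinition:
    """Three half-open segments around an occlusion window.

    a: [start_s, occl_start_s), b: [occl_start_s, occl_end_s),
    c: [occl_end_s, end_s] (the final segment includes its right edge so the
    last frame of the record is not dropped).
    """

    start_s: float = 0.0
    occl_start_s: float = 8.0
    occl_end_s: float = 16.0
    end_s: float = 24.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.start_s < self.occl_start_s < self.occl_end_s <= self.end_s):
            raise InvalidParameterError(
                "segments must satisfy 0 <= start < occl_start < occl_end <= end"
            )

    @classmethod
    def from_occlusion(
        cls, window: tuple[float, float], duration_s: float, start_s: float = 0.0
    ) -> "SegmentDefinition":
        return cls(
            start_s=start_s,
            occl_start_s=window[0],
            occl_end_s=window[1],
            end_s=duration_s,
        )

    def masks(self, t: np.ndarray) -> dict[str, np.ndarray]:
        t = np.asarray(t, float)
        return {
            "a": (t >= self.start_s) & (t < self.occl_start_s),
            "b": (t >= self.occl_start_s) & (t < self.occl_end_s),
            "c": (t >= self.occl_end_s) & (t <= self.end_s),
        }


def segment_trace(
    t: np.ndarray,
    values: np.ndarray,
    seg: SegmentDefinition,
    valid: np.ndarray | None = None,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Split a trace into the three segments, keeping only valid samples.

    Every valid sample belongs to exactly one segment (half-open intervals).
    Raises :class:`SegmentationError` naming any segment left without valid
    samples.
    """
    t = np.asarray(t, float)
    values = np.asarray(values, float)
    if valid is None:
        valid = np.isfinite(values)
    else:
        valid = np.asarray(valid, bool) & np.isfinite(values)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, mask in seg.masks(t).items():
        keep = mask & valid
        if not np.any(keep):
            raise SegmentationError(f"segment {name!r} contains no valid samples")
        out[name] = (t[keep], values[keep])
    return out


def segment_stats(
    segments: Mapping[str, tuple[np.ndarray, np.ndarray]]
) -> dict[str, dict[str, float]]:
    """Per-segment mean, unbiased standard deviation and valid-sample count.

    With fewer than 2 valid samples the standard deviation is reported as NaN
    (absent) while the mean is still computed.
    """
    out: dict[str, dict[str, float]] = {}
    for name, (_, v) in segments.items():
        n = v.size
        std = float(np.std(v, ddof=1)) if n >= 2 else float("nan")
        out[name] = {"mean": float(np.mean(v)), "std": std, "n_valid": n}
    return out


def ratio_metrics(stats: Mapping[str, Mapping[str, float]]) -> dict[str, float]:
    """During/pre and post/pre ratios of segment means and standard deviations.

    Zero (or missing) denominators yield NaN for the affected ratio — an
    undefined-ratio flag rather than an exception.
    """
    def _ratio(num: float, den: float) -> float:
        if not np.isfinite(den) or den == 0.0 or not np.isfinite(num):
            return float("nan")
        return num / den

    a, b, c = stats["a"], stats["b"], stats["c"]
    return {
        "ratio_mean_ba": _ratio(b["mean"], a["mean"]),
        "ratio_mean_ca": _ratio(c["mean"], a["mean"]),
        "ratio_std_ba": _ratio(b["std"], a["std"]),
        "ratio_std_ca": _ratio(c["std"], a["std"]),
    }


def subject_ratio_curve(
    hemo: HemoSeries,
    seg: SegmentDefinition,
    trace: str = "nbfi",
) -> pd.DataFrame:
    """Per-channel segment statistics and ratios for one subject.

    ``trace`` selects which normalized series is analyzed (``"nbfi"`` or
    ``"nbvi"``). Ratios are computed on the normalized traces.
    """
    rows = []
    for ch in hemo.channels:
        values = getattr(ch, trace)
        segs = segment_trace(ch.t, values, seg, ch.valid)
        stats = segment_stats(segs)
        ratios = ratio_metrics(stats)
        row = {
            "channel": ch.channel_id,
            "sd_distance_cm": ch.sd_distance_cm,
            **ratios,
        }
        for name in SEGMENTS:
            row[f"mean_{name}"] = stats[name]["mean"]
            row[f"std_{name}"] = stats[name]["std"]
            row[f"n_valid_{name}"] = stats[name]["n_valid"]
        rows.append(row)
    return pd.DataFrame(rows)


_RATIO_COLUMNS = ("ratio_mean_ba", "ratio_mean_ca", "ratio_std_ba", "ratio_std_ca")


def group_aggregate(
    curves: Sequence[pd.DataFrame],
    columns: Sequence[str] = _RATIO_COLUMNS,
) -> pd.DataFrame:
    """Cohort mean and across-subject standard deviation of each ratio column.

    Subject-channels with NaN ratios (excluded or undefined) are dropped per
    channel; ``n_subjects_used`` and ``n_excluded`` keep the bookkeeping
    (``n_subjects_used + n_excluded`` equals the cohort size; the count
    follows the first column in ``columns``). Channels with no valid subject
    at all are omitted with a warning. A single subject yields an
    across-subject standard deviation of 0.
    """
    if len(curves) == 0:
        raise InvalidParameterError("no subject curves to aggregate")
    n_cohort = len(curves)
    stacked = pd.concat(
        [c.assign(_subject=i) for i, c in enumerate(curves)], ignore_index=True
    )
    rows = []
    for (cid, sd), grp in stacked.groupby(["channel", "sd_distance_cm"], sort=True):
        row: dict[str, float] = {"channel": int(cid), "sd_distance_cm": float(sd)}
        any_used = 0
        for col in columns:
            vals = grp[col].to_numpy(float)
            ok = np.isfinite(vals)
            n_used = int(ok.sum())
            if col == columns[0]:
                any_used = n_used
            if n_used == 0:
                row[f"{col}_mean"] = float("nan")
                row[f"{col}_std"] = float("nan")
            else:
                row[f"{col}_mean"] = float(np.mean(vals[ok]))
                row[f"{col}_std"] = (
                    float(np.std(vals[ok], ddof=1)) if n_used > 1 else 0.0
                )
            row[f"{col}_n"] = n_used
        row["n_subjects_used"] = any_used
        row["n_excluded"] = n_cohort - any_used
        if any_used == 0:
            warnings.warn(
                f"channel {cid}: no valid subjects; omitted from aggregate",
                UserWarning,
                stacklevel=2,
            )
            continue
        rows.append(row)
    return pd.DataFrame(rows)


def convergence_distance(
    sd_distances_cm: np.ndarray,
    occlusion_ratio: np.ndarray,
    control_ratio: np.ndarray,
    tolerance: float = 0.05,
) -> float | None:
    """Smallest S-D distance from which the occlusion curve stays within
    ``tolerance`` of the control curve for all larger distances.

    Returns None when the criterion is never satisfied. Both curves must be
    sampled on the same S-D grid.
    """
    sd = np.asarray(sd_distances_cm, float)
    occ = np.asarray(occlusion_ratio, float)
    ctl = np.asarray(control_ratio, float)
    if sd.shape != occ.shape or sd.shape != ctl.shape:
        raise InvalidParameterError("curves must share the same S-D grid")
    within = np.abs(occ - ctl) <= tolerance
    # scan from the far end: find the earliest index from which all are within
    idx = None
    for i in range(len(sd) - 1, -1, -1):
        if within[i]:
            idx = i
        else:
            break
    if idx is None:
        return None
    return float(sd[idx])
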