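"""End-to-end orchestration: simulate -> calibrate -> process -> analyze -> report.

Ties the computational modules into deterministic, manifest-tracked runs.
All outputs are plain CSV/JSON; identical (config, seed) pairs produce
byte-identical files (no timestamps enter any output).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .contrast import CameraCalibration, HemoSeries, compute_dark_calibration, compute_hemo_series
from .exceptions import InvalidParameterError
from .hemodynamics import (
    SegmentDefinition,
    convergence_distance,
    group_aggregate,
    subject_ratio_curve,
)
from .io import (
    cohort_config_to_dict,
    write_calibration,
    write_cohort_config,
    write_frame_stack,
    write_hemo_series,
    write_layout,
)
from .synthetic import (
    SyntheticCohortConfig,
    synthesize_dark_frames,
    synthesize_frames,
)
from .waveform import SNR_THRESHOLD_DB, amplitude_ratio_curve, spectral_summary

__all__ = [
    "RunConfig",
    "simulate_cohort",
    "process_subject",
    "analyze_cohort",
    "run_pipeline",
]

_AMP_COLUMNS = (
    "amp_ratio_ba_flow",
    "amp_ratio_ca_flow",
    "amp_ratio_ba_vol",
    "amp_ratio_ca_vol",
)


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a full synthetic-cohort pipeline run."""

    cohort: SyntheticCohortConfig
    include_control: bool = True
    segments: SegmentDefinition | None = None
    snr_threshold_db: float = SNR_THRESHOLD_DB
    convergence_tolerance: float = 0.05
    baseline_window_s: float = 7.0
    bvi_method: str = "log"
    n_dark_frames: int = 100
    write_stacks: bool = False
    stack_format: str = "tiff"

    def segment_definition(self) -> SegmentDefinition:
        if self.segments is not None:
            return self.segments
        window = self.cohort.occlusion_window_s
        if window is None:
            raise InvalidParameterError(
                "segments must be given explicitly for a control-only cohort"
            )
        return SegmentDefinition.from_occlusion(window, self.cohort.duration_s)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = cohort_config_to_dict(self.cohort)
        d["segments"] = (
            dataclasses.asdict(self.segments) if self.segments is not None else None
        )
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def simulate_cohort(
    config: SyntheticCohortConfig,
    out_dir: str | Path,
    fmt: str = "tiff",
) -> dict:
    """Render a cohort to disk: per-subject stacks + sidecars, a shared dark
    stack, the channel layout, the config, ground-truth and ratio-oracle CSVs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_cohort_config(config, out / "config.json")
    write_layout(config.layout(), out / "layout.json")
    ext = "tif" if fmt == "tiff" else "raw"
    dark = synthesize_dark_frames(
        config.noise,
        n_frames=100,
        frame_shape=config.frame_shape,
        seed=config.seed,
        frame_rate_hz=config.frame_rate_hz,
        exposure_s=config.exposure_s,
    )
    write_frame_stack(dark, out / f"dark.{ext}", fmt=fmt)
    truth_frames = []
    oracle_frames = []
    stack_paths = []
    for s in range(config.n_subjects):
        stack, truth = synthesize_frames(config, s)
        path = out / f"subject_{s:02d}.{ext}"
        write_frame_stack(
            stack, path, fmt=fmt, extra_metadata={"subject": s, "seed": config.seed}
        )
        stack_paths.append(path)
        truth_frames.append(truth.to_frame())
        oracle_frames.append(truth.ratios_to_frame())
    pd.concat(truth_frames, ignore_index=True).to_csv(
        out / "ground_truth.csv", index=False, float_format="%.10g"
    )
    pd.concat(oracle_frames, ignore_index=True).to_csv(
        out / "ratio_oracle.csv", index=False, float_format="%.10g"
    )
    return {
        "out_dir": out,
        "stacks": stack_paths,
        "dark": out / f"dark.{ext}",
        "layout": out / "layout.json",
        "config": out / "config.json",
    }


def process_subject(
    config: SyntheticCohortConfig,
    subject_index: int,
    calib: CameraCalibration,
    baseline_window_s: float = 7.0,
    bvi_method: str = "log",
) -> HemoSeries:
    """Synthesize one subject in memory and run the contrast pipeline on it."""
    stack, _ = synthesize_frames(config, subject_index)
    return compute_hemo_series(
        stack,
        config.layout(),
        calib,
        baseline_window_s=baseline_window_s,
        bvi_method=bvi_method,
    )


def analyze_cohort(
    hemo_list: list[HemoSeries],
    seg: SegmentDefinition,
    snr_threshold_db: float = SNR_THRESHOLD_DB,
) -> dict:
    """Per-subject ratio and amplitude curves with SNR-based exclusion, plus
    cohort aggregates.

    A subject-channel whose nBFI frequency-domain SNR falls below the
    threshold is excluded (its ratios set to NaN) before aggregation.
    Returns a dict with per-subject curves, the SNR table, and the group
    tables for segment ratios and cardiac amplitude ratios.
    """
    ratio_curves = []
    amp_curves = []
    snr_rows = []
    n_excluded = 0
    for s, hemo in enumerate(hemo_list):
        curve = subject_ratio_curve(hemo, seg, trace="nbfi")
        snr_by_channel = {}
        hr_ref = None
        for ch in hemo.channels:
            try:
                summary = spectral_summary(ch.nbfi, hemo.frame_rate_hz, ch.valid)
                snr_val, hr = summary.snr_db, summary.heart_rate_hz
            except Exception:
                snr_val, hr = float("nan"), float("nan")
            snr_by_channel[ch.channel_id] = snr_val
            if hr_ref is None and np.isfinite(hr):
                hr_ref = hr
            snr_rows.append(
                {
                    "subject": s,
                    "channel": ch.channel_id,
                    "sd_distance_cm": ch.sd_distance_cm,
                    "snr_db": snr_val,
                    "heart_rate_hz": hr,
                }
            )
        excluded = curve["channel"].map(
            lambda cid: not (
                np.isfinite(snr_by_channel[cid])
                and snr_by_channel[cid] >= snr_threshold_db
            )
        )
        n_excluded += int(excluded.sum())
        ratio_cols = [c for c in curve.columns if c.startswith("ratio_")]
        curve.loc[excluded, ratio_cols] = np.nan
        ratio_curves.append(curve)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            amp = amplitude_ratio_curve(hemo, seg, heart_rate_hz=hr_ref)
        amp.loc[excluded.to_numpy(), list(_AMP_COLUMNS)] = np.nan
        amp_curves.append(amp)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        group_ratios = group_aggregate(ratio_curves)
        group_amps = group_aggregate(amp_curves, columns=_AMP_COLUMNS)
    return {
        "ratio_curves": ratio_curves,
        "amplitude_curves": amp_curves,
        "snr_table": pd.DataFrame(snr_rows),
        "group_ratios": group_ratios,
        "group_amplitudes": group_amps,
        "n_channel_exclusions": n_excluded,
    }


def _convergence_block(
    occl: pd.DataFrame, ctrl: pd.DataFrame, tolerance: float
) -> dict:
    """Convergence distances of the occlusion curves toward the control ones."""
    merged = occl.merge(ctrl, on=["channel", "sd_distance_cm"], suffixes=("_o", "_c"))
    out = {}
    pairs = {
        "mean_ba": "ratio_mean_ba_mean",
        "std_ba": "ratio_std_ba_mean",
        "amp_ba_flow": "amp_ratio_ba_flow_mean",
        "amp_ba_vol": "amp_ratio_ba_vol_mean",
    }
    for label, col in pairs.items():
        if f"{col}_o" not in merged.columns:
            continue
        sd = merged["sd_distance_cm"].to_numpy(float)
        occ_vals = merged[f"{col}_o"].to_numpy(float)
        ctl_vals = merged[f"{col}_c"].to_numpy(float)
        ok = np.isfinite(occ_vals) & np.isfinite(ctl_vals)
        if ok.sum() < 2:
            out[label] = None
            continue
        out[label] = convergence_distance(sd[ok], occ_vals[ok], ctl_vals[ok], tolerance)
    return out


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full workflow and write the result bundle.

    Stages: dark calibration -> per-subject processing -> segment/ratio and
    waveform analysis -> (optionally the matched control cohort) ->
    convergence estimates -> CSV tables, JSON report and manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = config.cohort
    seg = config.segment_definition()

    stage = "calibrate"
    try:
        dark = synthesize_dark_frames(
            cohort.noise,
            n_frames=config.n_dark_frames,
            frame_shape=cohort.frame_shape,
            seed=cohort.seed,
            frame_rate_hz=cohort.frame_rate_hz,
            exposure_s=cohort.exposure_s,
        )
        measured = compute_dark_calibration(
            dark, gain=cohort.noise.gain, conversion_factor=cohort.noise.conversion_factor
        )
        # when the generator has no Poisson stage, gamma must be 0
        calib = measured if cohort.noise.shot_noise else CameraCalibration(
            gain=0.0,
            conversion_factor=1.0,
            dark_offset=measured.dark_offset,
            dark_variance=measured.dark_variance,
        )
        write_calibration(calib, out / "calibration.json")
        write_layout(cohort.layout(), out / "layout.json")

        stage = "process"
        cohorts = {"occlusion": cohort}
        if config.include_control:
            cohorts["control"] = cohort.control()
        hemo: dict[str, list[HemoSeries]] = {}
        invalid_fractions: dict[str, list[float]] = {}
        for label, cfg in cohorts.items():
            series_list = []
            fracs = []
            for s in range(cfg.n_subjects):
                hs = process_subject(
                    cfg,
                    s,
                    calib,
                    baseline_window_s=config.baseline_window_s,
                    bvi_method=config.bvi_method,
                )
                if config.write_stacks:
                    write_hemo_series(
                        hs, out / f"series_{label}_{s:02d}.csv", subject=s
                    )
                series_list.append(hs)
                fracs.append(
                    float(np.mean([1.0 - ch.valid.mean() for ch in hs.channels]))
                )
            hemo[label] = series_list
            invalid_fractions[label] = fracs

        stage = "analyze"
        analyses = {
            label: analyze_cohort(series_list, seg, config.snr_threshold_db)
            for label, series_list in hemo.items()
        }
        for label, analysis in analyses.items():
            pd.concat(
                [c.assign(subject=i) for i, c in enumerate(analysis["ratio_curves"])],
                ignore_index=True,
            ).to_csv(out / f"ratios_{label}.csv", index=False, float_format="%.10g")
            analysis["group_ratios"].to_csv(
                out / f"group_ratios_{label}.csv", index=False, float_format="%.10g"
            )
            analysis["group_amplitudes"].to_csv(
                out / f"group_amplitudes_{label}.csv", index=False, float_format="%.10g"
            )
            analysis["snr_table"].to_csv(
                out / f"snr_{label}.csv", index=False, float_format="%.10g"
            )

        stage = "report"
        convergence = None
        if config.include_control:
            occl_curves = analyses["occlusion"]
            ctrl_curves = analyses["control"]
            convergence = _convergence_block(
                occl_curves["group_ratios"].merge(
                    occl_curves["group_amplitudes"],
                    on=["channel", "sd_distance_cm"],
                    suffixes=("", "_amp"),
                ),
                ctrl_curves["group_ratios"].merge(
                    ctrl_curves["group_amplitudes"],
                    on=["channel", "sd_distance_cm"],
                    suffixes=("", "_amp"),
                ),
                config.convergence_tolerance,
            )
        report = {
            "segments": dataclasses.asdict(seg),
            "snr_threshold_db": config.snr_threshold_db,
            "convergence_tolerance": config.convergence_tolerance,
            "convergence_distance_cm": convergence,
            "n_subjects": cohort.n_subjects,
            "channel_exclusions": {
                label: analysis["n_channel_exclusions"]
                for label, analysis in analyses.items()
            },
        }
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))

        manifest = {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": cohort.seed,
            "versions": {
                "scoskit": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "invalid_frame_fraction": invalid_fractions,
            "channel_exclusions": report["channel_exclusions"],
            "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str)
        )
    except Exception as exc:  # surface which stage failed
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {
        "out_dir": out,
        "analyses": analyses,
        "report": report,
        "manifest": manifest,
        "hemo": hemo,
    }
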