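"""On-disk formats: frame stacks (multi-page TIFF or raw + sidecar), channel
layouts, camera calibrations, cohort configs, and tidy hemodynamic CSVs.

Every writer has a matching reader and round-trips losslessly; sidecar JSON
files carry the acquisition metadata a bare pixel array cannot.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .contrast import (
    CameraCalibration,
    ChannelLayout,
    ChannelRegion,
    FrameStack,
    HemoSeries,
)
from .exceptions import FormatError
from .synthetic import ChannelSpec, NoiseModel, SyntheticCohortConfig

__all__ = [
    "write_frame_stack",
    "read_frame_stack",
    "write_layout",
    "read_layout",
    "write_calibration",
    "read_calibration",
    "write_hemo_series",
    "read_hemo_series",
    "write_cohort_config",
    "read_cohort_config",
]

_SIDECAR_REQUIRED = ("frame_rate_hz", "exposure_s", "bit_depth", "dtype", "shape")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_frame_stack(
    stack: FrameStack,
    path: str | Path,
    fmt: str = "tiff",
    extra_metadata: dict | None = None,
) -> Path:
    """Write a stack as multi-page TIFF (one page per frame) or raw binary,
    plus a JSON sidecar at ``<path>.json``. Returns the sidecar path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "tiff":
        tifffile.imwrite(path, stack.frames, photometric="minisblack")
    elif fmt == "raw":
        stack.frames.tofile(path)
    else:
        raise FormatError(f"unknown stack format {fmt!r}")
    meta = {
        "format": fmt,
        "frame_rate_hz": stack.frame_rate_hz,
        "exposure_s": stack.exposure_s,
        "bit_depth": stack.bit_depth,
        "dtype": str(stack.frames.dtype),
        "shape": list(stack.frames.shape),
    }
    if extra_metadata:
        meta.update(extra_metadata)
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return sidecar


def read_frame_stack(path: str | Path, sidecar: str | Path | None = None) -> FrameStack:
    """Read a stack written by :func:`write_frame_stack`.

    The sidecar (default ``<path>.json``) must declare frame rate, exposure,
    bit depth, dtype and shape; mismatches against the pixel payload raise
    :class:`FormatError`. Only 16-bit (or declared-bit-depth integer) input is
    accepted; 8-bit stacks are rejected explicitly.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing sidecar metadata file {sidecar}")
    meta = json.loads(sidecar.read_text())
    missing = [k for k in _SIDECAR_REQUIRED if k not in meta]
    if missing:
        raise FormatError(f"sidecar missing required keys: {missing}")
    if int(meta["bit_depth"]) < 10:
        raise FormatError(
            f"bit depth {meta['bit_depth']} not supported: 16-bit (>=10-bit) "
            "acquisition is required"
        )
    shape = tuple(meta["shape"])
    dtype = np.dtype(meta["dtype"])
    if meta.get("format", "tiff") == "raw" or path.suffix in (".raw", ".bin"):
        frames = np.fromfile(path, dtype=dtype)
        if frames.size != int(np.prod(shape)):
            raise FormatError(
                f"raw payload has {frames.size} values, sidecar shape {shape}"
            )
        frames = frames.reshape(shape)
    else:
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        if frames.shape != shape:
            raise FormatError(f"TIFF shape {frames.shape} != sidecar shape {shape}")
        if frames.dtype != dtype:
            raise FormatError(f"TIFF dtype {frames.dtype} != sidecar dtype {dtype}")
    return FrameStack(
        frames=frames,
        frame_rate_hz=float(meta["frame_rate_hz"]),
        exposure_s=float(meta["exposure_s"]),
        bit_depth=int(meta["bit_depth"]),
    )


# -- layout / calibration ----------------------------------------------------


def write_layout(layout: ChannelLayout, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "regions": [dataclasses.asdict(r) for r in layout.regions],
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_layout(path: str | Path) -> ChannelLayout:
    data = json.loads(Path(path).read_text())
    return ChannelLayout(
        regions=tuple(ChannelRegion(**r) for r in data["regions"])
    )


def write_calibration(calib: CameraCalibration, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(dataclasses.asdict(calib), indent=2, sort_keys=True))


def read_calibration(path: str | Path) -> CameraCalibration:
    data = json.loads(Path(path).read_text())
    return CameraCalibration(**data)


# -- hemodynamic series ------------------------------------------------------


def write_hemo_series(
    hemo: HemoSeries, path: str | Path, subject: int | None = None
) -> None:
    """Tidy long-format CSV with a one-line JSON metadata header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "frame_rate_hz": hemo.frame_rate_hz,
        "exposure_s": hemo.exposure_s,
        "measurement_period_s": hemo.measurement_period_s,
    }
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(meta, sort_keys=True) + "\n")
        hemo.to_frame(subject=subject).to_csv(fh, index=False, float_format="%.10g")


def read_hemo_series(path: str | Path) -> HemoSeries:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise FormatError(f"{path}: missing metadata header line")
        meta = json.loads(header[1:].strip())
        df = pd.read_csv(fh)
    return HemoSeries.from_frame(
        df, frame_rate_hz=meta["frame_rate_hz"], exposure_s=meta["exposure_s"]
    )


# -- cohort configuration ----------------------------------------------------


def cohort_config_to_dict(config: SyntheticCohortConfig) -> dict:
    d = dataclasses.asdict(config)
    d["channels"] = [dataclasses.asdict(c) for c in config.channels]
    d["noise"] = dataclasses.asdict(config.noise)
    return d


def cohort_config_from_dict(data: dict) -> SyntheticCohortConfig:
    data = dict(data)
    data["channels"] = tuple(ChannelSpec(**c) for c in data["channels"])
    data["noise"] = NoiseModel(**data["noise"])
    if data.get("occlusion_window_s") is not None:
        data["occlusion_window_s"] = tuple(data["occlusion_window_s"])
    if isinstance(data.get("heart_rate_hz"), list):
        data["heart_rate_hz"] = tuple(data["heart_rate_hz"])
    data["region_shape"] = tuple(data["region_shape"])
    return SyntheticCohortConfig(**data)


def write_cohort_config(config: SyntheticCohortConfig, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(cohort_config_to_dict(config), indent=2, sort_keys=True))


def read_cohort_config(path: str | Path) -> SyntheticCohortConfig:
    return cohort_config_from_dict(json.loads(Path(path).read_text()))
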