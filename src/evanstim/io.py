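"""File I/O: TIFF stacks with JSON sidecar metadata, CSV tables, JSON reports.

Pixel counts are preserved exactly — no rescaling on read or write.  Metadata
(frame interval, exposure, pixel size, acquisition start) travels in a JSON
sidecar named ``<image stem>.json`` next to the TIFF.  A multi-frame stack
without frame-interval metadata is an error, never a silent default.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .exceptions import ValidationError
from .loss import CutbackDataset
from .response import ResponseMap
from .stack import OpticalStack

__all__ = [
    "read_stack",
    "write_stack",
    "read_cutback_csv",
    "write_cutback_csv",
    "write_response_map",
    "write_trace_csv",
    "write_json",
    "sha256_of",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_stack(path: str | Path) -> OpticalStack:
    """Read a single- or multi-page TIFF plus its JSON sidecar metadata."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[np.newaxis, ...]
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    frame_interval = meta.get("frame_interval_s")
    if data.shape[0] > 1 and frame_interval is None:
        raise ValidationError(
            f"multi-frame stack {path} has no frame_interval_s metadata "
            f"(expected sidecar {sidecar.name}); refusing to guess a time base"
        )
    return OpticalStack(
        data=data,
        frame_interval_s=frame_interval,
        exposure_s=meta.get("exposure_s", 0.01),
        pixel_size_um=meta.get("pixel_size_um"),
        t0_s=meta.get("t0_s", 0.0),
    )


def write_stack(stack: OpticalStack, path: str | Path) -> Path:
    """Write a stack as TIFF with a JSON metadata sidecar; returns the TIFF path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = stack.data
    if np.issubdtype(data.dtype, np.floating) and np.all(data >= 0) and np.all(
        data == np.rint(data)
    ) and data.max(initial=0) < 2**16:
        data = data.astype(np.uint16)  # integer counts round-trip as 16-bit
    tifffile.imwrite(path, data, photometric="minisblack")
    write_json(stack.metadata(), _sidecar_path(path))
    return path


def read_cutback_csv(path: str | Path, wavelength_nm: float = 489.0) -> CutbackDataset:
    """Read a (length_cm, transmission_dB) table."""
    df = pd.read_csv(path)
    missing = {"length_cm", "transmission_dB"} - set(df.columns)
    if missing:
        raise ValidationError(f"cut-back CSV {path} is missing columns: {sorted(missing)}")
    return CutbackDataset(
        lengths_cm=tuple(df["length_cm"].astype(float)),
        transmissions_dB=tuple(df["transmission_dB"].astype(float)),
        wavelength_nm=wavelength_nm,
    )


def write_cutback_csv(data: CutbackDataset, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"length_cm": data.lengths_cm, "transmission_dB": data.transmissions_dB}
    ).to_csv(path, index=False)
    return path


def write_response_map(result: ResponseMap, path: str | Path) -> Path:
    """Write the normalized score map as 32-bit float TIFF + JSON metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, result.scores.astype(np.float32))
    write_json(result.to_metadata(), _sidecar_path(path))
    return path


def write_trace_csv(times_s: np.ndarray, mean_counts: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_s": times_s, "mean_counts": mean_counts}).to_csv(path, index=False)
    return path


def write_json(obj: dict, path: str | Path) -> Path:
    """Deterministic JSON: sorted keys, no timestamps, trailing newline."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")
    return path


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
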