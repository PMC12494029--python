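"""File formats: OME-TIFF stacks, CSV trace tables, JSON results."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .dynamics import TRACE_COLUMNS
from .synthetic.stack import CHANNELS, ImageStack


def write_ome_tiff(path: str | Path, stack: ImageStack) -> None:
    """Write a (T, C, Y, X) stack as OME-TIFF with physical metadata."""
    tifffile.imwrite(
        str(path),
        stack.data.astype(np.float32),
        ome=True,
        metadata={
            "axes": "TCYX",
            "PhysicalSizeX": stack.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.pixel_size_um,
            "PhysicalSizeYUnit": "µm",
            "TimeIncrement": stack.frame_interval_s,
            "TimeIncrementUnit": "s",
            "Channel": {"Name": list(stack.channels)},
        },
    )


def read_ome_tiff(path: str | Path) -> ImageStack:
    """Read a stack written by :func:`write_ome_tiff`."""
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        meta = tf.ome_metadata or ""
    if data.ndim == 3:  # single frame
        data = data[None]
    px = _ome_float(meta, "PhysicalSizeX", 1.0)
    dt = _ome_float(meta, "TimeIncrement", 1.0)
    return ImageStack(
        data=np.asarray(data, dtype=float),
        pixel_size_um=px,
        frame_interval_s=dt,
        channels=CHANNELS[: data.shape[1]],
    )


def _ome_float(xml: str, key: str, default: float) -> float:
    marker = f'{key}="'
    i = xml.find(marker)
    if i < 0:
        return default
    j = xml.find('"', i + len(marker))
    return float(xml[i + len(marker): j])


def write_traces_csv(path: str | Path, traces: pd.DataFrame) -> None:
    cols = [c for c in TRACE_COLUMNS if c in traces.columns]
    extra = [c for c in traces.columns if c not in cols]
    traces[cols + extra].to_csv(path, index=False, float_format="%.10g")


def read_traces_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace table missing columns: {sorted(missing)}")
    for col in ("time_s", "force_nN", "fak_ratio", "area_um2"):
        df[col] = df[col].astype(float)
    return df


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
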