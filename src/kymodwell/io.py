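"""Reading and writing kymograph TIFFs and event tables."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .kymo_analysis import EVENT_CSV_COLUMNS, EventTrace, Kymograph, traces_to_records


def write_kymograph_tiff(path: str | Path, kymo: Kymograph) -> None:
    """Write a two-channel 16-bit TIFF (channel 0 rhodamine, 1 GFP).

    Imaging geometry is stored as JSON in the image description so the
    file round-trips without sidecar config.
    """
    stack = np.stack([kymo.rhodamine, kymo.gfp])
    stack = np.clip(np.round(stack), 0, 65535).astype(np.uint16)
    meta = {
        "frame_interval_s": kymo.frame_interval,
        "pixel_size_nm": kymo.pixel_size,
        "channels": ["rhodamine", "gfp"],
        "axes": "CTX",
    }
    tifffile.imwrite(str(path), stack, description=json.dumps(meta))


def read_kymograph_tiff(
    path: str | Path,
    frame_interval: float | None = None,
    pixel_size: float | None = None,
    channel_order: str = "auto",
) -> Kymograph:
    """Read a kymograph TIFF written by :func:`write_kymograph_tiff`.

    Geometry falls back to the embedded JSON description; explicit
    arguments override it. ``channel_order`` may be ``"auto"`` (use
    metadata, default rhodamine-first), ``"rg"`` or ``"gr"``.
    """
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray()
        desc = tif.pages[0].description or ""
    meta = {}
    try:
        meta = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        pass
    if arr.ndim != 3 or arr.shape[0] != 2:
        raise ValueError(f"{path}: expected a (2, frames, pixels) TIFF, got {arr.shape}")
    order = channel_order
    if order == "auto":
        channels = meta.get("channels", ["rhodamine", "gfp"])
        order = "rg" if channels[0].startswith("rho") else "gr"
    rho, gfp = (arr[0], arr[1]) if order == "rg" else (arr[1], arr[0])
    fi = frame_interval or meta.get("frame_interval_s")
    px = pixel_size or meta.get("pixel_size_nm")
    if fi is None or px is None:
        raise ValueError(f"{path}: imaging geometry missing; pass it explicitly")
    return Kymograph(rho.astype(float), gfp.astype(float), float(fi), float(px))


def write_events_csv(
    path: str | Path, traces_per_mt: Sequence[Sequence[EventTrace]]
) -> pd.DataFrame:
    """Write the per-event measurement table; returns the DataFrame."""
    records = []
    for mt_id, traces in enumerate(traces_per_mt):
        records.extend(traces_to_records(traces, mt_id))
    df = pd.DataFrame(records, columns=EVENT_CSV_COLUMNS)
    df.to_csv(path, index=False)
    return df


def read_events_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=True)
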