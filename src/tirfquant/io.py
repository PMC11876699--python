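"""File formats: multipage TIFF movies with YAML sidecars, CSV tables,
JSON fit summaries.

Images are written as TIFF with axes ``(frames, channels, y, x)`` (or
``(channels, y, x)`` for snapshots); the channel order, pixel size and
frame interval live in a ``<name>.yaml`` sidecar next to the TIFF.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .binding import Titration
from .images import FOVImage

__all__ = [
    "save_movie",
    "load_movie",
    "save_fov",
    "load_fov",
    "read_lifetimes_csv",
    "write_titration_csv",
    "read_titration_csv",
    "write_json",
]


def _sidecar_path(path) -> Path:
    return Path(path).with_suffix(".yaml")


def save_movie(path, channels: dict, pixel_size_um: float, frame_interval_s: float) -> None:
    """Write a dict of (frames, y, x) channel stacks as one TIFF + sidecar."""
    labels = sorted(channels)
    stack = np.stack([np.asarray(channels[c], dtype=np.float32) for c in labels], axis=1)
    tifffile.imwrite(path, stack, metadata=None)
    meta = {
        "channels": labels,
        "axes": "TCYX",
        "pixel_size_um": float(pixel_size_um),
        "frame_interval_s": float(frame_interval_s),
    }
    _sidecar_path(path).write_text(yaml.safe_dump(meta))


def load_movie(path) -> tuple:
    """Read a movie written by :func:`save_movie`; returns (channels, meta)."""
    stack = tifffile.imread(path)
    meta = yaml.safe_load(_sidecar_path(path).read_text())
    labels = meta["channels"]
    n_ch = len(labels)
    if stack.ndim == 3 and n_ch == 1:
        stack = stack[:, None, :, :]
    elif stack.ndim == 3:  # pages flattened to (T*C, y, x)
        stack = stack.reshape(-1, n_ch, *stack.shape[1:])
    channels = {c: np.asarray(stack[:, i], dtype=float) for i, c in enumerate(labels)}
    return channels, meta


def save_fov(path, fov: FOVImage) -> None:
    labels = sorted(fov.channels)
    stack = np.stack([np.asarray(fov.channels[c], dtype=np.float32) for c in labels])
    tifffile.imwrite(path, stack)
    meta = {"channels": labels, "axes": "CYX", "pixel_size_um": float(fov.pixel_size_um)}
    _sidecar_path(path).write_text(yaml.safe_dump(meta))


def load_fov(path) -> FOVImage:
    stack = tifffile.imread(path)
    meta = yaml.safe_load(_sidecar_path(path).read_text())
    if stack.ndim == 2:
        stack = stack[None]
    channels = {c: np.asarray(stack[i], dtype=float) for i, c in enumerate(meta["channels"])}
    return FOVImage(channels=channels, pixel_size_um=meta["pixel_size_um"])


def read_lifetimes_csv(path) -> np.ndarray:
    """One lifetime (seconds) per row, column ``lifetime_s`` or first column."""
    df = pd.read_csv(path)
    col = "lifetime_s" if "lifetime_s" in df.columns else df.columns[0]
    return df[col].to_numpy(dtype=float)


def write_titration_csv(path, titration: Titration) -> None:
    pd.DataFrame(
        {"titrant_total_M": titration.titrant_total, "response": titration.response}
    ).to_csv(path, index=False)


def read_titration_csv(path, labeled_total: float) -> Titration:
    df = pd.read_csv(path)
    return Titration(
        titrant_total=df["titrant_total_M"].to_numpy(dtype=float),
        response=df["response"].to_numpy(dtype=float),
        labeled_total=labeled_total,
    )


def write_json(path, obj) -> None:
    """Serialize a dataclass or dict to JSON, coercing numpy scalars/arrays."""

    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return {
                k: v for k, v in dataclasses.asdict(o).items()
                if not isinstance(v, np.ndarray)
            }
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer, np.bool_)):
            return o.item()
        raise TypeError(f"cannot serialize {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
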