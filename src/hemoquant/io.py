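"""Reading and writing stacks and tables.

Stacks are stored as plain multi-page TIFF via :mod:`tifffile`, with a JSON
sidecar (``<name>.json``) carrying the axis order and physical calibration.
Tabular results travel as UTF-8 CSV with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .stack import Calibration, ImageStack

__all__ = ["write_stack", "read_stack", "sidecar_path"]


def sidecar_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a TIFF plus calibration sidecar; returns the TIFF path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(stack.data), photometric="minisblack")
    cal = stack.calibration
    meta = {
        "axes": stack.axes,
        "pixel_size_um": cal.pixel_size_um,
        "z_step_um": cal.z_step_um,
        "frame_interval_s": cal.frame_interval_s,
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_stack(path: str | Path) -> ImageStack:
    """Read a TIFF written by :func:`write_stack` (sidecar required)."""
    path = Path(path)
    side = sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(
            f"calibration sidecar {side} not found; stacks need physical units"
        )
    meta = json.loads(side.read_text())
    data = tifffile.imread(path)
    cal = Calibration(
        pixel_size_um=meta["pixel_size_um"],
        z_step_um=meta["z_step_um"],
        frame_interval_s=meta.get("frame_interval_s"),
    )
    return ImageStack(data=data, calibration=cal, axes=meta["axes"])
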