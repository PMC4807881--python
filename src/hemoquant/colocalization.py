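"""Pearson colocalization of two fluorescence channels within a cell mask.

The overlap between two markers is quantified as the sample Pearson
correlation of their pixel intensities over the segmented cell, the
plain (unthresholded) coefficient in [-1, 1]: values near 1 indicate
reliable colocalization, values near -1 mutual exclusion. Correlation is
computed per cell — background pixels outside the mask never enter the
statistic. 3D stacks are reduced to their maximum projection by default,
matching the projection-based scoring workflow; a per-plane mode is
available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, UndefinedCorrelationError
from .segmentation import CellRegion, max_project, mid_plane, segment_cell_body
from .stack import ImageStack

__all__ = ["ColocResult", "pearson_coloc", "coloc_by_group"]


@dataclass
class ColocResult:
    r: float
    n_pixels: int
    channel_a: int = 0
    channel_b: int = 1
    cell_id: str = "cell-0"
    group: str = ""


def pearson_coloc(
    ch_a: np.ndarray,
    ch_b: np.ndarray,
    mask: CellRegion | np.ndarray,
    channel_ids: tuple[int, int] = (0, 1),
) -> ColocResult:
    """Sample Pearson correlation of two images within a mask.

    Raises :class:`UndefinedCorrelationError` if either channel is
    constant within the mask — an undefined correlation is never
    silently reported as 0.
    """
    a = np.asarray(ch_a, dtype=np.float64)
    b = np.asarray(ch_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ConfigError(f"channel shapes differ: {a.shape} vs {b.shape}")
    m = mask.mask2d if isinstance(mask, CellRegion) else np.asarray(mask, dtype=bool)
    if m.shape != a.shape:
        raise ConfigError(f"mask shape {m.shape} does not match images {a.shape}")
    n = int(m.sum())
    if n < 2:
        raise ConfigError(f"mask must contain >= 2 pixels, got {n}")
    va, vb = a[m], b[m]
    if va.std() == 0 or vb.std() == 0:
        raise UndefinedCorrelationError(
            "a channel is constant within the mask; Pearson r is undefined"
        )
    cell_id = mask.cell_id if isinstance(mask, CellRegion) else "cell-0"
    r = float(np.corrcoef(va, vb)[0, 1])
    return ColocResult(
        r=r, n_pixels=n, channel_a=channel_ids[0], channel_b=channel_ids[1],
        cell_id=cell_id,
    )


def coloc_by_group(
    scenes: list[tuple[ImageStack, str]],
    pairs: list[tuple[int, int]] = [(0, 1)],
    mask_channel: int = 0,
    mode: str = "projection",
    plane: int | None = None,
) -> pd.DataFrame:
    """Per-cell Pearson r for a list of labelled scenes.

    Each scene is segmented on ``mask_channel`` and every requested
    channel pair is correlated within the resulting cell mask on the
    maximum projection (default) or a fixed plane. The result is a tidy
    table (cell_id, group, channel_a, channel_b, r, n_pixels, error);
    per-cell failures are flagged rows with ``r`` = NaN, never aborts.
    """
    rows = []
    for i, (stack, group) in enumerate(scenes):
        cell_id = f"cell-{i}"
        for ca, cb in pairs:
            row = {
                "cell_id": cell_id,
                "group": group,
                "channel_a": ca,
                "channel_b": cb,
                "r": np.nan,
                "n_pixels": 0,
                "error": "",
            }
            try:
                cell = segment_cell_body(stack, mask_channel, cell_id=cell_id)
                if mode == "projection":
                    img_a = max_project(stack, ca)
                    img_b = max_project(stack, cb)
                elif mode == "plane":
                    z = cell.reference_plane if plane is None else plane
                    img_a = mid_plane(stack, ca, z)
                    img_b = mid_plane(stack, cb, z)
                else:
                    raise ConfigError(f"unknown mode {mode!r}")
                res = pearson_coloc(img_a, img_b, cell, channel_ids=(ca, cb))
                row["r"] = res.r
                row["n_pixels"] = res.n_pixels
            except Exception as exc:  # flagged row, not an abort
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["cell_id", "group", "channel_a", "channel_b", "r", "n_pixels", "error"],
    )
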