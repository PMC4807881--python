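"""Calibrated multi-channel image stacks.

All imaging operations in this package exchange a single container, the
:class:`ImageStack`: a ``(C, Z, Y, X)`` volume or a ``(C, T, Z, Y, X)``
time-lapse together with its physical calibration. Axis order is fixed —
channel first, then time (if present), then z, y, x. The x–y plane is
isotropic (one pixel size); the z step is independent, matching confocal
acquisition where the optical section spacing differs from the lateral
sampling. Lengths are micrometres, time is seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Calibration", "ImageStack"]


@dataclass(frozen=True)
class Calibration:
    """Physical pixel/frame calibration.

    Parameters
    ----------
    pixel_size_um : float
        Lateral sampling in µm per pixel (x and y, isotropic).
    z_step_um : float
        Axial spacing between optical sections in µm.
    frame_interval_s : float, optional
        Time between frames in seconds; ``None`` for single-timepoint
        stacks. Frame intervals are a per-movie property, never assumed
        equal across movies.
    """

    pixel_size_um: float
    z_step_um: float
    frame_interval_s: float | None = None

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.z_step_um <= 0:
            raise ValueError(f"z_step_um must be > 0, got {self.z_step_um}")
        if self.frame_interval_s is not None and self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0 when given")

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2

    @property
    def voxel_volume_um3(self) -> float:
        return self.pixel_size_um**2 * self.z_step_um


@dataclass
class ImageStack:
    """A calibrated intensity grid, ``CZYX`` or ``CTZYX``."""

    data: np.ndarray
    calibration: Calibration
    axes: str = field(default="")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not self.axes:
            self.axes = {4: "CZYX", 5: "CTZYX"}.get(self.data.ndim, "")
        if self.axes not in ("CZYX", "CTZYX"):
            raise ValueError(f"unsupported axes {self.axes!r}; use CZYX or CTZYX")
        if self.data.ndim != len(self.axes):
            raise ValueError(
                f"data has {self.data.ndim} dims but axes is {self.axes!r}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def has_time(self) -> bool:
        return self.axes == "CTZYX"

    @property
    def n_frames(self) -> int:
        return self.data.shape[1] if self.has_time else 1

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[-3:])

    def channel(self, c: int) -> np.ndarray:
        """Return channel ``c`` as a ``(Z, Y, X)`` or ``(T, Z, Y, X)`` view."""
        if not 0 <= c < self.n_channels:
            raise IndexError(f"channel {c} out of range (0..{self.n_channels - 1})")
        return self.data[c]

    def frame(self, c: int, t: int) -> np.ndarray:
        """Return a single ``(Z, Y, X)`` frame of channel ``c``."""
        vol = self.channel(c)
        if self.has_time:
            if not 0 <= t < self.n_frames:
                raise IndexError(f"frame {t} out of range (0..{self.n_frames - 1})")
            return vol[t]
        if t != 0:
            raise IndexError("stack has no time axis; only t=0 is valid")
        return vol
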