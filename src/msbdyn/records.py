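"""Shared measurement containers.

Axis conventions used throughout the package:

* voxel arrays are indexed ``(z, y, x)`` (2D arrays: ``(y, x)``);
* physical coordinates are ``(x, y, z)`` tuples in micrometres;
* voxel index = ``floor(position / voxel_size)``, so the centre of voxel
  ``i`` sits at ``(i + 0.5) * voxel_size``;
* image stacks are ordered ``T, Z, C, Y, X`` with channel 0 the presynaptic
  marker and channel 1 the dendrite/spine fill.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError

PRESYNAPTIC_CHANNEL = 0
FILL_CHANNEL = 1


@dataclass
class ImageStack:
    """Two-channel, time-resolved voxel intensities with physical calibration.

    Parameters
    ----------
    data
        Non-negative integer intensities, shape ``(T, Z, C, Y, X)``.
    pixel_size_xy, z_step
        Voxel size in micrometres.
    frame_interval
        Time between frames in hours.
    channel_roles
        Role of each channel, by index.
    """

    data: np.ndarray
    pixel_size_xy: float
    z_step: float
    frame_interval: float = 1.0
    channel_roles: tuple[str, ...] = ("presynaptic", "fill")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ConfigError("data: expected a T,Z,C,Y,X array")
        if min(self.data.shape) < 1:
            raise ConfigError("data: every dimension must be >= 1")
        if np.issubdtype(self.data.dtype, np.integer) and self.data.min() < 0:
            raise ConfigError("data: intensities must be non-negative")
        for name in ("pixel_size_xy", "z_step", "frame_interval"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name}: must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def frame(self, t: int, channel: int) -> np.ndarray:
        """Single-channel 3D volume ``(Z, Y, X)`` at frame ``t``."""
        return self.data[t, :, channel]

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class PunctumRecord:
    """A segmented fluorescent punctum (typically a presynaptic bouton).

    ``region`` holds the voxel indices of the component as an ``(n, ndim)``
    integer array in ``(z, y, x)`` (or ``(y, x)``) order; ``centroid_um`` is
    the intensity-weighted centre of mass in physical ``(x, y, z)`` µm
    (z omitted for 2D sources).
    """

    id: int
    channel: int
    frame: int
    centroid_um: tuple[float, ...]
    region: np.ndarray
    total_intensity: float
    pixel_size_xy: float | None = None
    z_step: float | None = None


@dataclass
class SpineRecord:
    """A dendritic spine head with its shaft attachment point.

    ``head_um`` is the intensity-weighted head centre of mass and
    ``base_um`` the nearest shaft voxel centre, both physical ``(x, y, z)``
    µm. ``integrated_density`` is the head-region intensity sum
    (mean brightness × area).
    """

    id: int
    frame: int
    head_um: tuple[float, float, float]
    base_um: tuple[float, float, float]
    region: np.ndarray | None = None
    head_area_um2: float | None = None
    integrated_density: float | None = None
    pixel_size_xy: float | None = None
    z_step: float | None = None
    truth_id: int | None = field(default=None, compare=False)
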