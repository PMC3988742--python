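"""Scalar image container shared by all modules.

An :class:`ImageGrid` is a 2D or 3D scalar intensity field together with a
per-axis physical voxel spacing.  All geometry inside the segmentation engine
is done in voxel units; spacing only matters when surfaces are extracted or
files are written.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageGrid:
    """A 2D/3D scalar field with per-axis voxel spacing.

    Parameters
    ----------
    data
        Array of intensities, ``float`` dtype, indexed ``(row, col)`` in 2D or
        ``(plane, row, col)`` in 3D.
    spacing
        Physical size of one voxel along each axis, same length as
        ``data.ndim``. Defaults to isotropic 1.0.
    """

    data: np.ndarray
    spacing: tuple = field(default=None)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (2, 3):
            raise ValueError(f"ImageGrid must be 2D or 3D, got ndim={self.data.ndim}")
        if self.spacing is None:
            self.spacing = (1.0,) * self.data.ndim
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != self.data.ndim:
            raise ValueError("spacing length must match data.ndim")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def dynamic_range(self) -> float:
        """Peak-to-peak intensity range (0 for a constant image)."""
        return float(np.ptp(self.data))


def as_image(obj) -> ImageGrid:
    """Coerce an array or ImageGrid into an ImageGrid."""
    if isinstance(obj, ImageGrid):
        return obj
    return ImageGrid(np.asarray(obj, dtype=float))
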