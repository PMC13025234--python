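"""Physical image geometry.

All public quantities in this package are expressed in physical units
(micrometres) rather than pixels; :class:`ImageGeometry` is the single
place where the pixel/voxel grid is tied to physical spacing.  Axis
order follows the numpy convention: ``(y, x)`` in 2D and ``(z, y, x)``
in 3D, with the z axis allowed a coarser spacing than the lateral axes
(the usual situation for confocal stacks).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import GeometryError

MIN_AXIS_LENGTH = 16


@dataclass(frozen=True)
class ImageGeometry:
    """Pixel/voxel grid with physical spacing.

    Parameters
    ----------
    shape
        Array shape, ``(y, x)`` or ``(z, y, x)``.
    spacing
        Physical size of one pixel/voxel along each axis, in µm, same
        order as ``shape``.  2D default in this package is 0.1 µm/px;
        3D stacks are typically anisotropic with z coarser than xy.
    """

    shape: tuple[int, ...]
    spacing: tuple[float, ...]

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        if len(shape) not in (2, 3):
            raise GeometryError(f"shape must be 2D or 3D, got {len(shape)} axes")
        if len(spacing) != len(shape):
            raise GeometryError("spacing must have one entry per axis")
        if any(s < MIN_AXIS_LENGTH for s in shape):
            raise GeometryError(f"every axis must span at least {MIN_AXIS_LENGTH} pixels")
        if any(not math.isfinite(s) or s <= 0 for s in spacing):
            raise GeometryError("all spacing values must be positive and finite")

    @property
    def n_dims(self) -> int:
        return len(self.shape)

    @property
    def extent_um(self) -> tuple[float, ...]:
        """Physical field size along each axis, in µm."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    @property
    def pixel_area_um2(self) -> float:
        if self.n_dims != 2:
            raise GeometryError("pixel_area_um2 is defined for 2D geometries only")
        return self.spacing[0] * self.spacing[1]

    @property
    def voxel_volume_um3(self) -> float:
        if self.n_dims != 3:
            raise GeometryError("voxel_volume_um3 is defined for 3D geometries only")
        return self.spacing[0] * self.spacing[1] * self.spacing[2]

    @property
    def is_isotropic_xy(self) -> bool:
        return math.isclose(self.spacing[-1], self.spacing[-2], rel_tol=1e-9)

    def require_matching(self, array_shape: tuple[int, ...]) -> None:
        if tuple(array_shape) != self.shape:
            raise GeometryError(
                f"array shape {tuple(array_shape)} does not match geometry {self.shape}"
            )
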