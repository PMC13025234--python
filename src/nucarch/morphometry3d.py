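"""3D segmentation and volumetric shape measurement.

Sphericity follows Ψ = π^(1/3) (6V)^(2/3) / SA (1 for a perfect ball).
Volume is voxel count × voxel volume; surface area comes from a
marching-cubes iso-surface extracted, with physical spacing applied,
from a lightly smoothed copy of the binary object.  Counting voxel
faces instead would overestimate the area of a sphere by ~50 % and
destroy the Ψ → 1 limit; smoothing before meshing removes the residual
staircase bias of marching cubes on binary data (the level-0.5 surface
of a symmetrically blurred mask tracks the original interface).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_fill_holes, find_objects, gaussian_filter
from skimage.measure import label as cc_label
from skimage.measure import marching_cubes, mesh_surface_area, regionprops
from skimage.morphology import remove_small_objects
from skimage.segmentation import clear_border

from .errors import GeometryError
from .geometry import ImageGeometry
from .morphometry2d import SegmentationParams, _smoothed, _threshold_mask

METRICS_3D_COLUMNS = [
    "label", "volume_um3", "surface_um2", "sphericity",
    "centroid_z_um", "centroid_y_um", "centroid_x_um",
]

# Pre-mesh smoothing of the binary object, as a multiple of the
# geometric-mean voxel pitch.  Calibrated on closed forms: at 0.7 a
# radius-20-voxel ball measures within ~1 % of 4πr² while cube faces
# and edges are barely eroded (side-50 cube within ~2.4 %).
MESH_SMOOTHING_PITCH = 0.7


@dataclass
class LabeledObjects3D:
    """Connected components (26-connectivity) of one 3D channel."""

    label_mask: np.ndarray
    geometry: ImageGeometry
    source_channel: str = ""

    @property
    def n_objects(self) -> int:
        return int(self.label_mask.max())


def segment_3d(
    channel: np.ndarray,
    geometry: ImageGeometry,
    params: SegmentationParams,
    source_channel: str = "",
    exclude_z_border: bool = True,
) -> LabeledObjects3D:
    """Threshold-based 3D segmentation.

    As :func:`~nucarch.morphometry2d.segment_2d` but 26-connected, with
    ``min_size`` in µm³, holes filled per z-slice and then in 3D (so
    meshes are closed), and — by default — objects touching the first
    or last z-plane removed, since their volumes are incomplete.
    """
    params.validate()
    if geometry.n_dims != 3:
        raise GeometryError("segment_3d requires a 3D geometry and stack")
    geometry.require_matching(np.shape(channel))
    img = _smoothed(channel, geometry, params.smoothing_sigma)
    mask = _threshold_mask(img, params)
    if params.fill_holes:
        for z in range(mask.shape[0]):
            mask[z] = binary_fill_holes(mask[z])
        mask = binary_fill_holes(mask)
    if params.exclude_border:
        # lateral borders only; the z boundary is handled separately
        mask = np.moveaxis(clear_border(np.moveaxis(mask, 0, -1)), -1, 0)
    min_vox = int(math.ceil(params.min_size / geometry.voxel_volume_um3))
    if min_vox > 1:
        # keep components of at least min_vox voxels
        mask = remove_small_objects(mask, connectivity=3, max_size=min_vox - 1)
    labels = cc_label(mask, connectivity=3)
    if exclude_z_border:
        touching = np.union1d(np.unique(labels[0]), np.unique(labels[-1]))
        labels[np.isin(labels, touching[touching > 0])] = 0
    # relabel consecutively
    labels = cc_label(labels > 0, connectivity=3).astype(np.int32)
    return LabeledObjects3D(labels, geometry, source_channel)


def _object_surface_area(binary: np.ndarray, spacing) -> float:
    sigma_um = MESH_SMOOTHING_PITCH * float(np.prod(spacing)) ** (1.0 / 3.0)
    sigma_vox = tuple(sigma_um / s for s in spacing)
    pad = tuple(int(math.ceil(3 * sv)) + 2 for sv in sigma_vox)
    padded = np.pad(binary.astype(np.float64), [(p, p) for p in pad])
    smooth = gaussian_filter(padded, sigma=sigma_vox)
    verts, faces, _, _ = marching_cubes(smooth, level=0.5, spacing=tuple(spacing))
    return float(mesh_surface_area(verts, faces))


def measure_3d(objects: LabeledObjects3D) -> pd.DataFrame:
    """Per-object volume (µm³), iso-surface area (µm²), sphericity
    (clipped to 1) and centroid (µm).

    Single-voxel objects have no meaningful iso-surface; they are
    skipped with a warning.
    """
    geom = objects.geometry
    if geom.n_dims != 3:
        raise GeometryError("measure_3d requires a 3D geometry")
    spacing = geom.spacing
    voxvol = geom.voxel_volume_um3
    labels = objects.label_mask
    locations = find_objects(labels)
    rows = []
    for region in regionprops(labels):
        if region.area <= 1:
            warnings.warn(
                f"object {region.label} has a single voxel; skipping (degenerate mesh)",
                stacklevel=2,
            )
            continue
        sl = locations[region.label - 1]
        binary = labels[sl] == region.label
        volume = region.area * voxvol
        sa = _object_surface_area(binary, spacing)
        sph = min(1.0, math.pi ** (1 / 3) * (6.0 * volume) ** (2 / 3) / sa)
        cz, cy, cx = region.centroid
        rows.append(
            dict(
                label=int(region.label),
                volume_um3=float(volume),
                surface_um2=float(sa),
                sphericity=float(sph),
                centroid_z_um=float((cz + 0.5) * spacing[0]),
                centroid_y_um=float((cy + 0.5) * spacing[1]),
                centroid_x_um=float((cx + 0.5) * spacing[2]),
            )
        )
    return pd.DataFrame(rows, columns=METRICS_3D_COLUMNS)
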