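"""2D segmentation and shape measurement in physical units.

Circularity follows the convention 4πA/P² (1 for a perfect circle).
The perimeter is the length of the sub-pixel 0.5-level contour of the
lightly smoothed binary object (marching squares), the 2D analogue of
the iso-surface meshing used for 3D surface areas.  This estimator
recovers both the circle limit (circularity 1) and straight-edged
shapes (square → π/4) to well under a percent, where direction-limited
Crofton formulas carry an intrinsic ~5 % bias on axis-aligned edges.
All outputs are in µm/µm²; pixel units are never exposed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import binary_fill_holes, gaussian_filter
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, perimeter_crofton
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import remove_small_objects
from skimage.segmentation import clear_border

from .errors import GeometryError
from .geometry import ImageGeometry

METRICS_2D_COLUMNS = [
    "label", "area_um2", "perimeter_um", "circularity",
    "centroid_y_um", "centroid_x_um",
]

# Pre-contour smoothing of the binary object, in pixels.  Lattice
# staircase artifacts live at the pixel scale, so the parameter is a
# pixel quantity; 1.5 px suppresses the staircase to <0.2 % on discs of
# radius >= 50 px while leaving straight edges essentially untouched.
CONTOUR_SMOOTHING_PX = 1.5


def _contour_perimeter_px(binary: np.ndarray) -> float:
    """Length (in px) of the 0.5-level contour of a smoothed binary patch."""
    sigma = CONTOUR_SMOOTHING_PX
    pad = int(math.ceil(3 * sigma)) + 2
    img = np.pad(binary.astype(np.float64), pad)
    img = gaussian_filter(img, sigma)
    contours = find_contours(img, 0.5)
    if not contours:
        # object too small to support a 0.5 level set after smoothing
        return float(perimeter_crofton(binary, directions=4))
    return float(
        sum(np.sum(np.hypot(*np.diff(c, axis=0).T)) for c in contours)
    )


@dataclass(frozen=True)
class SegmentationParams:
    """Uniform segmentation parameter set.

    ``threshold`` is either the string ``"otsu"`` (per-image automatic
    threshold) or a fixed intensity.  Freezing the threshold from
    baseline images and reusing the resulting fixed value across
    conditions keeps quantification directly comparable (see
    :func:`freeze_threshold`).  ``min_size`` is in µm² (2D) or µm³ (3D).
    """

    smoothing_sigma: float = 0.15
    threshold: str | float = "otsu"
    min_size: float = 0.5
    fill_holes: bool = True
    exclude_border: bool = True

    def validate(self) -> None:
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")
        if self.min_size < 0:
            raise ValueError("min_size must be >= 0")
        if isinstance(self.threshold, str) and self.threshold != "otsu":
            raise ValueError(f"unknown threshold mode {self.threshold!r}")

    def with_threshold(self, value: float) -> "SegmentationParams":
        return replace(self, threshold=float(value))


@dataclass
class LabeledObjects2D:
    """Connected components of one channel: 0 = background, labels are
    consecutive positive integers."""

    label_mask: np.ndarray
    geometry: ImageGeometry
    source_channel: str = ""

    @property
    def n_objects(self) -> int:
        return int(self.label_mask.max())


def _smoothed(channel: np.ndarray, geometry: ImageGeometry, sigma_um: float) -> np.ndarray:
    img = np.asarray(channel, dtype=np.float64)
    if sigma_um > 0:
        img = gaussian_filter(img, sigma=tuple(sigma_um / s for s in geometry.spacing))
    return img


def freeze_threshold(
    channels: list[np.ndarray], geometry: ImageGeometry, params: SegmentationParams
) -> float:
    """Otsu threshold pooled over baseline images, for uniform reuse.

    Deriving a single threshold from 0-h samples and applying it
    unchanged to every condition and time point removes the per-image
    adaptive component from between-condition comparisons.
    """
    pooled = np.concatenate(
        [_smoothed(c, geometry, params.smoothing_sigma).ravel() for c in channels]
    )
    return float(threshold_otsu(pooled))


def _threshold_mask(img: np.ndarray, params: SegmentationParams) -> np.ndarray:
    if isinstance(params.threshold, str):  # otsu
        if img.max() == img.min():
            return np.zeros(img.shape, dtype=bool)
        t = threshold_otsu(img)
    else:
        t = float(params.threshold)
    return img > t


def segment_2d(
    channel: np.ndarray,
    geometry: ImageGeometry,
    params: SegmentationParams,
    source_channel: str = "",
) -> LabeledObjects2D:
    """Threshold-based 2D segmentation.

    Gaussian smoothing, Otsu or fixed threshold, optional hole filling
    and border exclusion, removal of components below ``min_size`` µm²,
    8-connected labelling.  A constant image under Otsu yields zero
    objects.
    """
    params.validate()
    if geometry.n_dims != 2:
        raise GeometryError("segment_2d requires a 2D geometry")
    geometry.require_matching(np.shape(channel))
    img = _smoothed(channel, geometry, params.smoothing_sigma)
    mask = _threshold_mask(img, params)
    if params.fill_holes:
        mask = binary_fill_holes(mask)
    if params.exclude_border:
        mask = clear_border(mask)
    min_px = int(math.ceil(params.min_size / geometry.pixel_area_um2))
    if min_px > 1:
        # keep components of at least min_px pixels
        mask = remove_small_objects(mask, connectivity=2, max_size=min_px - 1)
    labels = cc_label(mask, connectivity=2).astype(np.int32)
    return LabeledObjects2D(labels, geometry, source_channel)


def measure_2d(objects: LabeledObjects2D) -> pd.DataFrame:
    """Per-object area (µm²), contour perimeter (µm), circularity
    (clipped to 1) and centroid (µm)."""
    geom = objects.geometry
    if geom.n_dims != 2:
        raise GeometryError("measure_2d requires a 2D geometry")
    if not geom.is_isotropic_xy:
        raise GeometryError("2D morphometry requires isotropic pixels")
    s = geom.spacing[0]
    rows = []
    for region in regionprops(objects.label_mask):
        area = region.area * geom.pixel_area_um2
        perim = _contour_perimeter_px(region.image) * s
        circ = 1.0 if perim == 0 else min(1.0, 4.0 * math.pi * area / perim**2)
        cy, cx = region.centroid
        rows.append(
            dict(
                label=int(region.label),
                area_um2=float(area),
                perimeter_um=float(perim),
                circularity=float(circ),
                centroid_y_um=float((cy + 0.5) * geom.spacing[0]),
                centroid_x_um=float((cx + 0.5) * geom.spacing[1]),
            )
        )
    return pd.DataFrame(rows, columns=METRICS_2D_COLUMNS)


@dataclass
class CompartmentAssignment:
    """Majority-overlap child→parent map; children overlapping no parent
    by at least 50 % of their own pixels are orphans."""

    mapping: dict[int, int]
    orphans: list[int]


def assign_compartments(parents, children) -> CompartmentAssignment:
    """Assign each child object to the parent holding the majority of
    its pixels.  Works identically for 2D and 3D label masks.  Exact
    50/50 ties go to the lower parent label."""
    if parents.geometry != children.geometry:
        raise GeometryError("parent and child label masks must share a geometry")
    child = children.label_mask.ravel()
    parent = parents.label_mask.ravel()
    sel = child > 0
    child_sizes = np.bincount(child[sel])
    mapping: dict[int, int] = {}
    orphans: list[int] = []
    if child_sizes.size == 0:
        return CompartmentAssignment(mapping, orphans)

    inside = sel & (parent > 0)
    n_parent = int(parent.max()) + 1
    pair = child[inside].astype(np.int64) * n_parent + parent[inside]
    counts = np.bincount(pair)
    nz = np.flatnonzero(counts)
    best_count = {}
    best_parent = {}
    for code in nz:  # ascending code order -> lower parent label wins ties
        c_label = int(code // n_parent)
        p_label = int(code % n_parent)
        cnt = int(counts[code])
        if cnt > best_count.get(c_label, 0):
            best_count[c_label] = cnt
            best_parent[c_label] = p_label
    for c_label in range(1, len(child_sizes)):
        size = child_sizes[c_label]
        if size == 0:
            continue
        cnt = best_count.get(c_label, 0)
        if cnt * 2 >= size and cnt > 0:
            mapping[c_label] = best_parent[c_label]
        else:
            orphans.append(c_label)
    return CompartmentAssignment(mapping, orphans)
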