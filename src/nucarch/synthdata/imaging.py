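"""Seeded rendering of synthetic multi-channel nuclear images.

Each image carries four channels — nuclear stain plus nucleolin,
fibrillarin and SC-35 — together with ground-truth label masks and a
per-object truth-metrics table computed from the analytic generator
geometry (polygon/mesh), not from the raster.  Rendering follows the
simplest model that reproduces threshold-relevant edge blur: analytic
shape → binary raster → Gaussian PSF → additive Gaussian (and optional
Poisson) noise → 16-bit output.

2D images represent a single focal plane; 3D stacks model a monolayer
of adherent nuclei flattened along the optical axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from ..errors import CrowdedFieldError, GeometryError
from ..geometry import ImageGeometry
from . import shapes
from .specs import (
    CHANNEL_ORDER,
    NUCLEUS,
    CompartmentSpec,
    NoiseSpec,
    NuclearPhenotypeSpec,
)

FOREGROUND = 10000.0
MAX_PLACEMENT_RETRIES = 1000
_COMPARTMENT_TRIES = 100
TWO_PI = 2.0 * math.pi
# minimum clear gap between sibling compartment objects (µm); keeps
# separately generated objects separable after PSF blur
_SIBLING_GAP = 0.4


@dataclass
class SyntheticImage:
    """Rendered image plus generator-side ground truth."""

    geometry: ImageGeometry
    channels: dict[str, np.ndarray]
    truth_masks: dict[str, np.ndarray]
    truth_metrics: pd.DataFrame
    seed: int
    channel_order: tuple[str, ...] = field(default=CHANNEL_ORDER)


def _lognormal_sizes(rng, n, mean, cv):
    if cv == 0.0:
        return np.full(n, float(mean))
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - 0.5 * sigma2
    return np.exp(rng.normal(mu, math.sqrt(sigma2), size=n))


def _lognormal_mean_sigma(rng, n, mean, sigma_log):
    mu = math.log(mean) - 0.5 * sigma_log * sigma_log
    return np.exp(rng.normal(mu, sigma_log, size=n))


def _fibonacci_sphere(n=64):
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    golden = math.pi * (3.0 - math.sqrt(5.0))
    phi = golden * i
    return np.stack([z, r * np.sin(phi), r * np.cos(phi)], axis=1)  # (z, y, x)


_SPHERE_DIRS = _fibonacci_sphere(64)
_CIRCLE_DIRS = np.stack(
    [np.sin(np.linspace(0, 2 * math.pi, 48, endpoint=False)),
     np.cos(np.linspace(0, 2 * math.pi, 48, endpoint=False))],
    axis=1,
)  # (y, x)


# ---------------------------------------------------------------------------
# rasterization


def rasterize_boundary_2d(boundary, geometry: ImageGeometry, center_um) -> np.ndarray:
    """Boolean raster of a star-shaped 2D boundary (pixel-center test;
    pixel i covers [i, i+1) * spacing with its center at
    (i + 0.5) * spacing)."""
    half = (boundary.max_radius,) * 2
    slices = _bbox_slices(geometry, center_um, half)
    yy, xx = _voxel_centers(geometry, slices)
    dy = yy - center_um[0]
    dx = xx - center_um[1]
    rho = np.hypot(dy, dx)
    theta = np.mod(np.arctan2(dy, dx), TWO_PI)
    rad = np.interp(theta, boundary.theta, boundary.radii, period=TWO_PI)
    mask = np.zeros(geometry.shape, dtype=bool)
    mask[slices] = rho <= rad
    return mask


def _local_ball(geometry: ImageGeometry, center_um, radius_um):
    """(slices, inside) for a disc/ball on the voxel-center grid,
    restricted to its bounding box."""
    slices = _bbox_slices(geometry, center_um, (radius_um,) * geometry.n_dims)
    grids = _voxel_centers(geometry, slices)
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center_um))
    return slices, dist2 <= radius_um**2


def _bbox_slices(geometry, center_um, half_extent_um):
    slices = []
    for c, h, n, s in zip(center_um, half_extent_um, geometry.shape, geometry.spacing):
        lo = max(0, int(math.floor((c - h) / s)) - 1)
        hi = min(n, int(math.ceil((c + h) / s)) + 2)
        slices.append(slice(lo, hi))
    return tuple(slices)


def _voxel_centers(geometry, slices):
    axes = [
        (np.arange(sl.start, sl.stop) + 0.5) * s
        for sl, s in zip(slices, geometry.spacing)
    ]
    return np.meshgrid(*axes, indexing="ij")


def rasterize_surface_3d(surface, geometry: ImageGeometry, center_um) -> np.ndarray:
    """Boolean raster of a star-shaped 3D surface (voxel-center test)."""
    half = (surface.max_extent_z, surface.max_radius_xy, surface.max_radius_xy)
    slices = _bbox_slices(geometry, center_um, half)
    zz, yy, xx = _voxel_centers(geometry, slices)
    dz = zz - center_um[0]
    dy = yy - center_um[1]
    dx = xx - center_um[2]
    rho = np.sqrt(dz * dz + dy * dy + dx * dx)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(np.where(rho > 0, dz / np.where(rho > 0, rho, 1.0), 1.0), -1, 1))
    phi = np.arctan2(dy, dx)
    rad = surface.radius_at(theta, phi)
    inside = rho <= rad
    mask = np.zeros(geometry.shape, dtype=bool)
    mask[slices] = inside
    return mask


# ---------------------------------------------------------------------------
# placement


def _place_nuclei(rng, radii_xy, geometry: ImageGeometry, border_pad=0.5):
    """Rejection-sampled non-overlapping xy centers.

    Minimum center separation is r_i + r_j + max(r_i, r_j): one object
    radius of clear margin between neighbouring boundaries.
    """
    ext = geometry.extent_um
    ext_y, ext_x = ext[-2], ext[-1]
    centers = []
    for i, r in enumerate(radii_xy):
        lo_y, hi_y = r + border_pad, ext_y - r - border_pad
        lo_x, hi_x = r + border_pad, ext_x - r - border_pad
        if lo_y >= hi_y or lo_x >= hi_x:
            raise GeometryError(
                f"nucleus of radius {r:.2f} um does not fit the "
                f"{ext_y:.1f} x {ext_x:.1f} um field"
            )
        for _ in range(MAX_PLACEMENT_RETRIES):
            cy = rng.uniform(lo_y, hi_y)
            cx = rng.uniform(lo_x, hi_x)
            ok = True
            for (oy, ox), ro in centers:
                if math.hypot(cy - oy, cx - ox) < r + ro + max(r, ro):
                    ok = False
                    break
            if ok:
                centers.append(((cy, cx), r))
                break
        else:
            raise CrowdedFieldError(
                f"field too crowded: failed to place nucleus {i + 1} of "
                f"{len(radii_xy)} after {MAX_PLACEMENT_RETRIES} attempts"
            )
    return [c for c, _ in centers]


def _contained_2d(boundary, offset, radius, eps):
    pts = offset[None, :] + radius * _CIRCLE_DIRS
    rho = np.hypot(pts[:, 0], pts[:, 1])
    theta = np.arctan2(pts[:, 0], pts[:, 1])  # y, x -> polar angle
    return bool(np.all(rho + eps <= boundary.radius_at(theta)))


def _contained_3d(surface, offset, radius, eps):
    pts = offset[None, :] + radius * _SPHERE_DIRS
    rho = np.linalg.norm(pts, axis=1)
    safe = np.where(rho > 0, rho, 1.0)
    theta = np.arccos(np.clip(pts[:, 0] / safe, -1, 1))
    phi = np.arctan2(pts[:, 1], pts[:, 2])
    return bool(np.all(rho + eps <= surface.radius_at(theta, phi)))


# ---------------------------------------------------------------------------
# main generator


def generate_image(
    spec: NuclearPhenotypeSpec,
    compartments: list[CompartmentSpec],
    noise: NoiseSpec,
    geometry: ImageGeometry,
    seed: int,
) -> SyntheticImage:
    """Render one seeded synthetic field.

    Identical ``(spec, compartments, noise, geometry, seed)`` give
    bit-identical output.  Raises :class:`CrowdedFieldError` when the
    requested cell count cannot be placed and :class:`GeometryError`
    when a nucleus cannot fit the field at all.
    """
    spec.validate()
    noise.validate()
    for comp in compartments:
        comp.validate()
    markers = [c.marker for c in compartments]
    if len(set(markers)) != len(markers):
        raise ValueError("duplicate compartment markers")
    for comp in compartments:
        if comp.nesting is not None and comp.nesting not in markers:
            raise ValueError(f"compartment {comp.marker} nests in absent marker {comp.nesting}")

    ndim = geometry.n_dims
    ss = np.random.SeedSequence(int(seed))
    rng_shape, rng_place, rng_comp, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    sizes = _lognormal_sizes(rng_shape, spec.n_cells, spec.mean_size, spec.size_cv)
    if ndim == 2:
        nuclei = [
            shapes.build_boundary_2d(
                rng_shape,
                area=s,
                n_harmonics=spec.irregularity_harmonics,
                amplitude=spec.irregularity_amplitude,
                target_circularity=spec.target_shape,
            )
            for s in sizes
        ]
        radii_xy = [n.max_radius for n in nuclei]
    else:
        nuclei = [
            shapes.build_surface_3d(
                rng_shape,
                volume=s,
                n_modes=spec.irregularity_harmonics,
                amplitude=spec.irregularity_amplitude,
                target_sphericity=spec.target_shape,
            )
            for s in sizes
        ]
        radii_xy = [n.max_radius_xy for n in nuclei]

    centers_xy = _place_nuclei(rng_place, radii_xy, geometry)

    if ndim == 3:
        depth = geometry.extent_um[0]
        z_pad = geometry.spacing[0]
        centers = []
        for nuc, (cy, cx) in zip(nuclei, centers_xy):
            ext_z = nuc.max_extent_z
            if 2 * (ext_z + z_pad) > depth:
                raise GeometryError(
                    f"stack depth {depth:.1f} um too shallow for nucleus of "
                    f"z-extent {2 * ext_z:.1f} um"
                )
            jitter_lim = min(0.05 * depth, depth / 2 - ext_z - z_pad)
            cz = depth / 2 + rng_place.uniform(-jitter_lim, jitter_lim)
            centers.append((cz, cy, cx))
    else:
        centers = centers_xy

    # --- rasterize nuclei and collect truth -------------------------------
    masks = {name: np.zeros(geometry.shape, dtype=np.int32) for name in CHANNEL_ORDER}
    rows = []
    eps = max(geometry.spacing)
    for label, (nuc, center) in enumerate(zip(nuclei, centers), start=1):
        if ndim == 2:
            m = rasterize_boundary_2d(nuc, geometry, center)
            area, perim, circ = nuc.metrics()
            rows.append(
                dict(
                    channel=NUCLEUS, label=label, parent_channel="", parent_label=0,
                    area_um2=area, perimeter_um=perim, circularity=circ,
                    centroid_y_um=center[0], centroid_x_um=center[1],
                )
            )
        else:
            m = rasterize_surface_3d(nuc, geometry, center)
            vol, sa, sph = nuc.metrics()
            rows.append(
                dict(
                    channel=NUCLEUS, label=label, parent_channel="", parent_label=0,
                    volume_um3=vol, surface_um2=sa, sphericity=sph,
                    centroid_z_um=center[0], centroid_y_um=center[1],
                    centroid_x_um=center[2],
                )
            )
        masks[NUCLEUS][m] = label

    # --- compartments ------------------------------------------------------
    # top-level compartments (parent = nucleus) before nested ones
    ordered = [c for c in compartments if c.nesting is None] + [
        c for c in compartments if c.nesting is not None
    ]
    placed: dict[str, list[dict]] = {c.marker: [] for c in compartments}
    next_label = {c.marker: 1 for c in compartments}

    for comp in ordered:
        for nuc_label, (nuc, center) in enumerate(zip(nuclei, centers), start=1):
            count = int(rng_comp.poisson(comp.count_mean))
            if count == 0:
                continue
            obj_sizes = _lognormal_mean_sigma(rng_comp, count, comp.size_mean, comp.size_sigma)
            for size in obj_sizes:
                if ndim == 2:
                    radius = math.sqrt(size / math.pi)
                else:
                    radius = (3.0 * size / (4.0 * math.pi)) ** (1.0 / 3.0)
                item = _place_compartment(
                    rng_comp, comp, nuc, center, radius, placed, eps, ndim, nuc_label
                )
                if item is None:
                    continue  # could not fit; drop the object
                item["label"] = next_label[comp.marker]
                next_label[comp.marker] += 1
                placed[comp.marker].append(item)
                if ndim == 2:
                    a, p, c = shapes.circle_metrics(item["radius"])
                    rows.append(
                        dict(
                            channel=comp.marker, label=item["label"],
                            parent_channel=item["parent_channel"],
                            parent_label=item["parent_label"],
                            area_um2=a, perimeter_um=p, circularity=c,
                            centroid_y_um=item["center"][0],
                            centroid_x_um=item["center"][1],
                        )
                    )
                else:
                    v, sa, sp = shapes.sphere_metrics(item["radius"])
                    rows.append(
                        dict(
                            channel=comp.marker, label=item["label"],
                            parent_channel=item["parent_channel"],
                            parent_label=item["parent_label"],
                            volume_um3=v, surface_um2=sa, sphericity=sp,
                            centroid_z_um=item["center"][0],
                            centroid_y_um=item["center"][1],
                            centroid_x_um=item["center"][2],
                        )
                    )
                # rejection sampling keeps objects geometrically inside
                # their parent; intersecting with the parent raster makes
                # boundary voxels obey the same containment exactly
                slices, inside = _local_ball(geometry, item["center"], item["radius"])
                parent_sub = (
                    masks[item["parent_channel"]][slices] == item["parent_label"]
                )
                target = masks[comp.marker][slices]
                target[inside & parent_sub] = item["label"]

    truth = pd.DataFrame(rows)

    # --- render ------------------------------------------------------------
    channels = {}
    sigma_px = tuple(noise.psf_sigma / s for s in geometry.spacing)
    for name in CHANNEL_ORDER:
        img = (masks[name] > 0).astype(np.float64) * FOREGROUND
        if noise.psf_sigma > 0:
            img = gaussian_filter(img, sigma=sigma_px)
        img += noise.background
        if noise.photon_scale > 0:
            img = rng_noise.poisson(np.clip(img, 0, None) * noise.photon_scale) / noise.photon_scale
        if noise.gaussian_sigma > 0:
            img = img + rng_noise.normal(0.0, noise.gaussian_sigma, size=img.shape)
        channels[name] = np.clip(np.rint(img), 0, 65535).astype(np.uint16)

    return SyntheticImage(
        geometry=geometry,
        channels=channels,
        truth_masks=masks,
        truth_metrics=truth,
        seed=int(seed),
    )


def _place_compartment(rng, comp, nuc, nuc_center, radius, placed, eps, ndim, nuc_label):
    """Try to fit one compartment object; returns placement dict or None."""
    siblings = [
        p for p in placed[comp.marker] if p["nucleus_label"] == nuc_label
    ]
    if comp.nesting is None:
        parents = None
    else:
        parents = [p for p in placed[comp.nesting] if p["nucleus_label"] == nuc_label]
        if not parents:
            return None

    r = radius
    for _shrink in range(5):
        for _ in range(_COMPARTMENT_TRIES):
            if parents is None:
                # inside the (star-shaped) nucleus
                if ndim == 2:
                    rmax = nuc.max_radius - r - eps
                    if rmax <= 0:
                        break
                    ang = rng.uniform(0, 2 * math.pi)
                    rad = rmax * math.sqrt(rng.uniform())
                    offset = np.array([rad * math.sin(ang), rad * math.cos(ang)])
                    if not _contained_2d(nuc, offset, r, eps):
                        continue
                    center = (nuc_center[0] + offset[0], nuc_center[1] + offset[1])
                else:
                    rmax = nuc.max_radius_xy - r - eps
                    zmax = nuc.max_extent_z - r - eps
                    if rmax <= 0 or zmax <= 0:
                        break
                    offset = np.array(
                        [
                            rng.uniform(-zmax, zmax),
                            rng.uniform(-rmax, rmax),
                            rng.uniform(-rmax, rmax),
                        ]
                    )
                    if not _contained_3d(nuc, offset, r, eps):
                        continue
                    center = tuple(np.asarray(nuc_center) + offset)
                parent_channel, parent_label = NUCLEUS, nuc_label
            else:
                parent = parents[rng.integers(len(parents))]
                avail = parent["radius"] - r - eps
                if avail <= 0:
                    continue
                if ndim == 2:
                    ang = rng.uniform(0, 2 * math.pi)
                    rad = avail * math.sqrt(rng.uniform())
                    off = np.array([rad * math.sin(ang), rad * math.cos(ang)])
                else:
                    vec = rng.normal(size=3)
                    vec /= np.linalg.norm(vec)
                    off = vec * avail * rng.uniform() ** (1.0 / 3.0)
                center = tuple(np.asarray(parent["center"]) + off)
                parent_channel, parent_label = comp.nesting, parent["label"]
            # no overlap with already-placed siblings of the same marker
            clash = False
            for sib in siblings:
                d = np.linalg.norm(np.asarray(center) - np.asarray(sib["center"]))
                if d < r + sib["radius"] + _SIBLING_GAP:
                    clash = True
                    break
            if clash:
                continue
            return dict(
                center=center,
                radius=r,
                nucleus_label=nuc_label,
                parent_channel=parent_channel,
                parent_label=parent_label,
            )
        r *= 0.8
    return None


def generate_cohort(
    spec: NuclearPhenotypeSpec,
    compartments: list[CompartmentSpec],
    noise: NoiseSpec,
    geometry: ImageGeometry,
    seed: int,
    n_images: int,
) -> list[SyntheticImage]:
    """Render a cohort as independent replicate fields (one sub-seed each)."""
    child_seeds = np.random.SeedSequence(int(seed)).generate_state(n_images)
    return [
        generate_image(spec, compartments, noise, geometry, int(s))
        for s in child_seeds
    ]
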