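"""Analytic nucleus shapes with exact generator-side metrics.

Nuclei are modelled as circles (2D) or oblate spheroids (3D) whose
radius is modulated by a random truncated Fourier series (2D) or a
low-order real spherical-harmonic field (3D).  The perturbation
amplitude controls boundary irregularity; in 3D the flattening of the
spheroid additionally controls sphericity, which is the natural way an
adherent epithelial nucleus departs from a ball.

Ground-truth size and shape values are computed from the analytic
boundary itself — a dense polygon in 2D, a dense triangle mesh in 3D —
never from the raster, so they are independent of voxelization.
Unperturbed shapes short-circuit to closed forms (circle, sphere,
oblate spheroid) and are therefore exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import sph_harm_y

TWO_PI = 2.0 * math.pi

# Dense boundary discretizations used for truth metrics of perturbed
# shapes.  A regular 4096-gon measures a circle's circularity to ~2e-7,
# comfortably below the 1e-6 truth-consistency budget.
N_THETA_2D = 4096
MESH_THETA = 192
MESH_PHI = 384

MAX_AMPLITUDE = 0.45


# ---------------------------------------------------------------------------
# closed forms


def circle_metrics(radius: float) -> tuple[float, float, float]:
    """(area, perimeter, circularity) of a circle — exact."""
    return math.pi * radius**2, TWO_PI * radius, 1.0


def sphere_metrics(radius: float) -> tuple[float, float, float]:
    """(volume, surface area, sphericity) of a ball — exact."""
    return 4.0 / 3.0 * math.pi * radius**3, 4.0 * math.pi * radius**2, 1.0


def oblate_surface_area(a: float, q: float) -> float:
    """Surface area of an oblate spheroid with equatorial semi-axis ``a``
    and polar semi-axis ``q * a`` (0 < q <= 1)."""
    if q >= 1.0 - 1e-12:
        return 4.0 * math.pi * a**2
    e = math.sqrt(1.0 - q * q)
    return 2.0 * math.pi * a**2 * (1.0 + (q * q / e) * math.atanh(e))


def oblate_sphericity(q: float) -> float:
    """Sphericity of an oblate spheroid as a function of flattening q = c/a."""
    a = 1.0
    vol = 4.0 / 3.0 * math.pi * a**3 * q
    sa = oblate_surface_area(a, q)
    return math.pi ** (1.0 / 3.0) * (6.0 * vol) ** (2.0 / 3.0) / sa


def solve_oblate_flattening(target_sphericity: float) -> float:
    """Flattening q giving an unperturbed oblate spheroid the requested
    sphericity (closed-form bisection)."""
    if not 0.0 < target_sphericity <= 1.0:
        raise ValueError("target sphericity must lie in (0, 1]")
    if target_sphericity >= 1.0 - 1e-9:
        return 1.0
    lo = 1e-3
    if oblate_sphericity(lo) > target_sphericity:
        raise ValueError(f"target sphericity {target_sphericity} unreachable by flattening")
    return brentq(lambda q: oblate_sphericity(q) - target_sphericity, lo, 1.0, xtol=1e-12)


def prolate_sphericity(axis_ratio: float) -> float:
    """Sphericity of a prolate spheroid with polar/equatorial ratio > 1.

    Closed form used as an independent oracle for mesh-based surface
    measurements (e.g. a 2:1:1 ellipsoid).
    """
    c = axis_ratio
    a = 1.0
    e = math.sqrt(1.0 - (a / c) ** 2)
    sa = 2.0 * math.pi * a**2 * (1.0 + (c / (a * e)) * math.asin(e))
    vol = 4.0 / 3.0 * math.pi * a**2 * c
    return math.pi ** (1.0 / 3.0) * (6.0 * vol) ** (2.0 / 3.0) / sa


# ---------------------------------------------------------------------------
# 2D perturbed boundary


def polygon_area_perimeter(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Shoelace area and edge-sum perimeter of a closed polygon."""
    xs = np.roll(x, -1)
    ys = np.roll(y, -1)
    area = 0.5 * abs(np.sum(x * ys - xs * y))
    perim = float(np.sum(np.hypot(xs - x, ys - y)))
    return float(area), perim


@dataclass
class Boundary2D:
    """Star-shaped 2D boundary r(θ) = R (1 + a f(θ)).

    ``f`` is a random truncated Fourier series normalized to unit
    maximum absolute value, so ``amplitude`` is directly the maximum
    fractional radial excursion.
    """

    base_radius: float
    amplitude: float
    harmonics: np.ndarray  # integer orders, >= 2
    coefficients: np.ndarray  # relative weights, max|f| == 1
    phases: np.ndarray
    theta: np.ndarray = field(repr=False, default=None)
    radii: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if self.theta is None:
            self.theta = np.linspace(0.0, TWO_PI, N_THETA_2D, endpoint=False)
        if self.radii is None:
            self.radii = self.base_radius * (1.0 + self.amplitude * self._profile(self.theta))

    def _profile(self, theta: np.ndarray) -> np.ndarray:
        f = np.zeros_like(theta)
        for k, c, p in zip(self.harmonics, self.coefficients, self.phases):
            f += c * np.cos(k * theta + p)
        return f

    def radius_at(self, theta: np.ndarray) -> np.ndarray:
        return self.base_radius * (1.0 + self.amplitude * self._profile(np.asarray(theta)))

    def metrics(self) -> tuple[float, float, float]:
        """(area, perimeter, circularity) from analytic geometry."""
        if self.amplitude == 0.0:
            return circle_metrics(self.base_radius)
        x = self.radii * np.cos(self.theta)
        y = self.radii * np.sin(self.theta)
        area, perim = polygon_area_perimeter(x, y)
        circ = min(1.0, 4.0 * math.pi * area / perim**2)
        return area, perim, circ

    def scaled_to_area(self, target_area: float) -> "Boundary2D":
        area, _, _ = self.metrics()
        s = math.sqrt(target_area / area)
        return Boundary2D(
            base_radius=self.base_radius * s,
            amplitude=self.amplitude,
            harmonics=self.harmonics,
            coefficients=self.coefficients,
            phases=self.phases,
        )

    @property
    def max_radius(self) -> float:
        return float(self.radii.max())


def random_fourier_profile(rng: np.random.Generator, n_harmonics: int):
    """Random unit-normalized Fourier perturbation profile.

    Harmonic orders start at 2: order 0 is a size change and order 1 is
    (to first order) a translation, neither of which is irregularity.
    """
    n_harmonics = int(n_harmonics)
    if n_harmonics < 1:
        raise ValueError("need at least one harmonic")
    orders = np.arange(2, 2 + n_harmonics)
    coeffs = rng.normal(size=n_harmonics)
    phases = rng.uniform(0.0, TWO_PI, size=n_harmonics)
    theta = np.linspace(0.0, TWO_PI, N_THETA_2D, endpoint=False)
    f = np.zeros_like(theta)
    for k, c, p in zip(orders, coeffs, phases):
        f += c * np.cos(k * theta + p)
    peak = np.abs(f).max()
    if peak == 0.0:
        coeffs = np.ones(n_harmonics)
        return random_fourier_profile(rng, n_harmonics)
    return orders, coeffs / peak, phases


def build_boundary_2d(
    rng: np.random.Generator,
    area: float,
    n_harmonics: int,
    amplitude: float | None = None,
    target_circularity: float | None = None,
) -> Boundary2D:
    """Construct a nucleus boundary with the requested area.

    If ``target_circularity`` is given, the perturbation amplitude is
    solved per nucleus (monotone bisection on the polygon circularity)
    so that the analytic circularity equals the target; otherwise
    ``amplitude`` is used directly.
    """
    if target_circularity is not None and not 0.0 < target_circularity <= 1.0:
        raise ValueError("target circularity must lie in (0, 1]")

    # a peak-normalized profile dominated by one narrow bump may not
    # perturb the boundary enough to reach a low target; redraw a few
    # times before giving up
    for _attempt in range(10):
        orders, coeffs, phases = random_fourier_profile(rng, n_harmonics)

        def make(a: float) -> Boundary2D:
            return Boundary2D(1.0, a, orders, coeffs, phases)

        if target_circularity is None:
            amp = float(amplitude or 0.0)
            if not 0.0 <= amp <= 0.5:
                raise ValueError("irregularity amplitude must lie in [0, 0.5]")
            return make(amp).scaled_to_area(area)
        if target_circularity >= make(0.0).metrics()[2]:
            return make(0.0).scaled_to_area(area)
        if make(MAX_AMPLITUDE).metrics()[2] <= target_circularity:
            amp = brentq(
                lambda a: make(a).metrics()[2] - target_circularity,
                0.0, MAX_AMPLITUDE, xtol=1e-10,
            )
            return make(amp).scaled_to_area(area)
    raise ValueError(
        f"target circularity {target_circularity} unreachable with "
        f"{n_harmonics} harmonics at amplitude <= {MAX_AMPLITUDE}"
    )


# ---------------------------------------------------------------------------
# 3D perturbed spheroid


def _mesh_grid(n_theta: int, n_phi: int):
    theta = np.linspace(0.0, math.pi, n_theta)
    phi = np.linspace(0.0, TWO_PI, n_phi, endpoint=False)
    return np.meshgrid(theta, phi, indexing="ij")


def mesh_volume_area(radius_grid: np.ndarray, theta_g: np.ndarray, phi_g: np.ndarray):
    """Volume and surface area of a star-shaped surface sampled on a
    latitude/longitude grid, via a triangle fan closed over the seam."""
    x = radius_grid * np.sin(theta_g) * np.cos(phi_g)
    y = radius_grid * np.sin(theta_g) * np.sin(phi_g)
    z = radius_grid * np.cos(theta_g)
    verts = np.stack([x, y, z], axis=-1)  # (T, P, 3)
    a = verts[:-1, :, :]
    b = verts[1:, :, :]
    c = np.roll(verts[:-1, :, :], -1, axis=1)
    d = np.roll(verts[1:, :, :], -1, axis=1)

    def tri_quantities(p0, p1, p2):
        cross = np.cross(p1 - p0, p2 - p0)
        area = 0.5 * np.linalg.norm(cross, axis=-1)
        signed_vol = np.einsum("...i,...i->...", p0, np.cross(p1, p2)) / 6.0
        return area.sum(), signed_vol.sum()

    a1, v1 = tri_quantities(a, b, d)
    a2, v2 = tri_quantities(a, d, c)
    return abs(v1 + v2), a1 + a2


@dataclass
class Surface3D:
    """Star-shaped 3D surface r(θ, φ) = a s(θ; q) (1 + amp f(θ, φ)).

    ``s`` is the radial profile of an oblate spheroid flattened along z
    (q = polar/equatorial axis ratio) and ``f`` a random real
    spherical-harmonic field with unit maximum absolute value.
    """

    equatorial_radius: float
    flattening: float
    amplitude: float
    sh_orders: np.ndarray  # (n_modes, 2) integer (l, m)
    sh_coeffs: np.ndarray
    norm: float = 1.0

    def _profile(self, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
        if self.amplitude == 0.0 or len(self.sh_coeffs) == 0:
            return np.zeros_like(theta)
        f = np.zeros_like(theta, dtype=float)
        for (l, m), c in zip(self.sh_orders, self.sh_coeffs):
            y = sph_harm_y(int(l), int(abs(m)), theta, phi)
            if m > 0:
                f += c * math.sqrt(2.0) * y.real
            elif m < 0:
                f += c * math.sqrt(2.0) * y.imag
            else:
                f += c * y.real
        return f / self.norm

    def radius_at(self, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        phi = np.asarray(phi, dtype=float)
        q = self.flattening
        spheroid = q / np.sqrt((q * np.sin(theta)) ** 2 + np.cos(theta) ** 2)
        return self.equatorial_radius * spheroid * (1.0 + self.amplitude * self._profile(theta, phi))

    def metrics(self, n_theta: int = MESH_THETA, n_phi: int = MESH_PHI):
        """(volume, surface area, sphericity) from analytic geometry."""
        if self.amplitude == 0.0:
            a = self.equatorial_radius
            q = self.flattening
            if q >= 1.0 - 1e-12:
                return sphere_metrics(a)
            vol = 4.0 / 3.0 * math.pi * a**3 * q
            sa = oblate_surface_area(a, q)
            sph = min(1.0, math.pi ** (1.0 / 3.0) * (6.0 * vol) ** (2.0 / 3.0) / sa)
            return vol, sa, sph
        theta_g, phi_g = _mesh_grid(n_theta, n_phi)
        r = self.radius_at(theta_g, phi_g)
        vol, sa = mesh_volume_area(r, theta_g, phi_g)
        sph = min(1.0, math.pi ** (1.0 / 3.0) * (6.0 * vol) ** (2.0 / 3.0) / sa)
        return vol, sa, sph

    def scaled_to_volume(self, target_volume: float) -> "Surface3D":
        vol, _, _ = self.metrics()
        s = (target_volume / vol) ** (1.0 / 3.0)
        return Surface3D(
            equatorial_radius=self.equatorial_radius * s,
            flattening=self.flattening,
            amplitude=self.amplitude,
            sh_orders=self.sh_orders,
            sh_coeffs=self.sh_coeffs,
            norm=self.norm,
        )

    @property
    def max_radius_xy(self) -> float:
        return self.equatorial_radius * (1.0 + self.amplitude)

    @property
    def max_extent_z(self) -> float:
        return self.equatorial_radius * self.flattening * (1.0 + self.amplitude)


def random_sh_profile(rng: np.random.Generator, n_modes: int):
    """Random spherical-harmonic perturbation: degrees l = 2, 3, ... with
    all orders m per degree, Gaussian coefficients; normalized later."""
    n_modes = int(n_modes)
    orders = []
    l = 2
    while len(orders) < n_modes:
        for m in range(-l, l + 1):
            orders.append((l, m))
            if len(orders) >= n_modes:
                break
        l += 1
    orders = np.array(orders, dtype=int)
    coeffs = rng.normal(size=len(orders))
    return orders, coeffs


def build_surface_3d(
    rng: np.random.Generator,
    volume: float,
    n_modes: int,
    amplitude: float = 0.0,
    target_sphericity: float | None = None,
) -> Surface3D:
    """Construct a nucleus surface with the requested volume.

    Flattening is solved so the analytic sphericity hits
    ``target_sphericity`` (closed form when unperturbed, mesh-based
    bisection otherwise); the spherical-harmonic perturbation amplitude
    is applied as given.
    """
    amplitude = float(amplitude)
    if not 0.0 <= amplitude <= 0.5:
        raise ValueError("irregularity amplitude must lie in [0, 0.5]")
    if amplitude > 0.0 and n_modes >= 1:
        orders, coeffs = random_sh_profile(rng, n_modes)
    else:
        orders = np.empty((0, 2), dtype=int)
        coeffs = np.empty(0)
        amplitude = 0.0

    def make(q: float) -> Surface3D:
        surf = Surface3D(1.0, q, amplitude, orders, coeffs, norm=1.0)
        if amplitude > 0.0:
            theta_g, phi_g = _mesh_grid(96, 192)
            peak = float(np.abs(surf._profile(theta_g, phi_g)).max())
            surf.norm = peak if peak > 0 else 1.0
        return surf

    if target_sphericity is None:
        q = 1.0
    elif amplitude == 0.0:
        q = solve_oblate_flattening(target_sphericity)
    else:
        if not 0.0 < target_sphericity <= 1.0:
            raise ValueError("target sphericity must lie in (0, 1]")
        lo, hi = 2e-2, 1.0
        f_hi = make(hi).metrics(96, 192)[2] - target_sphericity
        if f_hi < 0.0:
            raise ValueError(
                f"target sphericity {target_sphericity} unreachable at amplitude {amplitude}"
            )
        f_lo = make(lo).metrics(96, 192)[2] - target_sphericity
        if f_lo > 0.0:
            raise ValueError(f"target sphericity {target_sphericity} unreachable by flattening")
        q = brentq(lambda qq: make(qq).metrics(96, 192)[2] - target_sphericity, lo, hi, xtol=1e-6)
    return make(q).scaled_to_volume(volume)
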