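"""Synthetic CT phantoms with known reference volumes.

Six test solids covering the topological variety of real hematomas — a smooth
ellipsoid, a biconvex lens (the classic epidural-hematoma profile), an
ellipsoid with low-frequency surface roughness, branched "pair of pants" and
"triple pants" solids (one trunk splitting into two or three legs), and a
knobby ellipsoid — plus seeded random hematoma-like shapes with tunable
surface roughness. Each phantom is voxelized at CT-like discretization by
center-point inclusion, and carries a reference volume obtained analytically,
by angular quadrature (star-convex solids), or by fine-grid evaluation with a
convergence check (branched solids).

Because every shape scales all of its length parameters uniformly, volume
scales exactly as the cube of the scale factor; :func:`calibrate_to_volume`
exploits this to hit any target volume in closed form.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .voxelgrid import HuVolume, VoxelGrid

__all__ = [
    "PhantomSpec",
    "ReferenceVolume",
    "generate_phantom",
    "reference_volume",
    "simulate_hu",
    "calibrate_to_volume",
    "default_suite",
    "SHAPES",
]

SHAPES = (
    "ellipsoid",
    "convex_lens",
    "rough_shape",
    "pair_of_pants",
    "triple_pants",
    "knobby_ellipsoid",
    "random_hematoma",
)

# Length-valued parameters (mm) scaled by calibrate_to_volume; everything
# else (amplitudes, counts, angular frequencies) is dimensionless.
_LENGTH_PARAMS = {
    "semi_axes",
    "ball_radius",
    "separation",
    "trunk_radius",
    "trunk_height",
    "leg_radius",
    "leg_height",
    "leg_offset",
    "mean_radius",
}

_DEFAULTS: dict[str, dict] = {
    "ellipsoid": {"semi_axes": (24.0, 19.0, 14.5)},
    "convex_lens": {"ball_radius": 25.0, "separation": 30.0},
    "rough_shape": {
        "semi_axes": (22.0, 18.0, 15.0),
        "roughness": 0.15,
        "n_waves": 5,
    },
    "pair_of_pants": {
        "trunk_radius": 16.0,
        "trunk_height": 24.0,
        "leg_radius": 10.0,
        "leg_height": 24.0,
        "leg_offset": 14.0,
    },
    "triple_pants": {
        "trunk_radius": 17.0,
        "trunk_height": 24.0,
        "leg_radius": 9.5,
        "leg_height": 24.0,
        "leg_offset": 16.0,
    },
    "knobby_ellipsoid": {
        "semi_axes": (22.0, 18.0, 15.0),
        "knob_amplitude": 0.8,
        "n_knobs": 24,
        "knob_width": 0.06,
    },
    "random_hematoma": {"mean_radius": 18.0, "roughness": 0.15, "n_waves": 10},
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of a synthetic shape.

    ``params`` defaults per shape; ``seed`` drives every random feature
    (roughness field, knob placement) deterministically.
    """

    shape: str
    params: dict = field(default_factory=dict)
    seed: int = 0
    target_volume_cm3: float | None = None

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; choose from {SHAPES}")
        merged = {**_DEFAULTS[self.shape], **self.params}
        for key, val in merged.items():
            if key in _LENGTH_PARAMS:
                arr = np.atleast_1d(np.asarray(val, dtype=float))
                if np.any(arr <= 0):
                    raise ValueError(f"{key} must be positive")
        object.__setattr__(self, "params", merged)

    def scaled(self, factor: float) -> "PhantomSpec":
        """Uniformly scale every length parameter by ``factor``."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        new = {}
        for key, val in self.params.items():
            if key in _LENGTH_PARAMS:
                if isinstance(val, (tuple, list, np.ndarray)):
                    new[key] = tuple(float(v) * factor for v in val)
                else:
                    new[key] = float(val) * factor
            else:
                new[key] = val
        return dataclasses.replace(self, params=new)

    def to_json(self) -> str:
        return json.dumps(
            {
                "shape": self.shape,
                "params": {
                    k: (list(v) if isinstance(v, (tuple, list)) else v)
                    for k, v in self.params.items()
                },
                "seed": self.seed,
                "target_volume_cm3": self.target_volume_cm3,
            },
            indent=2,
        )


@dataclass(frozen=True)
class ReferenceVolume:
    value_cm3: float
    method: str  # analytic | quadrature | fine_grid
    grid_refinement: int | None = None

    def __post_init__(self) -> None:
        if self.value_cm3 <= 0:
            raise ValueError("reference volume must be positive")


# ---------------------------------------------------------------------------
# Implicit solids


class _Solid:
    star_convex = False

    def inside(self, pts: np.ndarray) -> np.ndarray:  # (N,3) mm, shape-centered
        raise NotImplementedError

    def half_extent(self) -> np.ndarray:
        raise NotImplementedError

    def analytic_volume_mm3(self) -> float | None:
        return None

    def radial(self, u: np.ndarray) -> np.ndarray:  # star-convex only
        raise NotImplementedError


class _StarConvex(_Solid):
    """Solid defined by a radial function r(u) about the origin."""

    star_convex = True

    def inside(self, pts: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(pts, axis=-1)
        out = np.empty(d.shape, dtype=bool)
        zero = d == 0
        out[zero] = True
        nz = ~zero
        u = pts[nz] / d[nz, None]
        out[nz] = d[nz] <= self.radial(u)
        return out


class _Ellipsoid(_StarConvex):
    def __init__(self, semi_axes):
        self.abc = np.asarray(semi_axes, dtype=float)

    def radial(self, u):
        return 1.0 / np.sqrt(((u / self.abc) ** 2).sum(axis=-1))

    def inside(self, pts):  # quadric test is cheaper and exact
        return ((pts / self.abc) ** 2).sum(axis=-1) <= 1.0

    def half_extent(self):
        return self.abc.copy()

    def analytic_volume_mm3(self):
        return 4.0 / 3.0 * np.pi * float(np.prod(self.abc))


class _ConvexLens(_Solid):
    """Intersection of two balls of radius R with centers 'separation' apart along z."""

    def __init__(self, ball_radius, separation):
        if separation >= 2 * ball_radius:
            raise ValueError("separation must be < 2*ball_radius for a nonempty lens")
        self.R = float(ball_radius)
        self.d = float(separation)

    def inside(self, pts):
        up = pts + np.array([0.0, 0.0, self.d / 2.0])
        dn = pts - np.array([0.0, 0.0, self.d / 2.0])
        rr = self.R**2
        return ((up**2).sum(axis=-1) <= rr) & ((dn**2).sum(axis=-1) <= rr)

    def half_extent(self):
        rho = np.sqrt(self.R**2 - (self.d / 2.0) ** 2)  # equatorial radius
        return np.array([rho, rho, self.R - self.d / 2.0])

    def analytic_volume_mm3(self):
        # lens = intersection of two equal spheres, centers d apart
        return np.pi * (4.0 * self.R + self.d) * (2.0 * self.R - self.d) ** 2 / 12.0


def _wave_field(rng: np.random.Generator, n_waves: int):
    """Seeded band-limited scalar field on the unit sphere, max |f| ~ 1."""
    freqs = rng.uniform(2.0, 6.0, size=(n_waves, 3)) * rng.choice([-1, 1], size=(n_waves, 3))
    phases = rng.uniform(0, 2 * np.pi, size=n_waves)
    coefs = rng.normal(size=n_waves)
    coefs /= np.abs(coefs).sum()

    def f(u):
        acc = np.zeros(u.shape[:-1])
        for k in range(n_waves):
            acc += coefs[k] * np.cos(u @ freqs[k] + phases[k])
        return acc

    return f


class _PerturbedEllipsoid(_StarConvex):
    """Ellipsoid radial function modulated by a seeded perturbation field."""

    def __init__(self, semi_axes, perturb):
        self.base = _Ellipsoid(semi_axes)
        self.perturb = perturb  # callable u -> multiplicative factor >= some bound
        self._max_factor = None

    def radial(self, u):
        return self.base.radial(u) * self.perturb(u)

    def half_extent(self):
        if self._max_factor is None:
            u = _fibonacci_sphere(20000)
            self._max_factor = float(self.perturb(u).max())
        return self.base.abc * self._max_factor * 1.02


class _Capsule:
    def __init__(self, p0, p1, radius):
        self.p0 = np.asarray(p0, dtype=float)
        self.p1 = np.asarray(p1, dtype=float)
        self.r = float(radius)
        self.axis = self.p1 - self.p0
        self.len2 = float(self.axis @ self.axis)

    def inside(self, pts):
        rel = pts - self.p0
        t = np.clip((rel @ self.axis) / self.len2, 0.0, 1.0)
        closest = self.p0 + t[..., None] * self.axis
        return ((pts - closest) ** 2).sum(axis=-1) <= self.r**2


class _Pants(_Solid):
    """Trunk capsule splitting into 2 or 3 leg capsules (branched solid).

    The trunk rises along +z; the legs descend below z = 0, so the lower
    slices show 2 (or 3) separate 2D components while the upper slices
    show one.
    """

    def __init__(self, n_legs, trunk_radius, trunk_height, leg_radius, leg_height, leg_offset):
        angles = np.linspace(0, 2 * np.pi, n_legs, endpoint=False)
        self.capsules = [_Capsule((0, 0, 0), (0, 0, trunk_height), trunk_radius)]
        for ang in angles:
            foot = (leg_offset * np.cos(ang), leg_offset * np.sin(ang), -leg_height)
            hip = (
                0.2 * leg_offset * np.cos(ang),
                0.2 * leg_offset * np.sin(ang),
                0.3 * trunk_height,
            )
            self.capsules.append(_Capsule(foot, hip, leg_radius))
        self._ext = self._compute_extent()

    def _compute_extent(self):
        lo = np.full(3, np.inf)
        hi = np.full(3, -np.inf)
        for cap in self.capsules:
            lo = np.minimum(lo, np.minimum(cap.p0, cap.p1) - cap.r)
            hi = np.maximum(hi, np.maximum(cap.p0, cap.p1) + cap.r)
        return lo, hi

    def inside(self, pts):
        out = np.zeros(pts.shape[:-1], dtype=bool)
        for cap in self.capsules:
            out |= cap.inside(pts)
        return out

    def half_extent(self):
        lo, hi = self._ext
        return np.maximum(np.abs(lo), np.abs(hi))


def _build_solid(spec: PhantomSpec) -> _Solid:
    p = spec.params
    rng = np.random.default_rng(spec.seed)
    if spec.shape == "ellipsoid":
        return _Ellipsoid(p["semi_axes"])
    if spec.shape == "convex_lens":
        return _ConvexLens(p["ball_radius"], p["separation"])
    if spec.shape == "rough_shape":
        f = _wave_field(rng, int(p["n_waves"]))
        amp = float(p["roughness"])
        return _PerturbedEllipsoid(p["semi_axes"], lambda u: 1.0 + amp * f(u))
    if spec.shape == "knobby_ellipsoid":
        n_knobs = int(p["n_knobs"])
        dirs = rng.normal(size=(n_knobs, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        amp = float(p["knob_amplitude"])
        width = float(p["knob_width"])

        def knobs(u):
            acc = np.zeros(u.shape[:-1])
            for d in dirs:
                acc += np.exp(-(1.0 - u @ d) / width)
            return 1.0 + amp * acc

        return _PerturbedEllipsoid(p["semi_axes"], knobs)
    if spec.shape in ("pair_of_pants", "triple_pants"):
        n_legs = 2 if spec.shape == "pair_of_pants" else 3
        return _Pants(
            n_legs,
            p["trunk_radius"],
            p["trunk_height"],
            p["leg_radius"],
            p["leg_height"],
            p["leg_offset"],
        )
    if spec.shape == "random_hematoma":
        f = _wave_field(rng, int(p["n_waves"]))
        amp = float(p["roughness"])
        r0 = float(p["mean_radius"])
        return _PerturbedEllipsoid((r0, r0, r0), lambda u: 1.0 + amp * f(u))
    raise ValueError(spec.shape)


# ---------------------------------------------------------------------------
# Voxelization and reference volumes


def generate_phantom(spec: PhantomSpec, s: float, dx: float) -> VoxelGrid:
    """Voxelize a phantom at pixel size ``s`` and slice thickness ``dx`` (mm).

    A voxel is set iff its center lies inside the implicit solid; this is the
    same convention a binary radiologist mask follows, and makes planimetry
    exact with respect to the discrete shape. Deterministic given the spec.
    """
    if s <= 0 or dx <= 0:
        raise ValueError("spacing must be positive")
    solid = _build_solid(spec)
    ext = solid.half_extent()
    # even dimensions: voxel centers straddle the shape center symmetrically
    cols = int(np.ceil(2 * ext[0] / s)) + 4
    cols += cols % 2
    rows = int(np.ceil(2 * ext[1] / s)) + 4
    rows += rows % 2
    n = int(np.ceil(2 * ext[2] / dx)) + 4
    n += n % 2
    cx, cy, cz = cols * s / 2.0, rows * s / 2.0, n * dx / 2.0
    x = (np.arange(cols) + 0.5) * s - cx
    y = (np.arange(rows) + 0.5) * s - cy
    occ = np.zeros((n, rows, cols), dtype=bool)
    X, Y = np.meshgrid(x, y)  # (rows, cols)
    pts2 = np.stack([X, Y], axis=-1)
    for i in range(n):
        z = (i + 0.5) * dx - cz
        pts = np.concatenate([pts2, np.full((rows, cols, 1), z)], axis=-1)
        occ[i] = solid.inside(pts)
    if not occ.any():
        raise ValueError("shape too small for the grid: no interior voxel")
    return VoxelGrid(occ, s, dx)


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + np.sqrt(5)) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _quadrature_volume_mm3(solid: _StarConvex, n_dirs: int) -> float:
    u = _fibonacci_sphere(n_dirs)
    r = solid.radial(u)
    return float((r**3).mean() * 4.0 * np.pi / 3.0)


def _grid_volume_mm3(solid: _Solid, h: float) -> float:
    ext = solid.half_extent()
    count = 0
    nz = int(np.ceil(2 * ext[2] / h)) + 4
    nx = int(np.ceil(2 * ext[0] / h)) + 4
    ny = int(np.ceil(2 * ext[1] / h)) + 4
    x = (np.arange(nx) + 0.5) * h - nx * h / 2.0
    y = (np.arange(ny) + 0.5) * h - ny * h / 2.0
    X, Y = np.meshgrid(x, y)
    pts2 = np.stack([X, Y], axis=-1)
    for i in range(nz):
        z = (i + 0.5) * h - nz * h / 2.0
        pts = np.concatenate([pts2, np.full((ny, nx, 1), z)], axis=-1)
        count += int(solid.inside(pts).sum())
    return count * h**3


BASE_SPACING_MM = 1.5  # benchmark slice thickness; fine grids refine from here


def reference_volume(spec: PhantomSpec, refinement: int = 8) -> ReferenceVolume:
    """Ground-truth volume of a phantom, in cm^3.

    Closed form where one exists (ellipsoid, lens); exact angular quadrature
    for star-convex solids; otherwise fine-grid counting at isotropic spacing
    ``1.5 mm / refinement`` with a convergence check against a 1.5x finer
    grid (the two must agree within 0.2%).
    """
    solid = _build_solid(spec)
    v = solid.analytic_volume_mm3()
    if v is not None:
        return ReferenceVolume(v / 1000.0, "analytic")
    if solid.star_convex:
        v1 = _quadrature_volume_mm3(solid, 100_000)
        v2 = _quadrature_volume_mm3(solid, 400_000)
        if abs(v2 - v1) / v2 > 0.002:
            raise RuntimeError("angular quadrature failed to converge")
        return ReferenceVolume(v2 / 1000.0, "quadrature")
    if refinement < 8:
        raise ValueError("fine-grid refinement must be at least 8")
    h1 = BASE_SPACING_MM / refinement
    h2 = BASE_SPACING_MM / int(np.ceil(1.5 * refinement))
    v1 = _grid_volume_mm3(solid, h1)
    v2 = _grid_volume_mm3(solid, h2)
    if abs(v2 - v1) / v2 > 0.002:
        raise RuntimeError(
            f"fine-grid reference did not converge: {v1 / 1000:.4f} vs {v2 / 1000:.4f} cm^3"
        )
    return ReferenceVolume(v2 / 1000.0, "fine_grid", grid_refinement=refinement)


def calibrate_to_volume(spec: PhantomSpec, target_cm3: float) -> PhantomSpec:
    """Scale a spec's length parameters so its reference volume hits a target.

    Uniform scaling by ``lambda`` scales any solid's volume by exactly
    ``lambda^3``, so the factor is ``(target / V0)^(1/3)`` in closed form.
    """
    if target_cm3 <= 0:
        raise ValueError("target volume must be positive")
    v0 = reference_volume(spec).value_cm3
    factor = (target_cm3 / v0) ** (1.0 / 3.0)
    out = spec.scaled(factor)
    return dataclasses.replace(out, target_volume_cm3=target_cm3)


def simulate_hu(
    grid: VoxelGrid,
    water_range: tuple[float, float] = (5.0, 8.0),
    background: float = 0.0,
    seed: int = 0,
) -> HuVolume:
    """Fill a mask with water-like HU values on a uniform background.

    Interior voxels draw uniformly from ``water_range`` (the CT water window,
    HU 5-8 by default); thresholding the result back at the same window
    recovers the mask exactly.
    """
    low, high = water_range
    if low > high:
        raise ValueError("water_range must be ordered")
    if low <= background <= high:
        raise ValueError("background HU must lie outside the water range")
    rng = np.random.default_rng(seed)
    values = np.full(grid.occupancy.shape, float(background))
    n = grid.voxel_count
    values[grid.occupancy] = rng.uniform(low, high, size=n)
    return HuVolume(values, grid.pixel_size, grid.slice_thickness)


def default_suite() -> list[tuple[PhantomSpec, float]]:
    """The six-shape benchmark suite with its calibration targets (cm^3)."""
    targets = {
        "ellipsoid": 58.0,
        "convex_lens": 27.0,
        "rough_shape": 28.0,
        "triple_pants": 68.0,
        "pair_of_pants": 59.0,
        "knobby_ellipsoid": 36.0,
    }
    return [(PhantomSpec(shape, seed=0), vol) for shape, vol in targets.items()]
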