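"""The four hematoma volume estimators.

Given one annotated hemorrhage region as a :class:`~hemovol.voxelgrid.VoxelGrid`:

* **planimetry** — voxel counting: ``V = sum_i N_i * s^2 * dX``. Exact with
  respect to the discrete mask; the clinical reference standard when a full
  segmentation is available.
* **truncated pyramid** — frusta between footprint-overlapping regions on
  adjacent slices, ``V_k = (1/3)(A + B + sqrt(A*B)) * dX``, with zero-area
  virtual slices capping the first and last appearance of a region.
* **ABC/2 via PCA** — the bedside ellipsoid shortcut ``V = A*B*C/2`` (the
  pi ~ 3 simplification is deliberate and kept literal), with the three
  perpendicular diameters extracted automatically by principal component
  analysis either slice-wise (2D) or on the full voxel cloud (3D).

All volumes are reported in cm^3; axes in mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .voxelgrid import VoxelGrid, connected_components_2d

__all__ = [
    "VolumeEstimate",
    "PrincipalAxes",
    "planimetry_volume",
    "truncated_pyramid_volume",
    "pca_axes_2d",
    "pca_axes_3d",
    "abc_over_2",
    "METHODS",
]

METHODS = ("planimetry", "truncated_pyramid", "abc2_pca2d", "abc2_pca3d")


@dataclass(frozen=True)
class VolumeEstimate:
    method: str
    volume_cm3: float

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.volume_cm3 < 0:
            raise ValueError("volume must be non-negative")


@dataclass(frozen=True)
class PrincipalAxes:
    """Lesion diameters A >= B (>= C for the 3D variant) with orientation.

    ``basis`` columns are the principal directions (orthonormal); for the
    slice-wise variant the first two columns span the selected slice plane
    and the third is the scan axis. ``centroid_mm`` is in physical (x, y, z).
    """

    A: float
    B: float
    C: float
    basis: np.ndarray
    centroid_mm: np.ndarray
    slice_index: int | None = None  # slice carrying A (2D variant only)

    def __post_init__(self) -> None:
        if not (self.A > 0 and self.B > 0 and self.C > 0):
            raise ValueError("axis lengths must be positive")
        if self.A < self.B - 1e-12:
            raise ValueError("axes must satisfy A >= B")
        gram = self.basis.T @ self.basis
        if not np.allclose(gram, np.eye(3), atol=1e-9):
            raise ValueError("basis must be orthonormal")


def planimetry_volume(grid: VoxelGrid) -> VolumeEstimate:
    """Voxel-counting volume: set-voxel count times single-voxel volume, in cm^3."""
    if not grid.occupancy.any():
        raise ValueError("empty grid")
    v_mm3 = grid.voxel_count * grid.voxel_volume_mm3
    return VolumeEstimate("planimetry", v_mm3 / 1000.0)


def _frustum_mm3(a: float, b: float, dx: float) -> float:
    return (a + b + np.sqrt(a * b)) * dx / 3.0


def truncated_pyramid_volume(grid: VoxelGrid) -> VolumeEstimate:
    """Sum of frusta between paired regions on adjacent slices.

    Regions on slice i and i+1 are paired when their (row, col) footprints
    overlap. Overlap groups are merged (a region facing k counterparts meets
    their summed area once, not k frusta). Any region face without a
    counterpart — including the slice before the first appearance and after
    the last — meets a zero-area virtual slice and contributes (1/3)*A*dX.
    """
    occ = grid.occupancy
    if not occ.any():
        raise ValueError("empty grid")
    dx = grid.slice_thickness
    n = grid.n_slices
    slice_regions = [connected_components_2d(grid, i) for i in range(n)]
    areas = [[r.area_mm2 for r in regs] for regs in slice_regions]

    total = 0.0
    # caps below the first slice and above the last
    total += sum(a / 3.0 * dx for a in areas[0])
    total += sum(a / 3.0 * dx for a in areas[-1])

    for i in range(n - 1):
        lower, upper = slice_regions[i], slice_regions[i + 1]
        if not lower and not upper:
            continue
        # label maps for footprint overlap
        shape = occ.shape[1:]
        lo_lbl = np.zeros(shape, dtype=np.int32)
        for k, r in enumerate(lower, start=1):
            lo_lbl[r.pixels[:, 0], r.pixels[:, 1]] = k
        up_lbl = np.zeros(shape, dtype=np.int32)
        for k, r in enumerate(upper, start=1):
            up_lbl[r.pixels[:, 0], r.pixels[:, 1]] = k
        both = (lo_lbl > 0) & (up_lbl > 0)
        pairs = set(zip(lo_lbl[both].tolist(), up_lbl[both].tolist()))

        # union-find over (side, index) nodes to merge many-to-one overlaps
        parent: dict[tuple[int, int], tuple[int, int]] = {}

        def find(x):
            while parent.setdefault(x, x) != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for lo, up in pairs:
            ra, rb = find((0, lo)), find((1, up))
            if ra != rb:
                parent[ra] = rb

        groups: dict[tuple[int, int], list[tuple[int, int]]] = {}
        for lo, up in pairs:
            for node in ((0, lo), (1, up)):
                groups.setdefault(find(node), [])
        for node in {n_ for p in pairs for n_ in ((0, p[0]), (1, p[1]))}:
            groups[find(node)].append(node)

        matched_lo: set[int] = set()
        matched_up: set[int] = set()
        for members in groups.values():
            a_sum = sum(areas[i][k - 1] for side, k in members if side == 0)
            b_sum = sum(areas[i + 1][k - 1] for side, k in members if side == 1)
            matched_lo.update(k for side, k in members if side == 0)
            matched_up.update(k for side, k in members if side == 1)
            total += _frustum_mm3(a_sum, b_sum, dx)
        # unmatched faces meet a zero-area virtual slice
        for k, a in enumerate(areas[i], start=1):
            if k not in matched_lo:
                total += a / 3.0 * dx
        for k, b in enumerate(areas[i + 1], start=1):
            if k not in matched_up:
                total += b / 3.0 * dx

    return VolumeEstimate("truncated_pyramid", total / 1000.0)


def _principal_frame(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centered covariance eigendecomposition, eigenvalues descending.

    Eigenvector sign is fixed by making the largest-magnitude component
    positive, so results are deterministic across BLAS implementations.
    """
    centroid = points.mean(axis=0)
    centered = points - centroid
    cov = centered.T @ centered / len(points)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvecs = eigvecs[:, order]
    for j in range(eigvecs.shape[1]):
        k = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    return centroid, eigvecs


def pca_axes_2d(grid: VoxelGrid) -> PrincipalAxes:
    """Slice-wise ABC axis extraction.

    For every nonempty slice the set-pixel coordinates are centered and the
    2x2 covariance eigendecomposed; A and B are the extents along the first
    and second principal directions (plus one pixel, so a single-pixel slice
    measures s rather than 0). The slice maximizing A is returned; C is the
    number of nonempty slices times the slice thickness — the scan axis is
    treated as the third, imaginary diameter.
    """
    occ = grid.occupancy
    if not occ.any():
        raise ValueError("empty grid")
    s, dx = grid.pixel_size, grid.slice_thickness
    nonempty = np.flatnonzero(occ.reshape(grid.n_slices, -1).any(axis=1))
    best = None
    for i in nonempty:
        pix = np.argwhere(occ[i]).astype(float)  # (row, col)
        xy = pix[:, ::-1]  # (col, row) -> in-plane (x, y) pixel units
        centroid, vecs = _principal_frame(xy)
        proj = (xy - centroid) @ vecs
        a_len = (proj[:, 0].max() - proj[:, 0].min() + 1.0) * s
        b_len = (proj[:, 1].max() - proj[:, 1].min() + 1.0) * s
        if best is None or a_len > best[0]:
            best = (a_len, b_len, int(i), centroid, vecs)
    a_len, b_len, idx, centroid, vecs = best
    c_len = len(nonempty) * dx
    basis = np.eye(3)
    basis[:2, 0] = vecs[:, 0]
    basis[:2, 1] = vecs[:, 1]
    centroid_mm = np.array([(centroid[0] + 0.5) * s, (centroid[1] + 0.5) * s, (idx + 0.5) * dx])
    return PrincipalAxes(a_len, b_len, c_len, basis, centroid_mm, slice_index=idx)


def pca_axes_3d(grid: VoxelGrid) -> PrincipalAxes:
    """Principal axes of the full voxel cloud in physical mm.

    Axis length along each principal direction u is the extent of the voxel
    centers' projections plus the extent of one voxel along u (the support
    ``s|u_x| + s|u_y| + dX|u_z|``), so flat or thin regions still measure at
    least one voxel. Lengths are returned sorted A >= B >= C with the basis
    permuted accordingly.
    """
    if not grid.occupancy.any():
        raise ValueError("empty grid")
    pts = grid.voxel_centers_mm()
    centroid, vecs = _principal_frame(pts)
    proj = (pts - centroid) @ vecs
    spans = proj.max(axis=0) - proj.min(axis=0)
    voxel_half = np.array([grid.pixel_size, grid.pixel_size, grid.slice_thickness])
    support = np.abs(vecs.T) @ voxel_half  # one-voxel extent along each PC
    lengths = spans + support
    order = np.argsort(lengths)[::-1]
    lengths = lengths[order]
    vecs = vecs[:, order]
    return PrincipalAxes(lengths[0], lengths[1], lengths[2], vecs, centroid)


def abc_over_2(axes: PrincipalAxes) -> VolumeEstimate:
    """The ABC/2 ellipsoid shortcut, in cm^3 (axes in mm).

    Implements the clinical simplification literally: (4/3) pi (A/2)(B/2)(C/2)
    with pi approximated as 3 collapses to A*B*C/2.
    """
    method = "abc2_pca2d" if axes.slice_index is not None else "abc2_pca3d"
    return VolumeEstimate(method, axes.A * axes.B * axes.C / 2.0 / 1000.0)
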