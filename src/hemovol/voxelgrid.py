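"""Stacked-slice binary masks and HU volumes.

A segmentation exported from a CT annotation tool is a stack of 2D binary
images: slice ``i`` lives at axial position ``(i + 0.5) * slice_thickness``
and each in-plane pixel is a square of side ``pixel_size``. Every volume
estimator in :mod:`hemovol.volumetry` consumes this one container, so the
physical interpretation (voxel centers, spacing) is fixed here once.

Conventions
-----------
* Arrays are indexed ``(slice, row, col)``; indices are 0-based internally.
* Voxel centers sit at ``((col + 0.5) s, (row + 0.5) s, (i + 0.5) dX)`` mm.
* In-plane pixels must be square: a single side length ``s`` enters every
  formula downstream, so anisotropic in-plane spacing is rejected rather
  than silently averaged.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label as _sk_label

__all__ = [
    "VoxelGrid",
    "HuVolume",
    "SliceRegion",
    "read_mask",
    "write_mask",
    "threshold_hu",
    "connected_components_2d",
    "border_voxels",
]


@dataclass(frozen=True)
class VoxelGrid:
    """Binary occupancy over a slice stack with physical spacing.

    Parameters
    ----------
    occupancy:
        Boolean array of shape ``(n_slices, rows, cols)``.
    pixel_size:
        In-plane pixel side length ``s`` in mm.
    slice_thickness:
        Inter-slice distance ``dX`` in mm.
    """

    occupancy: np.ndarray
    pixel_size: float
    slice_thickness: float

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if occ.ndim != 3:
            raise ValueError(f"occupancy must be 3D (slice,row,col), got {occ.ndim}D")
        if occ.dtype != bool:
            vals = np.unique(occ)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("occupancy values must be exactly 0 or 1")
            occ = occ.astype(bool)
        if self.pixel_size <= 0 or self.slice_thickness <= 0:
            raise ValueError("pixel_size and slice_thickness must be positive")
        object.__setattr__(self, "occupancy", occ)

    @property
    def n_slices(self) -> int:
        return self.occupancy.shape[0]

    @property
    def voxel_count(self) -> int:
        return int(self.occupancy.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return self.pixel_size**2 * self.slice_thickness

    def voxel_centers_mm(self) -> np.ndarray:
        """(N, 3) physical centers ``(x, y, z)`` of the set voxels in mm."""
        idx = np.argwhere(self.occupancy)  # (i, row, col)
        s, dx = self.pixel_size, self.slice_thickness
        centers = np.empty((len(idx), 3))
        centers[:, 0] = (idx[:, 2] + 0.5) * s
        centers[:, 1] = (idx[:, 1] + 0.5) * s
        centers[:, 2] = (idx[:, 0] + 0.5) * dx
        return centers


@dataclass(frozen=True)
class HuVolume:
    """A Hounsfield-unit valued volume with the same spacing fields."""

    values: np.ndarray
    pixel_size: float
    slice_thickness: float

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 3:
            raise ValueError("values must be 3D (slice,row,col)")
        if not np.all(np.isfinite(vals)):
            raise ValueError("HU values must be finite")
        if self.pixel_size <= 0 or self.slice_thickness <= 0:
            raise ValueError("pixel_size and slice_thickness must be positive")
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class SliceRegion:
    """One 8-connected component of set pixels on a single slice."""

    slice_index: int
    pixels: np.ndarray  # (N, 2) array of (row, col)
    pixel_size: float = field(repr=False, default=1.0)

    @property
    def pixel_count(self) -> int:
        return len(self.pixels)

    @property
    def area_mm2(self) -> float:
        return self.pixel_count * self.pixel_size**2


# ---------------------------------------------------------------------------
# I/O


def _read_csv_mask(path: str) -> VoxelGrid:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing '# s=... dX=... dims=...' metadata line")
        meta = dict(tok.split("=", 1) for tok in header.lstrip("#").split())
        s = float(meta["s"])
        dx = float(meta["dX"])
        dims = tuple(int(v) for v in meta["dims"].split(","))
        body = np.loadtxt(fh, delimiter=",", dtype=int, ndmin=2)
    occ = np.zeros(dims, dtype=bool)
    if body.size:
        occ[body[:, 0], body[:, 1], body[:, 2]] = True
    return VoxelGrid(occ, s, dx)


def _write_csv_mask(grid: VoxelGrid, path: str) -> None:
    n, r, c = grid.occupancy.shape
    with open(path, "w") as fh:
        fh.write(f"# s={grid.pixel_size:g} dX={grid.slice_thickness:g} dims={n},{r},{c}\n")
        for i, row, col in np.argwhere(grid.occupancy):
            fh.write(f"{i},{row},{col}\n")


def _nifti_to_grid(img) -> VoxelGrid:
    sx, sy, sz = (float(z) for z in img.header.get_zooms()[:3])
    if not np.isclose(sx, sy, rtol=1e-6):
        raise ValueError(f"anisotropic in-plane spacing {sx} x {sy}: square pixels required")
    data = np.asanyarray(img.dataobj)  # (x, y, z) in nibabel's layout
    occ = (data > 0.5).transpose(2, 1, 0)  # -> (slice, row, col)
    return VoxelGrid(occ, sx, sz)


def read_mask(path: str, format_name: str | None = None) -> VoxelGrid:
    """Read a binary mask from NIfTI, NRRD or voxel-list CSV.

    Spacing is always taken from the file's metadata, never guessed. Values
    are binarized at 0.5. ``format_name`` (``"nifti"``, ``"nrrd"``, ``"csv"``)
    overrides extension sniffing.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = (format_name or _sniff_format(path)).lower()
    if fmt == "csv":
        return _read_csv_mask(path)
    if fmt == "nifti":
        import nibabel as nib

        return _nifti_to_grid(nib.load(path))
    if fmt == "nrrd":
        import SimpleITK as sitk

        img = sitk.ReadImage(path)
        sx, sy, sz = img.GetSpacing()
        if not np.isclose(sx, sy, rtol=1e-6):
            raise ValueError(f"anisotropic in-plane spacing {sx} x {sy}: square pixels required")
        data = sitk.GetArrayFromImage(img)  # already (z, y, x)
        return VoxelGrid(data > 0.5, float(sx), float(sz))
    raise ValueError(f"unknown mask format {fmt!r}")


def write_mask(grid: VoxelGrid, path: str, format_name: str | None = None) -> None:
    """Write a mask so that :func:`read_mask` round-trips occupancy and spacing."""
    fmt = (format_name or _sniff_format(path)).lower()
    if fmt == "csv":
        _write_csv_mask(grid, path)
    elif fmt == "nifti":
        import nibabel as nib

        s, dx = grid.pixel_size, grid.slice_thickness
        data = grid.occupancy.transpose(2, 1, 0).astype(np.uint8)
        affine = np.diag([s, s, dx, 1.0])
        nib.save(nib.Nifti1Image(data, affine), path)
    elif fmt == "nrrd":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(grid.occupancy.astype(np.uint8))
        img.SetSpacing((grid.pixel_size, grid.pixel_size, grid.slice_thickness))
        sitk.WriteImage(img, path)
    else:
        raise ValueError(f"unknown mask format {fmt!r}")


def _sniff_format(path: str) -> str:
    lower = path.lower()
    if lower.endswith((".nii", ".nii.gz")):
        return "nifti"
    if lower.endswith((".nrrd", ".nhdr")):
        return "nrrd"
    if lower.endswith(".csv"):
        return "csv"
    raise ValueError(f"cannot infer mask format from {path!r}")


# ---------------------------------------------------------------------------
# Derived structures


def threshold_hu(vol: HuVolume, low: float, high: float) -> VoxelGrid:
    """Binarize an HU volume: voxel set iff ``low <= HU <= high`` (inclusive).

    The CT phantom convention sets water at HU 5-8; thresholding in that
    window recovers the water-filled interior.
    """
    if low > high:
        raise ValueError(f"low ({low}) must not exceed high ({high})")
    occ = (vol.values >= low) & (vol.values <= high)
    return VoxelGrid(occ, vol.pixel_size, vol.slice_thickness)


# 8-connectivity: diagonal pixels belong to the same bleed region.
def connected_components_2d(grid: VoxelGrid, slice_index: int) -> list[SliceRegion]:
    """Partition a slice's set pixels into 8-connected components.

    Components are ordered deterministically by (min row, min col). An empty
    slice yields an empty list.
    """
    if not 0 <= slice_index < grid.n_slices:
        raise IndexError(f"slice_index {slice_index} out of range 0..{grid.n_slices - 1}")
    sl = grid.occupancy[slice_index]
    labels = _sk_label(sl, connectivity=2)
    regions = []
    for lbl in range(1, labels.max() + 1):
        pix = np.argwhere(labels == lbl)
        regions.append(SliceRegion(slice_index, pix, grid.pixel_size))
    regions.sort(key=lambda r: (int(r.pixels[:, 0].min()), int(r.pixels[:, 1].min())))
    return regions


def border_voxels(grid: VoxelGrid) -> np.ndarray:
    """Indices (i, row, col) of set voxels on the 6-connected surface shell.

    A voxel is border when at least one face-adjacent neighbor is unset or
    lies outside the lattice.
    """
    occ = grid.occupancy
    if not occ.any():
        raise ValueError("empty grid has no border voxels")
    # border_value=0 treats outside-the-lattice as unset
    interior = ndimage.binary_erosion(occ, structure=ndimage.generate_binary_structure(3, 1))
    return np.argwhere(occ & ~interior)
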