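import numpy as np
import pytest

from hemovol.voxelgrid import VoxelGrid


@pytest.fixture
def single_voxel_grid():
    occ = np.zeros((1, 11, 11), dtype=bool)
    occ[0, 5, 5] = True
    return VoxelGrid(occ, 10.0, 10.0)


@pytest.fixture
def cube_grid():
    """5x5x5 solid cube inside a 7x7x7 lattice, s = dX = 1 mm."""
    occ = np.zeros((7, 7, 7), dtype=bool)
    occ[1:6, 1:6, 1:6] = True
    return VoxelGrid(occ, 1.0, 1.0)


def digital_ball(radius_vox: int, s: float = 1.0, dx: float = 1.0) -> VoxelGrid:
    """Ball of given radius in voxel units on an isotropic-index lattice."""
    n = radius_vox + 2
    ax = np.arange(-n, n + 1)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    occ = X * X + Y * Y + Z * Z <= radius_vox * radius_vox
    return VoxelGrid(occ, s, dx)


def voxelized_ellipsoid(a: float, b: float, c: float, h: float, rot=None) -> VoxelGrid:
    """Axis-aligned (or rotated) solid ellipsoid voxelized at isotropic h mm."""
    ext = max(a, b, c)
    n = int(np.ceil(ext / h)) + 2
    ax = (np.arange(-n, n + 1)) * h
    occ = np.zeros((len(ax), len(ax), len(ax)), dtype=bool)
    X, Y = np.meshgrid(ax, ax)  # (rows=y, cols=x) per slice
    for i, z in enumerate(ax):
        if rot is None:
            q = (X / b) ** 2 + (Y / a) ** 2 + (z / c) ** 2  # arbitrary axis naming
        else:
            pts = np.stack([X, Y, np.full_like(X, z)], axis=-1) @ rot
            q = (pts[..., 0] / a) ** 2 + (pts[..., 1] / b) ** 2 + (pts[..., 2] / c) ** 2
        occ[i] = q <= 1.0
    return VoxelGrid(occ, h, h)
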