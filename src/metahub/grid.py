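"""Voxel-grid data model.

Everything downstream operates on a :class:`VoxelGrid` — a 3-D box of
isotropic voxels in a millimetre (MNI-like) coordinate frame carrying a
gray-matter mask and a partition of that mask into large-scale networks —
and on :class:`VoxelMap` vectors holding one scalar per in-mask voxel.

Maps are stored flat over the gray mask in a fixed C-order voxel ordering
so that every module sees the same voxel sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class GridIncompatibilityError(ValueError):
    """Raised when a volume or map does not live on the session grid."""


@dataclass(frozen=True)
class VoxelGrid:
    """Isotropic voxel grid with gray mask and network labels.

    Parameters
    ----------
    dims
        Number of voxels along each axis, ``(nx, ny, nz)``.
    voxel_size_mm
        Isotropic voxel edge length in mm.
    affine
        4x4 voxel-index -> mm map (homogeneous coordinates).
    gray_mask
        Boolean array of shape ``dims``; True marks gray-matter voxels.
    network_labels
        Integer array of shape ``dims``; values ``1..n_networks`` inside the
        gray mask, 0 outside.
    """

    dims: tuple[int, int, int]
    voxel_size_mm: float
    affine: np.ndarray
    gray_mask: np.ndarray
    network_labels: np.ndarray
    _mask_idx: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.dims):
            raise ValueError(f"dims must be positive, got {self.dims}")
        if self.gray_mask.shape != tuple(self.dims):
            raise GridIncompatibilityError("gray_mask shape does not match dims")
        if self.network_labels.shape != tuple(self.dims):
            raise GridIncompatibilityError("network_labels shape does not match dims")
        if np.any(self.network_labels[~self.gray_mask] != 0):
            raise ValueError("network labels must be zero outside the gray mask")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        # stable voxel ordering: C-order indices of in-mask voxels
        object.__setattr__(
            self, "_mask_idx", np.flatnonzero(self.gray_mask.ravel(order="C"))
        )

    @property
    def n_gray(self) -> int:
        """Number of gray-mask voxels."""
        return int(self._mask_idx.size)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.voxel_size_mm) ** 3

    @property
    def n_networks(self) -> int:
        return int(self.network_labels.max())

    def mask_ijk(self) -> np.ndarray:
        """(n_gray, 3) integer voxel indices of in-mask voxels, C-order."""
        return np.stack(np.unravel_index(self._mask_idx, self.dims), axis=1)

    def coords_mm(self) -> np.ndarray:
        """(n_gray, 3) mm coordinates of in-mask voxel centers."""
        ijk = self.mask_ijk()
        homo = np.c_[ijk, np.ones(len(ijk))]
        return (homo @ self.affine.T)[:, :3]

    def labels_flat(self) -> np.ndarray:
        """Network label per in-mask voxel."""
        return self.network_labels.ravel(order="C")[self._mask_idx]

    def embed(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a flat masked vector back into a full 3-D volume."""
        values = np.asarray(values)
        if values.shape != (self.n_gray,):
            raise GridIncompatibilityError(
                f"expected {self.n_gray} values, got {values.shape}"
            )
        vol = np.full(int(np.prod(self.dims)), fill, dtype=float)
        vol[self._mask_idx] = values
        return vol.reshape(self.dims, order="C")

    def extract(self, volume: np.ndarray) -> np.ndarray:
        """Gather in-mask values from a full 3-D volume."""
        if volume.shape != tuple(self.dims):
            raise GridIncompatibilityError(
                f"volume shape {volume.shape} does not match grid dims {self.dims}"
            )
        return volume.ravel(order="C")[self._mask_idx].astype(float)

    def mm_of_index(self, flat_index: int | np.ndarray) -> np.ndarray:
        """mm coordinates of one (or several) gray-mask voxel indices."""
        return self.coords_mm()[flat_index]


@dataclass
class VoxelMap:
    """One scalar per gray-mask voxel on a shared grid."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_gray,):
            raise GridIncompatibilityError(
                f"map length {self.values.shape} != gray voxel count {self.grid.n_gray}"
            )

    def copy_with(self, values: np.ndarray) -> "VoxelMap":
        return VoxelMap(self.grid, values)


def make_grid(
    dims: tuple[int, int, int],
    voxel_size_mm: float = 3.0,
    n_networks: int = 8,
    seed: int = 0,
) -> VoxelGrid:
    """Build a fully gray grid whose mask is partitioned into contiguous networks.

    The mask covers every voxel and is split into ``n_networks`` contiguous
    slabs along the first axis (balanced in voxel count), emulating a
    gray-matter mask divided into large-scale networks. The construction is
    deterministic; ``seed`` is accepted for interface uniformity.
    """
    if any(int(d) <= 0 for d in dims):
        raise ValueError(f"dims must be positive, got {dims}")
    if n_networks < 2:
        raise ValueError("n_networks must be >= 2")
    dims = (int(dims[0]), int(dims[1]), int(dims[2]))
    affine = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
    gray = np.ones(dims, dtype=bool)
    # contiguous slab partition over the flat C-order index
    n_vox = int(np.prod(dims))
    flat_labels = 1 + (np.arange(n_vox) * n_networks) // n_vox
    labels = flat_labels.reshape(dims, order="C").astype(np.int32)
    return VoxelGrid(
        dims=dims,
        voxel_size_mm=float(voxel_size_mm),
        affine=affine,
        gray_mask=gray,
        network_labels=labels,
    )


def euclidean_distance_mm(grid: VoxelGrid, i: int, j: int) -> float:
    """Center-to-center distance in mm between two gray-mask voxels.

    ``i`` and ``j`` index the flat gray-mask voxel ordering.
    """
    n = grid.n_gray
    if not (0 <= i < n and 0 <= j < n):
        raise ValueError(f"voxel index out of mask range [0, {n})")
    coords = grid.coords_mm()
    return float(np.linalg.norm(coords[i] - coords[j]))


def pairwise_distances_mm(grid: VoxelGrid) -> np.ndarray:
    """(n_gray, n_gray) center-to-center distance matrix in mm."""
    from scipy.spatial.distance import squareform, pdist

    return squareform(pdist(grid.coords_mm()))
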