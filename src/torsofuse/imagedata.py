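"""Shared image-domain containers: axial slices, deformation fields,
voxel volumes.

Conventions (fixed so Dice and Jacobian results are reproducible):

* masks are 0-based ``(row, col)`` arrays; increasing column = patient
  left->right image axis (in-plane u), increasing row = posterior ->
  anterior (in-plane v);
* pixel-center convention: pixel ``(i, j)`` samples the physical point
  at in-plane coordinates ``(j * spacing_u, i * spacing_v)``;
* a slice's world pose is a 4x4 homogeneous matrix with unit direction
  columns ``(u_dir, v_dir, normal)`` and the world position of pixel
  (0, 0) as translation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["AxialSlice", "DeformationField", "VoxelVolume"]


@dataclass
class AxialSlice:
    """One axial MRI slice: world pose plus torso and vertebra masks.

    Attributes
    ----------
    pose : (4, 4) array
        Rotation columns are the in-plane u (column) and v (row) unit
        directions and the plane normal; translation is the world
        position of the pixel (0, 0) center, in mm.
    spacing : (2,) tuple
        In-plane pixel size ``(u_mm, v_mm)`` (default 1 x 1 mm).
    torso_mask, vertebra_mask : (ny, nx) bool arrays
    vertebra_label : str or None
        Assigned vertebra (nearest center z at acquisition for phantom
        slices; reassigned during registration otherwise).
    index : int
        Position in the inferior-to-superior stack.
    """

    pose: np.ndarray
    spacing: tuple
    torso_mask: np.ndarray
    vertebra_mask: np.ndarray
    vertebra_label: Optional[str] = None
    index: int = 0

    def __post_init__(self) -> None:
        self.pose = np.asarray(self.pose, dtype=float).reshape(4, 4)
        self.torso_mask = np.asarray(self.torso_mask, dtype=bool)
        self.vertebra_mask = np.asarray(self.vertebra_mask, dtype=bool)
        if self.torso_mask.shape != self.vertebra_mask.shape:
            raise ValueError("torso and vertebra masks must share a grid")
        if np.any(self.vertebra_mask & ~self.torso_mask):
            raise ValueError("vertebra mask must be contained in torso mask")

    @property
    def shape(self) -> tuple:
        return self.torso_mask.shape

    @property
    def origin(self) -> np.ndarray:
        return self.pose[:3, 3]

    @property
    def u_dir(self) -> np.ndarray:
        return self.pose[:3, 0]

    @property
    def v_dir(self) -> np.ndarray:
        return self.pose[:3, 1]

    @property
    def normal(self) -> np.ndarray:
        return self.pose[:3, 2]

    def plane_to_world(self, uv: np.ndarray) -> np.ndarray:
        """Map in-plane mm coordinates (…, 2) to world mm points (…, 3)."""
        uv = np.asarray(uv, dtype=float)
        return (
            self.origin
            + np.multiply.outer(uv[..., 0], self.u_dir)
            + np.multiply.outer(uv[..., 1], self.v_dir)
        )

    def world_to_plane(self, points: np.ndarray) -> np.ndarray:
        """Project world points (…, 3) to in-plane mm coordinates (…, 2)."""
        rel = np.asarray(points, dtype=float) - self.origin
        return np.stack([rel @ self.u_dir, rel @ self.v_dir], axis=-1)

    def pixel_to_world(self, ij: np.ndarray) -> np.ndarray:
        """World positions of ``(row, col)`` pixel indices (…, 2)."""
        ij = np.asarray(ij, dtype=float)
        uv = np.stack(
            [ij[..., 1] * self.spacing[0], ij[..., 0] * self.spacing[1]], axis=-1
        )
        return self.plane_to_world(uv)

    def pixel_grid_plane(self) -> np.ndarray:
        """In-plane mm coordinates of every pixel center, shape (ny, nx, 2)."""
        ny, nx = self.shape
        u = np.arange(nx) * self.spacing[0]
        v = np.arange(ny) * self.spacing[1]
        uu, vv = np.meshgrid(u, v)
        return np.stack([uu, vv], axis=-1)

    def transformed(self, T) -> "AxialSlice":
        """Slice with pose pre-multiplied by a RigidTransform; pixels
        untouched (pose-only reslicing)."""
        return AxialSlice(
            T.as_matrix() @ self.pose,
            self.spacing,
            self.torso_mask.copy(),
            self.vertebra_mask.copy(),
            vertebra_label=self.vertebra_label,
            index=self.index,
        )


@dataclass
class DeformationField:
    """Dense in-plane displacement grid for one slice.

    ``displacements[i, j]`` is the (du, dv) displacement in mm of the
    pixel-(i, j) point under the forward mapping x -> x + u(x),
    expressed in the slice's in-plane coordinates.
    """

    displacements: np.ndarray
    spacing: tuple

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=float)
        if not np.all(np.isfinite(self.displacements)):
            raise ValueError("deformation field contains non-finite values")
        if self.displacements.ndim != 3 or self.displacements.shape[2] != 2:
            raise ValueError("expected an (ny, nx, 2) displacement grid")


@dataclass
class VoxelVolume:
    """Anisotropic binary occupancy grid.

    ``occupancy[ix, iy, iz]`` covers the voxel whose center is at
    ``origin + ((ix + .5) sx, (iy + .5) sy, (iz + .5) sz)`` — axis order
    (x, y, z) matching ``spacing``.
    """

    occupancy: np.ndarray
    spacing: tuple
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy).astype(np.uint8)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.occupancy.ndim != 3:
            raise ValueError("occupancy must be a 3D grid")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if not np.all((self.occupancy == 0) | (self.occupancy == 1)):
            raise ValueError("occupancy must be binary")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def volume_mm3(self) -> float:
        return float(self.occupancy.sum()) * self.voxel_volume_mm3
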