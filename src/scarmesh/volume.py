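"""Volumetric domain types: LGE intensity volumes and binary masks.

An :class:`LGEVolume` is a 3D scalar grid with voxel spacing and a 4x4
voxel-index -> world-mm affine. Voxel indices are 0-based and a voxel's
world position refers to its *center*; the cuboid rendered for a voxel
spans +/- spacing/2 about that center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class LGEVolume:
    """A 3D late-gadolinium-enhancement intensity volume.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Signal intensity in arbitrary units.
    spacing : tuple of float
        Voxel size ``(dx, dy, dz)`` in mm; all components > 0.
    affine : ndarray, shape (4, 4), optional
        Voxel-index -> world-mm transform. Defaults to a diagonal affine
        built from ``spacing`` with the origin at voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"volume data must be 3D, got {self.data.ndim} dimensions"
            )
        if min(self.data.shape) < 1:
            raise ValueError("volume must have extent >= 1 along each axis")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to world mm (voxel centers)."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        homo = np.concatenate([idx, np.ones((len(idx), 1))], axis=1)
        out = homo @ self.affine.T
        return out[:, :3].reshape(np.shape(indices))

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map (..., 3) world-mm points to (fractional) voxel indices."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        homo = np.concatenate([pts, np.ones((len(pts), 1))], axis=1)
        out = homo @ np.linalg.inv(self.affine).T
        return out[:, :3].reshape(np.shape(points))

    def voxel_centers(self, mask: np.ndarray | None = None) -> np.ndarray:
        """World-mm centers of all voxels (or of ``mask`` voxels), (N, 3)."""
        if mask is None:
            idx = np.stack(
                np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"), -1
            ).reshape(-1, 3)
        else:
            idx = np.argwhere(np.asarray(mask, dtype=bool))
        return self.index_to_world(idx)


@dataclass
class BinaryMask:
    """A boolean mask living on the grid of a reference :class:`LGEVolume`."""

    data: np.ndarray
    grid: LGEVolume

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.data.shape} != grid shape {self.grid.shape}"
            )

    @property
    def count(self) -> int:
        return int(self.data.sum())

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        return BinaryMask(self.data & other.data, self.grid)

    def __or__(self, other: "BinaryMask") -> "BinaryMask":
        return BinaryMask(self.data | other.data, self.grid)
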