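"""Voxel grids with world (MNI-style millimetre) coordinates.

A :class:`Grid` couples a 3-D voxel array shape with a 4x4 affine that maps
voxel indices to the centres of the voxels in world space, the same
convention nibabel uses for NIfTI images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from nibabel.affines import apply_affine


@dataclass(frozen=True)
class Grid:
    """Regular 3-D voxel grid embedded in world coordinates.

    Parameters
    ----------
    shape
        Number of voxels along x, y, z.
    affine
        4x4 voxel-to-world transform; ``affine @ [i, j, k, 1]`` is the world
        coordinate of the centre of voxel ``(i, j, k)``.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self):
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("grid transform is not invertible")
        object.__setattr__(self, "affine", aff)
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    @classmethod
    def from_spacing(
        cls,
        shape: tuple[int, int, int],
        voxel_size_mm: float | tuple[float, float, float],
        origin_mm: tuple[float, float, float],
    ) -> "Grid":
        """Axis-aligned grid: voxel ``(0,0,0)`` has its centre at ``origin_mm``."""
        vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
        aff = np.eye(4)
        aff[:3, :3] = np.diag(vs)
        aff[:3, 3] = origin_mm
        return cls(tuple(shape), aff)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centres, shape ``(n_voxels, 3)``.

        Ordering is C-order over ``(i, j, k)``, matching ``np.ravel`` of a
        volume with this grid's shape.
        """
        idx = np.indices(self.shape).reshape(3, -1).T
        return apply_affine(self.affine, idx)

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinates of world points."""
        return apply_affine(np.linalg.inv(self.affine), np.asarray(xyz, float))

    def contains_world(self, xyz: np.ndarray) -> np.ndarray:
        """True where world points fall inside the grid's voxel extent."""
        v = np.atleast_2d(self.world_to_voxel(xyz))
        lo = v >= -0.5
        hi = v <= np.asarray(self.shape) - 0.5
        return (lo & hi).all(axis=1)

    def __eq__(self, other):
        return (
            isinstance(other, Grid)
            and self.shape == other.shape
            and np.allclose(self.affine, other.affine)
        )

    def __hash__(self):
        return hash((self.shape, self.affine.tobytes()))
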