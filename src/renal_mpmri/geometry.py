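"""Acquisition geometry: field of view, matrix, slice stack and the voxel arithmetic.

World coordinates are in millimetres with the origin at the corner of the imaged
slab and positions given at voxel centres. The array layout is always
``(row, col, slice)``; ``orientation`` records which anatomical axis the slice
stack runs along (axial: slices along the animal's long axis z; coronal: slices
along y), which is what makes axial and coronal stacks of the same phantom
comparable lesion by lesion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AcquisitionGeometry"]


@dataclass(frozen=True)
class AcquisitionGeometry:
    """In-plane field of view / matrix plus a slice stack.

    Parameters
    ----------
    fov_mm:
        In-plane field of view (row extent, col extent) in mm.
    matrix:
        In-plane matrix size (rows, cols); voxel size is ``fov_mm / matrix``.
    slice_thickness_mm:
        Slice thickness in mm (slices are contiguous, no gap).
    n_slices:
        Number of slices in the stack.
    orientation:
        ``"axial"`` (slices stacked along world z) or ``"coronal"``
        (slices stacked along world y).
    """

    fov_mm: tuple[float, float]
    matrix: tuple[int, int]
    slice_thickness_mm: float
    n_slices: int
    orientation: str = "axial"

    def __post_init__(self) -> None:
        if len(self.fov_mm) != 2 or len(self.matrix) != 2:
            raise ValueError("fov_mm and matrix must have two entries")
        if any(f <= 0 for f in self.fov_mm):
            raise ValueError("field of view must be positive")
        if any(int(m) != m or m <= 0 for m in self.matrix):
            raise ValueError("matrix entries must be positive integers")
        if self.slice_thickness_mm <= 0:
            raise ValueError("slice thickness must be positive")
        if self.n_slices <= 0:
            raise ValueError("n_slices must be positive")
        if self.orientation not in ("axial", "coronal"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    # ------------------------------------------------------------------ sizes
    @property
    def inplane_voxel_mm(self) -> tuple[float, float]:
        return (self.fov_mm[0] / self.matrix[0], self.fov_mm[1] / self.matrix[1])

    @property
    def voxel_size_mm(self) -> tuple[float, float, float]:
        """(row, col, slice) voxel dimensions in mm."""
        dr, dc = self.inplane_voxel_mm
        return (dr, dc, self.slice_thickness_mm)

    @property
    def voxel_volume_mm3(self) -> float:
        dr, dc, ds = self.voxel_size_mm
        return dr * dc * ds

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.matrix[0], self.matrix[1], self.n_slices)

    @property
    def slab_mm(self) -> float:
        return self.n_slices * self.slice_thickness_mm

    # ----------------------------------------------------------- coordinates
    def axis_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-centre coordinates along each *array* axis (row, col, slice)."""
        dr, dc, ds = self.voxel_size_mm
        r = (np.arange(self.matrix[0]) + 0.5) * dr
        c = (np.arange(self.matrix[1]) + 0.5) * dc
        s = (np.arange(self.n_slices) + 0.5) * ds
        return r, c, s

    @property
    def world_permutation(self) -> tuple[int, int, int]:
        """World component (0=x, 1=y, 2=z) carried by each array axis.

        Axial slices tile the (x, y) plane and stack along z → (0, 1, 2);
        coronal slices tile (x, z) and stack along y → (0, 2, 1).
        """
        return (0, 1, 2) if self.orientation == "axial" else (0, 2, 1)

    def array_to_world(self, rcs: np.ndarray) -> np.ndarray:
        """Map (..., 3) array-axis mm coordinates to world (x, y, z) mm."""
        rcs = np.asarray(rcs, dtype=float)
        out = np.empty_like(rcs)
        for axis, world in enumerate(self.world_permutation):
            out[..., world] = rcs[..., axis]
        return out

    def world_to_array(self, xyz: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`array_to_world` (permutation is an involution here)."""
        xyz = np.asarray(xyz, dtype=float)
        out = np.empty_like(xyz)
        for axis, world in enumerate(self.world_permutation):
            out[..., axis] = xyz[..., world]
        return out

    def affine(self) -> np.ndarray:
        """NIfTI-style affine mapping voxel indices to world mm."""
        dr, dc, ds = self.voxel_size_mm
        aff = np.zeros((4, 4))
        aff[3, 3] = 1.0
        if self.orientation == "axial":
            steps = [(0, dr), (1, dc), (2, ds)]
        else:
            steps = [(0, dr), (2, dc), (1, ds)]
        for axis, (world, step) in enumerate(steps):
            aff[world, axis] = step
            aff[world, 3] = step / 2.0
        return aff
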