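"""Core data containers shared across the pipeline.

The pipeline operates on 4D BOLD runs sampled on a common 3D grid. All
spatial reasoning (neighbourhood spheres, cluster peak coordinates) goes
through :class:`GridGeometry`, which carries the voxel-to-world affine in
the NIfTI convention: world mm coordinates of voxel (i, j, k) are obtained
by applying the 4x4 affine to the homogeneous vector (i, j, k, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridGeometry",
    "BoldRun",
    "MotionParams",
    "TissueMasks",
]


@dataclass(frozen=True)
class GridGeometry:
    """A 3D sampling grid with its voxel-to-world-mm affine."""

    dims: tuple[int, int, int]
    affine: np.ndarray  # 4x4 voxel -> world mm

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        object.__setattr__(self, "dims", dims)
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {aff.shape}")
        if any(d < 1 for d in dims):
            raise ValueError(f"grid dims must all be >= 1, got {dims}")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        aff.flags.writeable = False
        object.__setattr__(self, "affine", aff)

    @property
    def voxel_size_mm(self) -> tuple[float, float, float]:
        """Per-axis voxel edge length in mm (column norms of the affine)."""
        sizes = np.linalg.norm(self.affine[:3, :3], axis=0)
        return tuple(float(s) for s in sizes)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to world mm coordinates (..., 3)."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        out = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
        return out if out.shape[0] > 1 else out[0]

    @classmethod
    def isotropic(
        cls, dims: tuple[int, int, int], voxel_mm: float = 3.0
    ) -> "GridGeometry":
        """Isotropic grid with the world origin at the grid centre.

        Centring the origin makes cluster peak coordinates read like the
        usual standard-space mm coordinates (0 near the middle of the
        volume, symmetric negative/positive ranges).
        """
        dims = tuple(int(d) for d in dims)
        affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
        affine[:3, 3] = -voxel_mm * (np.array(dims) - 1) / 2.0
        return cls(dims=dims, affine=affine)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GridGeometry):
            return NotImplemented
        return self.dims == other.dims and np.allclose(self.affine, other.affine)

    def __hash__(self) -> int:  # frozen dataclass with ndarray field
        return hash((self.dims, self.affine.tobytes()))


@dataclass
class BoldRun:
    """A single subject's 4D BOLD time series (x, y, z, t)."""

    data: np.ndarray
    geometry: GridGeometry
    tr_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D, got {self.data.ndim}D")
        if self.data.shape[:3] != self.geometry.dims:
            raise ValueError(
                f"spatial dims {self.data.shape[:3]} do not match "
                f"geometry {self.geometry.dims}"
            )
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_s)


@dataclass
class MotionParams:
    """Rigid-body head-motion trace: per-timepoint translations and rotations.

    Columns follow the common realignment-file convention: three
    translations in mm then three rotations in degrees.
    """

    translations_mm: np.ndarray  # (t, 3)
    rotations_deg: np.ndarray  # (t, 3)

    def __post_init__(self) -> None:
        self.translations_mm = np.atleast_2d(
            np.asarray(self.translations_mm, dtype=float)
        )
        self.rotations_deg = np.atleast_2d(np.asarray(self.rotations_deg, dtype=float))
        if self.translations_mm.shape != self.rotations_deg.shape:
            raise ValueError("translations and rotations must have the same shape")
        if self.translations_mm.shape[1] != 3:
            raise ValueError("motion parameters must have 3 columns per block")

    @property
    def n_timepoints(self) -> int:
        return self.translations_mm.shape[0]

    def as_matrix(self) -> np.ndarray:
        """(t, 6) matrix: trans x,y,z mm then rot x,y,z degrees."""
        return np.hstack([self.translations_mm, self.rotations_deg])

    @classmethod
    def from_matrix(cls, mat: np.ndarray) -> "MotionParams":
        mat = np.atleast_2d(np.asarray(mat, dtype=float))
        if mat.shape[1] < 6:
            raise ValueError(f"motion matrix needs >= 6 columns, got {mat.shape[1]}")
        return cls(translations_mm=mat[:, :3], rotations_deg=mat[:, 3:6])


@dataclass
class TissueMasks:
    """Binary tissue masks on a common grid.

    gray, white and csf are pairwise disjoint and each is contained in
    whole_brain; this is validated at construction.
    """

    gray: np.ndarray
    white: np.ndarray
    csf: np.ndarray
    whole_brain: np.ndarray
    geometry: GridGeometry | None = field(default=None)

    def __post_init__(self) -> None:
        for name in ("gray", "white", "csf", "whole_brain"):
            setattr(self, name, np.asarray(getattr(self, name)).astype(bool))
        shapes = {getattr(self, n).shape for n in ("gray", "white", "csf", "whole_brain")}
        if len(shapes) != 1:
            raise ValueError(f"mask shapes differ: {shapes}")
        pairs = [("gray", "white"), ("gray", "csf"), ("white", "csf")]
        for a, b in pairs:
            if np.any(getattr(self, a) & getattr(self, b)):
                raise ValueError(f"masks {a} and {b} overlap")
        for name in ("gray", "white", "csf"):
            if np.any(getattr(self, name) & ~self.whole_brain):
                raise ValueError(f"mask {name} extends outside whole_brain")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.gray.shape
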