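"""Core spatial data types.

All grids are 3D scalar (or per-voxel vector) arrays paired with a 4x4
voxel-to-world affine in mm (RAS orientation, 0-based voxel indices).
Displacement fields are stored in world millimetres, never voxel units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Volume",
    "BinaryMask",
    "ProbabilityMap",
    "TissueLabels",
    "AffineTransform",
    "DeformationField",
    "CompositeTransform",
    "GridMismatchError",
    "BACKGROUND",
    "CSF",
    "GM",
    "WM",
]

# tissue label codes
BACKGROUND, CSF, GM, WM = 0, 1, 2, 3


class GridMismatchError(ValueError):
    """Two grid-aligned objects do not share shape and affine."""


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if not np.all(np.isfinite(affine)):
        raise ValueError("affine contains non-finite entries")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-8:
        raise ValueError("affine is singular")
    return affine


def same_grid(a, b, atol: float = 1e-5) -> bool:
    """True when two grid objects share shape and affine (within atol)."""
    return a.data.shape == b.data.shape and np.allclose(a.affine, b.affine, atol=atol)


def require_same_grid(a, b, what: str = "operands") -> None:
    if not same_grid(a, b):
        raise GridMismatchError(
            f"{what} must share a grid: shapes {a.data.shape} vs {b.data.shape}"
        )


@dataclass
class Volume:
    """A 3D scalar grid with a voxel-to-world affine (mm)."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.data.ndim}")
        n_bad = int(np.size(self.data) - np.count_nonzero(np.isfinite(self.data)))
        if n_bad:
            raise ValueError(f"volume contains {n_bad} non-finite voxel(s)")
        self.affine = _check_affine(self.affine)

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Per-axis voxel spacing in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.affine.copy())

    def world_coordinates(self) -> np.ndarray:
        """World (mm) coordinates of every voxel centre, shape (3, *grid)."""
        idx = np.indices(self.data.shape, dtype=float)
        flat = idx.reshape(3, -1)
        world = self.affine[:3, :3] @ flat + self.affine[:3, 3:4]
        return world.reshape((3,) + self.data.shape)


@dataclass
class BinaryMask:
    """A {0,1}-valued grid sharing the geometry conventions of Volume."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={arr.ndim}")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask values must be in {{0,1}}, found {vals[:10]}")
        self.data = arr.astype(np.uint8)
        self.affine = _check_affine(self.affine)

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())

    def astype_bool(self) -> np.ndarray:
        return self.data.astype(bool)

    def copy(self) -> "BinaryMask":
        return BinaryMask(self.data.copy(), self.affine.copy())


@dataclass
class ProbabilityMap:
    """A [0,1]-valued grid (blood probability, replacement weights...)."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D map, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("probability map contains non-finite values")
        lo, hi = float(self.data.min()), float(self.data.max())
        if lo < -1e-12 or hi > 1 + 1e-12:
            raise ValueError(f"probability values outside [0,1]: min={lo}, max={hi}")
        np.clip(self.data, 0.0, 1.0, out=self.data)
        self.affine = _check_affine(self.affine)

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class TissueLabels:
    """Label grid: 0 background, 1 CSF, 2 grey matter, 3 white matter."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D label grid, got ndim={arr.ndim}")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (BACKGROUND, CSF, GM, WM))):
            raise ValueError(f"labels must be in {{0,1,2,3}}, found {vals[:10]}")
        self.data = arr.astype(np.uint8)
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def mask_of(self, label: int) -> np.ndarray:
        return self.data == label

    def brain(self) -> BinaryMask:
        """Union of the non-background classes."""
        return BinaryMask((self.data != BACKGROUND).astype(np.uint8), self.affine)


@dataclass
class AffineTransform:
    """World-to-world affine, mapping moving-space mm to fixed-space mm."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"matrix must be 4x4, got {m.shape}")
        if not np.allclose(m[3], (0, 0, 0, 1), atol=1e-9):
            raise ValueError("last affine row must be (0,0,0,1)")
        if abs(np.linalg.det(m[:3, :3])) < 1e-8:
            raise ValueError("affine transform is singular")
        self.matrix = m
        self.matrix[3] = (0, 0, 0, 1)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        """Map (N,3) moving-space points to fixed space."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def compose_after(self, first: "AffineTransform") -> "AffineTransform":
        """Transform applying `first`, then self."""
        return AffineTransform(self.matrix @ first.matrix)

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3].copy()


@dataclass
class DeformationField:
    """Per-voxel displacement vectors (mm, world) on a reference grid.

    The total mapping in fixed space is phi(x) = x + u(x); during
    resampling the displaced point is handed on to any affine component.
    """

    displacements: np.ndarray  # shape grid + (3,)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        u = np.asarray(self.displacements, dtype=np.float64)
        if u.ndim != 4 or u.shape[-1] != 3:
            raise ValueError(f"displacements must have shape (i,j,k,3), got {u.shape}")
        if not np.all(np.isfinite(u)):
            raise ValueError("deformation field contains non-finite values")
        self.displacements = u
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.displacements.shape[:3]

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def magnitude(self) -> np.ndarray:
        return np.sqrt((self.displacements**2).sum(axis=-1))


@dataclass
class CompositeTransform:
    """An affine followed by an optional deformation in fixed space."""

    affine_part: AffineTransform
    deformation: DeformationField | None = None

    @classmethod
    def from_affine(cls, t: AffineTransform) -> "CompositeTransform":
        return cls(affine_part=t, deformation=None)

    @property
    def has_deformation(self) -> bool:
        return self.deformation is not None
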