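"""Voxel lattice primitives shared by structures and dose distributions.

Conventions
-----------
* Array axes (0, 1, 2) map to the patient axes (left-right, posterior-anterior,
  inferior-superior); increasing index means right / anterior / superior.
* Physical coordinates are millimetres: ``x = origin + index * spacing``.
* Volumes are reported in cubic centimetres (cc); 1 voxel at 2 mm isotropic
  spacing is 0.008 cc.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Tuple

import numpy as np

Triple = Tuple[float, float, float]


@dataclass(frozen=True)
class GridSpec:
    """Regular 3D lattice: shape in voxels, spacing and origin in mm."""

    shape: Tuple[int, int, int]
    spacing: Triple = (2.0, 2.0, 2.0)
    origin: Triple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"shape must be three positive ints, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def axes(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates of voxel centres along each axis (mm)."""
        return tuple(
            self.origin[i] + self.spacing[i] * np.arange(self.shape[i])
            for i in range(3)
        )

    def coordinate_grids(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable physical-coordinate grids (mm) for the full lattice."""
        ax = self.axes()
        return np.meshgrid(*ax, indexing="ij", sparse=True)

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(idx) * np.asarray(self.spacing)

    def physical_to_index(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def same_lattice(self, other: "GridSpec", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


class LatticeMismatchError(ValueError):
    """Two objects that must share a voxel lattice do not."""


def _require_same_lattice(a: GridSpec, b: GridSpec) -> None:
    if not a.same_lattice(b):
        raise LatticeMismatchError(f"lattice mismatch: {a} vs {b}")


@dataclass
class StructureSet:
    """Named binary organ masks sharing one voxel lattice."""

    grid: GridSpec
    masks: Dict[str, np.ndarray] = field(default_factory=dict)
    provenance: str = "planning"

    def __post_init__(self) -> None:
        for name, mask in self.masks.items():
            self.masks[name] = self._validate_mask(name, mask)

    def _validate_mask(self, name: str, mask: np.ndarray) -> np.ndarray:
        mask = np.asarray(mask)
        if mask.shape != self.grid.shape:
            raise LatticeMismatchError(
                f"mask {name!r} shape {mask.shape} != grid shape {self.grid.shape}"
            )
        return mask.astype(bool)

    def add(self, name: str, mask: np.ndarray) -> None:
        self.masks[name] = self._validate_mask(name, mask)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def names(self) -> Iterator[str]:
        return iter(self.masks)

    def volume_cc(self, name: str) -> float:
        return float(self.masks[name].sum()) * self.grid.voxel_volume_cc

    def centroid_mm(self, name: str) -> np.ndarray:
        """Physical centroid (mm) of a mask; raises on empty masks."""
        mask = self.masks[name]
        if not mask.any():
            raise ValueError(f"mask {name!r} is empty")
        idx = np.argwhere(mask).mean(axis=0)
        return self.grid.index_to_physical(idx)


@dataclass
class DoseGrid:
    """3D dose field in Gy on a regular lattice."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise LatticeMismatchError(
                f"dose shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("dose contains negative values")

    def scaled(self, factor: float) -> "DoseGrid":
        return DoseGrid(self.grid, self.values * float(factor))
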