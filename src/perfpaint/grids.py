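"""Shared voxel-grid geometry and the scalar/binary volume containers.

All volumes in a pipeline run live on one :class:`ImageGrid`. Geometry is
kept in physical millimetres; voxel indices are 0-based and ordered
(x, y, z) to match the NIfTI affine convention used by :mod:`perfpaint.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = ["ImageGrid", "PerfusionMap", "DoseGrid", "StructureMask", "StructureSet"]


@dataclass(frozen=True)
class ImageGrid:
    """Voxel lattice shared by all volumes of one subject.

    Parameters
    ----------
    shape
        Number of voxels along each axis.
    spacing_mm
        Physical voxel spacing along each axis in mm; strictly positive.
    origin_mm
        World coordinate of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 3.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing_mm}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(s) for s in self.origin_mm))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def coordinates_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of every voxel center, one array per axis."""
        axes = [
            self.origin_mm[i] + np.arange(self.shape[i]) * self.spacing_mm[i]
            for i in range(3)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij"))

    def center_mm(self) -> tuple[float, float, float]:
        return tuple(
            self.origin_mm[i] + (self.shape[i] - 1) * self.spacing_mm[i] / 2.0
            for i in range(3)
        )

    def extent_mm(self) -> tuple[float, float, float]:
        return tuple((self.shape[i] - 1) * self.spacing_mm[i] for i in range(3))


def _check_grid(grid: ImageGrid, values: np.ndarray, what: str) -> np.ndarray:
    values = np.asarray(values)
    if values.shape != grid.shape:
        raise ValueError(
            f"{what} shape {values.shape} does not match grid shape {grid.shape}"
        )
    return values


@dataclass
class PerfusionMap:
    """Cerebral blood flow map in ml/100g/min on an :class:`ImageGrid`."""

    grid: ImageGrid
    cbf: np.ndarray

    def __post_init__(self) -> None:
        self.cbf = _check_grid(self.grid, self.cbf, "CBF").astype(np.float32)
        if not np.all(np.isfinite(self.cbf)):
            raise ValueError("CBF map contains non-finite values")
        if np.any(self.cbf < 0):
            raise ValueError("CBF values must be nonnegative")


@dataclass
class DoseGrid:
    """Absorbed dose in Gy on an :class:`ImageGrid`."""

    grid: ImageGrid
    dose: np.ndarray

    def __post_init__(self) -> None:
        self.dose = _check_grid(self.grid, self.dose, "dose").astype(np.float64)
        if not np.all(np.isfinite(self.dose)):
            raise ValueError("dose grid contains non-finite values")
        if np.any(self.dose < 0):
            raise ValueError("dose values must be nonnegative")


@dataclass
class StructureMask:
    """Named binary structure mask on an :class:`ImageGrid`."""

    grid: ImageGrid
    name: str
    member: np.ndarray

    def __post_init__(self) -> None:
        self.member = _check_grid(self.grid, self.member, f"mask {self.name!r}").astype(
            bool
        )

    @property
    def voxel_count(self) -> int:
        return int(self.member.sum())

    @property
    def volume_cc(self) -> float:
        return self.voxel_count * self.grid.voxel_volume_cc

    def is_empty(self) -> bool:
        return not self.member.any()

    def with_name(self, name: str) -> "StructureMask":
        return StructureMask(self.grid, name, self.member)

    # set algebra on a shared grid
    def union(self, other: "StructureMask", name: str | None = None) -> "StructureMask":
        self._check_companion(other)
        return StructureMask(self.grid, name or self.name, self.member | other.member)

    def subtract(
        self, other: "StructureMask", name: str | None = None
    ) -> "StructureMask":
        self._check_companion(other)
        return StructureMask(self.grid, name or self.name, self.member & ~other.member)

    def intersect(
        self, other: "StructureMask", name: str | None = None
    ) -> "StructureMask":
        self._check_companion(other)
        return StructureMask(self.grid, name or self.name, self.member & other.member)

    def contains(self, other: "StructureMask") -> bool:
        self._check_companion(other)
        return bool(np.all(~other.member | self.member))

    def _check_companion(self, other: "StructureMask") -> None:
        if other.grid != self.grid:
            raise ValueError(
                f"masks {self.name!r} and {other.name!r} are on different grids"
            )


@dataclass
class StructureSet:
    """Collection of structure masks sharing one grid, addressable by name."""

    grid: ImageGrid
    masks: dict[str, StructureMask] = field(default_factory=dict)

    def add(self, mask: StructureMask) -> None:
        if mask.grid != self.grid:
            raise ValueError(f"mask {mask.name!r} grid differs from structure set grid")
        self.masks[mask.name] = mask

    def __getitem__(self, name: str) -> StructureMask:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __iter__(self) -> Iterator[StructureMask]:
        return iter(self.masks.values())

    def names(self) -> list[str]:
        return list(self.masks)

    def volumes_cc(self) -> dict[str, float]:
        return {name: m.volume_cc for name, m in self.masks.items()}
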