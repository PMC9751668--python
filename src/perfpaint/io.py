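"""NIfTI I/O for perfusion maps, dose grids and structure masks.

NIfTI is the sole exchange format: masks are stored as uint8 {0, 1}, scalar
volumes as float32. Grid geometry (shape, spacing, origin) travels in the
affine, which is kept diagonal (axis-aligned grids only). Validation is
strict: a mask payload must be binary to within 1e-6 and a CBF map must be
nonnegative — malformed inputs are rejected, not coerced.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .grids import DoseGrid, ImageGrid, PerfusionMap, StructureMask

__all__ = [
    "grid_to_affine",
    "grid_from_image",
    "write_volume",
    "read_perfusion_map",
    "read_dose_grid",
    "read_structure_mask",
]

_BINARY_TOL = 1e-6


def grid_to_affine(grid: ImageGrid) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(grid.spacing_mm)
    affine[:3, 3] = grid.origin_mm
    return affine


def grid_from_image(img: nib.Nifti1Image) -> ImageGrid:
    if img.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {img.shape}")
    affine = img.affine
    rotation = affine[:3, :3]
    if not np.allclose(rotation, np.diag(np.diag(rotation)), atol=1e-6):
        raise ValueError("only axis-aligned (diagonal-affine) volumes are supported")
    spacing = np.abs(np.diag(rotation))
    return ImageGrid(
        shape=tuple(int(s) for s in img.shape),
        spacing_mm=tuple(float(s) for s in spacing),
        origin_mm=tuple(float(v) for v in affine[:3, 3]),
    )


def write_volume(volume, path: str | Path) -> Path:
    """Write a PerfusionMap, DoseGrid or StructureMask as NIfTI."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(volume, StructureMask):
        data = volume.member.astype(np.uint8)
    elif isinstance(volume, PerfusionMap):
        data = volume.cbf.astype(np.float32)
    elif isinstance(volume, DoseGrid):
        data = volume.dose.astype(np.float32)
    else:
        raise TypeError(f"cannot write object of type {type(volume).__name__}")
    img = nib.Nifti1Image(data, grid_to_affine(volume.grid))
    img.header.set_zooms(volume.grid.spacing_mm)
    nib.save(img, str(path))
    return path


def _load(path: str | Path) -> tuple[ImageGrid, np.ndarray]:
    img = nib.load(str(path))
    grid = grid_from_image(img)
    return grid, np.asarray(img.dataobj, dtype=np.float64)


def read_perfusion_map(path: str | Path) -> PerfusionMap:
    grid, data = _load(path)
    if np.any(data < 0):
        bad = float(data.min())
        raise ValueError(f"{path}: CBF map contains negative values (min {bad:g})")
    return PerfusionMap(grid, data)


def read_dose_grid(path: str | Path) -> DoseGrid:
    grid, data = _load(path)
    if np.any(data < 0):
        raise ValueError(f"{path}: dose grid contains negative values")
    return DoseGrid(grid, data)


def read_structure_mask(path: str | Path, name: str | None = None) -> StructureMask:
    grid, data = _load(path)
    off_binary = np.minimum(np.abs(data), np.abs(data - 1.0)) > _BINARY_TOL
    if off_binary.any():
        offending = np.unique(data[off_binary])[:5]
        raise ValueError(
            f"{path}: mask payload is not binary; offending values include "
            f"{[float(v) for v in offending]}"
        )
    mask_name = name if name is not None else Path(path).name.split(".")[0]
    return StructureMask(grid, mask_name, data > 0.5)


def check_shared_grid(*volumes) -> ImageGrid:
    """Assert all volumes share one grid and return it."""
    grids = {v.grid for v in volumes}
    if len(grids) != 1:
        raise ValueError("companion volumes are on mismatched grids")
    return next(iter(grids))
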