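"""Seeded synthetic single-metastasis head phantoms.

Each phantom is a CBF map plus structure masks (brain, GTV, organs at risk)
on a shared grid. The tumor is an axis-aligned ellipsoid whose perfusion is
layered by normalized ellipsoidal radius into three compartments:

* a hyperperfused rim (high CBF, the well-vascularised growing edge),
* a hypoperfused mantle (low CBF, the presumed hypoxic, radioresistant zone),
* an optional nonperfused (necrotic) core with CBF near zero.

Layering by normalized radius ``r`` means compartment volume fractions are
analytic: the mantle+core occupies exactly ``mantle_fraction**3`` of the
tumor volume, so segmentation recovery can be checked against closed forms.

The default compartment CBF levels are configurable stand-ins — plausible
ml/100g/min magnitudes chosen so the mantle sits well below one quarter of
the rim value — not measured values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .grids import ImageGrid, PerfusionMap, StructureMask, StructureSet

__all__ = [
    "PhantomSpec",
    "default_oar_layout",
    "generate_phantom",
    "sample_cohort",
    "ellipsoid_volume_cc",
]

#: Canonical OAR atlas: name -> (offset from brain center in mm, semiaxes mm).
#: x is left(-)/right(+), y is anterior(-)/posterior(+), z inferior(-)/superior(+).
#: Lenses are embedded in the anterior pole of the eyes; optic nerves are
#: elongated ellipsoids running posteriorly from the eyes; the brainstem is a
#: long midline ellipsoid reaching inferiorly. Only Dmax sampling is needed
#: downstream, so anatomical fidelity beyond plausible offsets is not a goal.
_DEFAULT_OAR_LAYOUT: dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]] = {
    "eye_l": ((-31.0, -82.0, -32.0), (12.0, 12.0, 12.0)),
    "eye_r": ((31.0, -82.0, -32.0), (12.0, 12.0, 12.0)),
    "lens_l": ((-31.0, -92.0, -32.0), (4.5, 2.5, 4.5)),
    "lens_r": ((31.0, -92.0, -32.0), (4.5, 2.5, 4.5)),
    "optic_nerve_l": ((-22.0, -58.0, -32.0), (3.5, 18.0, 3.5)),
    "optic_nerve_r": ((22.0, -58.0, -32.0), (3.5, 18.0, 3.5)),
    "brainstem": ((0.0, 8.0, -42.0), (10.0, 12.0, 38.0)),
}


def default_oar_layout() -> dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]]:
    """Return a copy of the canonical OAR ellipsoid atlas."""
    return {k: (tuple(v[0]), tuple(v[1])) for k, v in _DEFAULT_OAR_LAYOUT.items()}


def _default_grid() -> ImageGrid:
    # Emulates the MR matrix (256x256 in-plane at ~1 mm) with 3 mm slices.
    return ImageGrid(shape=(256, 256, 64), spacing_mm=(1.0, 1.0, 3.0))


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic head phantom.

    ``core_fraction`` and ``mantle_fraction`` are radial fractions of the
    normalized tumor radius: voxels with r < core_fraction are nonperfused,
    core_fraction <= r < mantle_fraction are hypoperfused mantle, and
    r >= mantle_fraction are the hyperperfused rim. CBF levels are in
    ml/100g/min.
    """

    seed: int = 0
    grid: ImageGrid = field(default_factory=_default_grid)
    brain_semiaxes_mm: tuple[float, float, float] = (75.0, 90.0, 70.0)
    brain_center_mm: tuple[float, float, float] | None = None
    tumor_center_mm: tuple[float, float, float] | None = None
    tumor_semiaxes_mm: tuple[float, float, float] = (20.0, 15.0, 10.0)
    core_fraction: float = 0.28
    mantle_fraction: float = 0.79
    cbf_rim: float = 80.0
    cbf_mantle: float = 12.0
    cbf_core: float = 0.0
    cbf_brain_background: float = 20.0
    noise_sd: float = 4.0
    oar_layout: dict = field(default_factory=default_oar_layout)

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.tumor_semiaxes_mm):
            raise ValueError(f"tumor semiaxes must be positive: {self.tumor_semiaxes_mm}")
        if any(a <= 0 for a in self.brain_semiaxes_mm):
            raise ValueError(f"brain semiaxes must be positive: {self.brain_semiaxes_mm}")
        if not 0.0 <= self.core_fraction < 1.0:
            raise ValueError("core_fraction must be in [0, 1)")
        if not self.core_fraction < self.mantle_fraction <= 1.0:
            raise ValueError("mantle_fraction must be in (core_fraction, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if min(self.cbf_rim, self.cbf_mantle, self.cbf_core, self.cbf_brain_background) < 0:
            raise ValueError("CBF levels must be nonnegative")
        if self.cbf_rim <= 4 * self.cbf_mantle:
            raise ValueError(
                "cbf_rim must exceed 4 x cbf_mantle so the mantle falls below the "
                "quarter-of-maximum threshold in the noise-free case "
                f"(got rim={self.cbf_rim}, mantle={self.cbf_mantle})"
            )

    @property
    def analytic_gtv_volume_cc(self) -> float:
        return ellipsoid_volume_cc(self.tumor_semiaxes_mm)

    @property
    def analytic_hypoperfused_fraction(self) -> float:
        """Volume fraction of GTV below the rim (mantle + core), exact for the
        ellipsoid-aligned layering."""
        return self.mantle_fraction**3

    def resolved_brain_center(self) -> tuple[float, float, float]:
        if self.brain_center_mm is not None:
            return tuple(float(v) for v in self.brain_center_mm)
        cx, cy, cz = self.grid.center_mm()
        # brain sits slightly superior so inferior OARs stay on the grid
        return (cx, cy, cz + 0.08 * self.grid.extent_mm()[2])

    def resolved_tumor_center(self) -> tuple[float, float, float]:
        if self.tumor_center_mm is not None:
            return tuple(float(v) for v in self.tumor_center_mm)
        bc = self.resolved_brain_center()
        # default lesion: posterior-superior, off-midline
        return (bc[0] + 22.0, bc[1] + 28.0, bc[2] + 14.0)


def ellipsoid_volume_cc(semiaxes_mm) -> float:
    a, b, c = semiaxes_mm
    return 4.0 / 3.0 * math.pi * a * b * c / 1000.0


def _normalized_radius(
    coords: tuple[np.ndarray, np.ndarray, np.ndarray],
    center: tuple[float, float, float],
    semiaxes: tuple[float, float, float],
) -> np.ndarray:
    q = np.zeros(coords[0].shape, dtype=np.float64)
    for x, c, a in zip(coords, center, semiaxes):
        q += ((x - c) / a) ** 2
    return np.sqrt(q)


def _ellipsoid_mask(grid, coords, name, center, semiaxes) -> StructureMask:
    return StructureMask(grid, name, _normalized_radius(coords, center, semiaxes) <= 1.0)


def _tumor_inside_brain(
    tumor_center, tumor_semiaxes, brain_center, brain_semiaxes, n_dirs: int = 146
) -> bool:
    """Check containment by sampling tumor-surface points (Fibonacci sphere)."""
    i = np.arange(n_dirs)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n_dirs
    r = np.sqrt(1.0 - z**2)
    dirs = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    surface = np.asarray(tumor_center) + dirs * np.asarray(tumor_semiaxes)
    q = np.sum(((surface - np.asarray(brain_center)) / np.asarray(brain_semiaxes)) ** 2, axis=1)
    return bool(np.all(q <= 1.0))


def generate_phantom(spec: PhantomSpec) -> tuple[PerfusionMap, StructureSet]:
    """Generate a CBF map and structure set (brain, GTV, OARs) from a spec.

    Deterministic: identical spec (including seed) yields bit-identical
    output. Raises ``ValueError`` if the tumor extends outside the grid or
    outside the brain ellipsoid.
    """
    grid = spec.grid
    brain_center = spec.resolved_brain_center()
    tumor_center = spec.resolved_tumor_center()

    # geometric validation in physical coordinates
    lo = np.asarray(grid.origin_mm)
    hi = lo + np.asarray(grid.extent_mm())
    t_lo = np.asarray(tumor_center) - np.asarray(spec.tumor_semiaxes_mm)
    t_hi = np.asarray(tumor_center) + np.asarray(spec.tumor_semiaxes_mm)
    if np.any(t_lo < lo) or np.any(t_hi > hi):
        raise ValueError(
            f"tumor ellipsoid (center {tumor_center}, semiaxes "
            f"{spec.tumor_semiaxes_mm}) extends outside the grid"
        )
    if not _tumor_inside_brain(
        tumor_center, spec.tumor_semiaxes_mm, brain_center, spec.brain_semiaxes_mm
    ):
        raise ValueError("tumor ellipsoid is not fully inside the brain ellipsoid")

    coords = grid.coordinates_mm()
    structures = StructureSet(grid)

    brain = _ellipsoid_mask(grid, coords, "brain", brain_center, spec.brain_semiaxes_mm)
    structures.add(brain)

    r_tumor = _normalized_radius(coords, tumor_center, spec.tumor_semiaxes_mm)
    gtv = StructureMask(grid, "gtv", r_tumor <= 1.0)
    if gtv.is_empty():
        raise ValueError("tumor ellipsoid contains no voxel centers")
    structures.add(gtv)

    for name, (offset, semiaxes) in spec.oar_layout.items():
        center = tuple(brain_center[i] + offset[i] for i in range(3))
        oar = _ellipsoid_mask(grid, coords, name, center, semiaxes)
        if (oar.member & gtv.member).any():
            warnings.warn(f"OAR {name!r} overlaps the GTV in this layout", stacklevel=2)
        structures.add(oar)

    cbf = np.zeros(grid.shape, dtype=np.float64)
    cbf[brain.member] = spec.cbf_brain_background
    inside = gtv.member
    cbf[inside & (r_tumor >= spec.mantle_fraction)] = spec.cbf_rim
    cbf[inside & (r_tumor < spec.mantle_fraction)] = spec.cbf_mantle
    cbf[inside & (r_tumor < spec.core_fraction)] = spec.cbf_core

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        cbf = cbf + rng.normal(0.0, spec.noise_sd, size=grid.shape)
    cbf = np.clip(cbf, 0.0, None)

    return PerfusionMap(grid, cbf), structures


def sample_cohort(
    n: int,
    seed: int,
    volume_range_cc: tuple[float, float] = (8.4, 118.0),
    hypo_fraction_mean: float = 0.493,
    hypo_fraction_sd: float = 0.06,
    grid: ImageGrid | None = None,
    **spec_overrides,
) -> list[PhantomSpec]:
    """Draw ``n`` reproducible phantom specs emulating a patient cohort.

    Tumor volumes are sampled log-uniformly within ``volume_range_cc`` (the
    right-skewed draw puts the cohort mean well below the range midpoint, as
    observed for real metastasis cohorts). The hypoperfused fraction of each
    GTV is drawn around ``hypo_fraction_mean`` and converted to the radial
    mantle fraction via the cube root.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    low, high = volume_range_cc
    if not 0 < low < high:
        raise ValueError(f"volume range must satisfy 0 < low < high, got {volume_range_cc}")

    base_grid = grid if grid is not None else _default_grid()
    rng = np.random.default_rng(seed)
    specs: list[PhantomSpec] = []
    for _ in range(n):
        subject_seed = int(rng.integers(0, 2**31 - 1))
        vol_cc = float(np.exp(rng.uniform(np.log(low), np.log(high))))
        q2, q3 = rng.uniform(0.6, 1.0, size=2)
        a = (3.0 * vol_cc * 1000.0 / (4.0 * math.pi * q2 * q3)) ** (1.0 / 3.0)
        semiaxes = (a, q2 * a, q3 * a)

        hypo_frac = float(np.clip(rng.normal(hypo_fraction_mean, hypo_fraction_sd), 0.15, 0.85))
        mantle = hypo_frac ** (1.0 / 3.0)
        core = float(rng.uniform(0.25, 0.45)) * mantle

        spec = PhantomSpec(
            seed=subject_seed,
            grid=base_grid,
            core_fraction=core,
            mantle_fraction=mantle,
            tumor_semiaxes_mm=semiaxes,
            **spec_overrides,
        )
        brain_center = np.asarray(spec.resolved_brain_center())
        brain_semiaxes = np.asarray(spec.brain_semiaxes_mm)
        grid_lo = np.asarray(base_grid.origin_mm)
        grid_hi = grid_lo + np.asarray(base_grid.extent_mm())
        semi = np.asarray(semiaxes)

        def _fits(center_arr: np.ndarray) -> bool:
            in_grid = np.all(center_arr - semi >= grid_lo) and np.all(
                center_arr + semi <= grid_hi
            )
            return in_grid and _tumor_inside_brain(
                tuple(center_arr), semiaxes, tuple(brain_center), tuple(brain_semiaxes)
            )

        offset = rng.uniform(-0.35, 0.35, size=3) * brain_semiaxes
        # shrink the offset toward the brain center until the tumor fits
        for _ in range(40):
            center = tuple(brain_center + offset)
            if _fits(brain_center + offset):
                break
            offset *= 0.8
        else:
            center = tuple(brain_center)
        specs.append(replace(spec, tumor_center_mm=tuple(float(v) for v in center)))
    return specs
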