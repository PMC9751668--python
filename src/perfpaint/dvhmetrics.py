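"""Dose-volume histograms and plan-quality indices.

Implements the evaluation layer: differential/cumulative DVHs, the
descending-sort dose-at-volume convention for D2%/D50%/D98%, target
coverage, the Paddick-style conformity index

    CI = (V_t,ref / V_t) x (V_t,ref / V_ref),

and the index of achievement

    IOA = 1 + sum_K sum_j [ ((D_j - D_K,RX) / D_K,RX)^2
                            x dDVH_PTV(K)(D_j) / V_PTV(K) ],

the volume-weighted mean squared relative deviation of planned dose from
prescription over each assigned target (1 is ideal; larger is worse).

Conventions that matter and are therefore explicit:

* Dx% uses the descending-sort rank ceil(x/100 * N) with no interpolation,
  so values are exactly testable; an interpolation option is not offered.
* The index reported as ``d_mean`` is the volume-weighted arithmetic mean;
  the median dose is reported separately as ``d50``. (Clinical reports
  sometimes conflate the two.)
* V_ref for the conformity index is evaluated within a stated evaluation
  region (typically the brain/body mask) so background air cannot inflate
  conformity; pass ``region=None`` to use the whole grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import DoseGrid, StructureMask

__all__ = [
    "DVHCurve",
    "compute_dvh",
    "dose_at_volume",
    "mean_dose",
    "target_coverage",
    "conformity_index",
    "index_of_achievement",
    "PrescriptionAssignment",
    "evaluate_structures",
]

DEFAULT_BIN_WIDTH_GY = 0.05


@dataclass
class DVHCurve:
    """Differential and cumulative dose-volume histogram for one structure.

    ``bin_edges_gy`` has length nbins+1 with uniform width;
    ``differential_cc`` is the absolute volume in each bin and sums to the
    structure volume; ``cumulative_fraction`` gives, at each edge, the
    fraction of the structure receiving at least that dose (1 at 0 Gy,
    monotone non-increasing).
    """

    structure: str
    bin_edges_gy: np.ndarray
    differential_cc: np.ndarray
    cumulative_fraction: np.ndarray

    @property
    def bin_centers_gy(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_gy[:-1] + self.bin_edges_gy[1:])

    @property
    def total_volume_cc(self) -> float:
        return float(self.differential_cc.sum())


def _masked_doses(dose: DoseGrid, mask: StructureMask) -> np.ndarray:
    if dose.grid != mask.grid:
        raise ValueError(f"dose and mask {mask.name!r} are on different grids")
    if mask.is_empty():
        raise ValueError(f"structure {mask.name!r} is empty")
    return dose.dose[mask.member]


def compute_dvh(
    dose: DoseGrid, mask: StructureMask, bin_width_gy: float = DEFAULT_BIN_WIDTH_GY
) -> DVHCurve:
    """Differential DVH (voxel-volume weighted) plus its cumulative curve."""
    if bin_width_gy <= 0:
        raise ValueError("bin width must be positive")
    doses = _masked_doses(dose, mask)
    vox_cc = mask.grid.voxel_volume_cc
    nbins = max(int(np.ceil((doses.max() + 1e-12) / bin_width_gy)), 1)
    edges = np.arange(nbins + 1) * bin_width_gy
    counts, _ = np.histogram(doses, bins=edges)
    differential = counts.astype(np.float64) * vox_cc
    total = differential.sum()
    # cumulative at edge e = fraction receiving >= e; right-closed bins mean
    # volume in bin j (edges[j], edges[j+1]] counts for all edges <= edges[j]
    tail = np.concatenate([np.cumsum(differential[::-1])[::-1], [0.0]])
    cumulative = tail / total
    cumulative[0] = 1.0
    return DVHCurve(mask.name, edges, differential, cumulative)


def dose_at_volume(doses_or_dose, mask_or_p, p: float | None = None) -> float:
    """Dose Dp% received by at least p% of the structure volume.

    Convention: sort voxel doses descending and take rank ceil(p/100 * N)
    (1-based); no interpolation. Accepts either (DoseGrid, StructureMask, p)
    or (array of voxel doses, p).
    """
    if p is None:
        doses = np.asarray(doses_or_dose, dtype=np.float64).ravel()
        p = float(mask_or_p)
    else:
        doses = _masked_doses(doses_or_dose, mask_or_p)
    if doses.size == 0:
        raise ValueError("empty structure has no dose-at-volume")
    if not 0.0 < p < 100.0:
        raise ValueError("p must be in (0, 100)")
    ordered = np.sort(doses)[::-1]
    rank = int(np.ceil(p / 100.0 * ordered.size))
    rank = min(max(rank, 1), ordered.size)
    return float(ordered[rank - 1])


def mean_dose(dose: DoseGrid, mask: StructureMask) -> float:
    """Volume-weighted arithmetic mean dose over the structure."""
    return float(_masked_doses(dose, mask).mean())


def target_coverage(
    dose: DoseGrid, mask: StructureMask, rx_gy: float, level_fraction: float = 1.0
) -> float:
    """Percent of the structure volume receiving >= level_fraction x rx."""
    if rx_gy <= 0:
        raise ValueError("prescription must be positive")
    doses = _masked_doses(dose, mask)
    return 100.0 * float(np.count_nonzero(doses >= level_fraction * rx_gy)) / doses.size


def conformity_index(
    dose: DoseGrid,
    target: StructureMask,
    rx_gy: float,
    region: StructureMask | None = None,
) -> float:
    """Conformity index (V_t,ref / V_t) x (V_t,ref / V_ref) in [0, 1].

    V_ref is the total volume receiving >= rx within ``region`` (the
    evaluation region, e.g. the brain); 0 when the prescription isodose is
    empty, 1 iff the isodose coincides with the target voxel-for-voxel.
    """
    if rx_gy <= 0:
        raise ValueError("prescription must be positive")
    if target.is_empty():
        raise ValueError("target is empty")
    if dose.grid != target.grid:
        raise ValueError("dose and target are on different grids")
    isodose = dose.dose >= rx_gy
    if region is not None:
        if region.grid != dose.grid:
            raise ValueError("evaluation region is on a different grid")
        isodose = isodose & region.member
    v_ref = int(isodose.sum())
    if v_ref == 0:
        return 0.0
    v_t = target.voxel_count
    v_t_ref = int((isodose & target.member).sum())
    return (v_t_ref / v_t) * (v_t_ref / v_ref)


@dataclass(frozen=True)
class PrescriptionAssignment:
    """Ordered (target mask, prescription Gy) pairs for a multi-target index."""

    items: tuple

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("assignment must contain at least one target")
        for mask, rx in self.items:
            if rx <= 0:
                raise ValueError("prescriptions must be positive")
            if mask.is_empty():
                raise ValueError(f"assigned target {mask.name!r} is empty")


def index_of_achievement(
    dose: DoseGrid,
    assignment: PrescriptionAssignment | list[tuple[StructureMask, float]],
    bin_width_gy: float = DEFAULT_BIN_WIDTH_GY,
) -> float:
    """Index of achievement over one or more prescribed targets (>= 1).

    Computed from the differential DVH of each target with doses taken at
    bin centers; as the bin width shrinks this converges to the voxel-wise
    volume-weighted mean squared relative deviation. The single-target case
    is the per-structure index clinical tables report.
    """
    if not isinstance(assignment, PrescriptionAssignment):
        assignment = PrescriptionAssignment(tuple(assignment))
    total = 0.0
    for mask, rx in assignment.items:
        curve = compute_dvh(dose, mask, bin_width_gy)
        centers = curve.bin_centers_gy
        rel_sq = ((centers - rx) / rx) ** 2
        total += float(np.sum(rel_sq * curve.differential_cc) / curve.total_volume_cc)
    return 1.0 + total


def evaluate_structures(
    dose: DoseGrid,
    targets_rx: dict[str, tuple[StructureMask, float]],
    region: StructureMask | None = None,
    bin_width_gy: float = DEFAULT_BIN_WIDTH_GY,
    coverage_level_fraction: float = 1.0,
) -> dict[str, dict[str, float]]:
    """Per-target metric block: D2/D98/D50/Dmean, coverage, CI, IOA.

    ``targets_rx`` maps structure name to (mask, prescription Gy); ``region``
    is the conformity evaluation region. Returns a nested dict keyed by
    structure name, values keyed by metric name.
    """
    out: dict[str, dict[str, float]] = {}
    for name, (mask, rx) in targets_rx.items():
        if mask.is_empty():
            continue
        doses = _masked_doses(dose, mask)
        out[name] = {
            "d2": dose_at_volume(doses, 2.0),
            "d50": dose_at_volume(doses, 50.0),
            "d98": dose_at_volume(doses, 98.0),
            "d_mean": float(doses.mean()),
            "coverage_pct": target_coverage(dose, mask, rx, coverage_level_fraction),
            "ci": conformity_index(dose, mask, rx, region=region),
            "ioa": index_of_achievement(dose, [(mask, rx)], bin_width_gy),
            "volume_cc": mask.volume_cc,
        }
    return out
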