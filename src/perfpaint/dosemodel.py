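"""Synthetic dose-distribution surrogate for the treatment planning system.

This module deliberately replaces inverse-optimized IMRT/SIB dose calculation
with a transparent surrogate: it builds an objective dose map from the
per-target prescriptions, applies a Gaussian penumbra in physical
millimetres, optionally perturbs the boost volume with seeded hotspots,
renormalizes each target so its prescription covers the configured volume
fraction, and finally soft-clamps the global maximum when the plan carries a
maximum-dose constraint. The resulting grids carry the prescription, cap and
coverage structure of real SIB plans — which is all the downstream DVH
metrics and cohort statistics consume — without any claim to fluence-level
realism.

The three built-in plan styles:

* plan1 — conventional: 60 Gy to PTV, Dmax capped at 66 Gy (110%).
* plan2 — dose painting: 60 Gy to PTV_N, 72 Gy boost to PTV_H, cap 79 Gy.
* plan3 — dose painting as plan2 but without the maximum-dose constraint
  (hotspots inside the boost volume survive).

All plans assume 2 Gy daily fractions; fraction size never enters the
surrogate but is recorded for reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import TargetSet
from .grids import DoseGrid, StructureMask

__all__ = [
    "PlanSpec",
    "OARConstraint",
    "DEFAULT_OAR_CONSTRAINTS",
    "default_plans",
    "simulate_plan_dose",
    "oar_dmax_report",
]


@dataclass(frozen=True)
class PlanSpec:
    """Prescription structure and surrogate-shaping parameters for one plan.

    prescriptions maps target names ('ptv', 'ptv_h', 'ptv_n') to Gy; where
    targets overlap the boost ('ptv_h') wins. ``dmax_cap_gy`` of None means
    an unconstrained plan. ``normalization_coverage`` is the volume fraction
    of each target that must receive at least its prescription after
    renormalization. ``hotspot_amplitude_gy`` adds seeded smooth
    perturbations inside the boost volume (used by the uncapped plan style).
    ``falloff_mm`` is the e-folding length of the background dose outside
    the PTV, so organs at risk receive distance-dependent low doses.
    """

    plan_id: str
    prescriptions: dict[str, float]
    dmax_cap_gy: float | None = None
    fraction_dose_gy: float = 2.0
    penumbra_sigma_mm: float = 3.0
    normalization_coverage: float = 0.95
    hotspot_amplitude_gy: float = 0.0
    falloff_mm: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.prescriptions:
            raise ValueError("plan must prescribe at least one target")
        if any(rx <= 0 for rx in self.prescriptions.values()):
            raise ValueError("prescriptions must be positive")
        if self.dmax_cap_gy is not None and self.dmax_cap_gy < max(self.prescriptions.values()):
            raise ValueError(
                f"plan {self.plan_id!r}: cap {self.dmax_cap_gy} Gy is below the highest "
                f"prescription {max(self.prescriptions.values())} Gy — the coverage goal "
                "cannot be met under this maximum-dose constraint"
            )
        if not 0.0 < self.normalization_coverage <= 1.0:
            raise ValueError("normalization_coverage must be in (0, 1]")
        if self.penumbra_sigma_mm < 0 or self.hotspot_amplitude_gy < 0:
            raise ValueError("penumbra sigma and hotspot amplitude must be >= 0")

    @property
    def max_prescription_gy(self) -> float:
        return max(self.prescriptions.values())


@dataclass(frozen=True)
class OARConstraint:
    """Maximum-dose limit for one organ at risk."""

    name: str
    dmax_limit_gy: float

    def __post_init__(self) -> None:
        if self.dmax_limit_gy <= 0:
            raise ValueError("Dmax limit must be positive")


#: Clinical OAR maximum-dose limits used for all three plan styles.
DEFAULT_OAR_CONSTRAINTS: tuple[OARConstraint, ...] = (
    OARConstraint("eye_l", 50.0),
    OARConstraint("eye_r", 50.0),
    OARConstraint("optic_nerve_l", 54.0),
    OARConstraint("optic_nerve_r", 54.0),
    OARConstraint("lens_l", 8.0),
    OARConstraint("lens_r", 8.0),
    OARConstraint("brainstem", 54.0),
)


def default_plans(seed: int = 0) -> dict[str, PlanSpec]:
    """The three built-in plan styles (conventional, capped boost, uncapped boost)."""
    return {
        "plan1": PlanSpec("plan1", {"ptv": 60.0}, dmax_cap_gy=66.0, seed=seed),
        "plan2": PlanSpec(
            "plan2", {"ptv_n": 60.0, "ptv_h": 72.0}, dmax_cap_gy=79.0, seed=seed
        ),
        "plan3": PlanSpec(
            "plan3",
            {"ptv_n": 60.0, "ptv_h": 72.0},
            dmax_cap_gy=None,
            hotspot_amplitude_gy=6.0,
            seed=seed,
        ),
    }


def _coverage_dose(dose: np.ndarray, mask: np.ndarray, coverage: float) -> float:
    """Dose received by at least ``coverage`` fraction of the masked voxels."""
    values = np.sort(dose[mask])[::-1]
    rank = int(np.ceil(coverage * values.size))
    rank = min(max(rank, 1), values.size)
    return float(values[rank - 1])


def _soft_clamp(dose: np.ndarray, cap: float, knee: float) -> np.ndarray:
    """Monotone compressive map: identity below ``knee``, asymptotic to ``cap``.

    Values above the knee are remapped to knee + (cap-knee)(1 - exp(-t)), so
    no output exceeds the cap while the ordering of doses is preserved and
    nothing at or below the knee (in particular prescription-level coverage)
    changes.
    """
    if cap <= knee:
        return np.minimum(dose, cap)
    over = dose > knee
    out = dose.copy()
    t = (dose[over] - knee) / (cap - knee)
    out[over] = knee + (cap - knee) * (1.0 - np.exp(-t))
    return out


def simulate_plan_dose(
    targets: TargetSet,
    brain: StructureMask,
    plan: PlanSpec,
    max_iter: int = 10,
) -> DoseGrid:
    """Produce a deterministic synthetic dose grid realizing a plan spec.

    Pipeline: objective map (per-target prescriptions, boost wins;
    exponential background falloff outside the PTV) -> anisotropic Gaussian
    penumbra blur -> optional seeded hotspots inside the boost volume ->
    per-target coverage renormalization (base targets to their prescription,
    then a local boost renormalization) -> soft clamp to the plan's maximum
    dose, iterating clamp/renormalize until the coverage goal holds (<=
    ``max_iter`` rounds, warns if not converged).
    """
    grid = targets.ptv.grid
    if brain.grid != grid:
        raise ValueError("brain mask and targets are on different grids")
    masks = targets.masks()
    for name in plan.prescriptions:
        if name not in masks:
            raise ValueError(f"plan prescribes unknown target {name!r}")
        if masks[name].is_empty() and name != "ptv_h":
            raise ValueError(f"prescribed target {name!r} is empty")

    spacing = np.asarray(grid.spacing_mm)
    base_rx = min(plan.prescriptions.values())

    # (1) objective map: prescription inside targets (boost wins), exponential
    # falloff with distance from the PTV surface outside
    objective = np.zeros(grid.shape, dtype=np.float64)
    dist_out = ndimage.distance_transform_edt(~targets.ptv.member, sampling=spacing)
    outside = ~targets.ptv.member
    objective[outside] = base_rx * np.exp(-dist_out[outside] / plan.falloff_mm)
    ordered = sorted(plan.prescriptions.items(), key=lambda kv: kv[1])  # boost last
    for name, rx in ordered:
        objective[masks[name].member] = rx

    # (2) penumbra blur in physical units
    if plan.penumbra_sigma_mm > 0:
        sigma_vox = plan.penumbra_sigma_mm / spacing
        dose = ndimage.gaussian_filter(objective, sigma=sigma_vox)
    else:
        dose = objective.copy()

    # (3) seeded hotspot perturbation inside the boost volume
    boost = masks.get("ptv_h")
    if (
        plan.hotspot_amplitude_gy > 0
        and boost is not None
        and not boost.is_empty()
    ):
        rng = np.random.default_rng(plan.seed)
        noise = rng.normal(0.0, 1.0, size=grid.shape)
        smooth = ndimage.gaussian_filter(noise, sigma=4.0 / spacing)
        smooth /= max(float(np.abs(smooth[boost.member]).max()), 1e-12)
        bump = np.zeros(grid.shape)
        # positive bumps only: hotspots, not cold spots
        bump[boost.member] = plan.hotspot_amplitude_gy * np.abs(smooth[boost.member])
        dose = dose + bump

    # (4)+(5) renormalize each target, then clamp; iterate to a fixed point.
    # The soft clamp is the identity at and below the highest prescription
    # (the knee), so prescription-level coverage survives capping and the
    # loop normally converges in one round.
    cap = plan.dmax_cap_gy
    knee = plan.max_prescription_gy
    base_name, base_rx_value = ordered[0]
    boost_items = [
        (name, rx)
        for name, rx in ordered[1:]
        if not masks[name].is_empty()
    ]
    feather = {}
    for name, _ in boost_items:
        soft = ndimage.gaussian_filter(
            masks[name].member.astype(np.float64), sigma=2.0 / spacing
        )
        feather[name] = soft / max(float(soft.max()), 1e-12)

    converged = False
    for _ in range(max_iter):
        # global affine rescale anchored on the lowest-prescription target
        d_cov = _coverage_dose(dose, masks[base_name].member, plan.normalization_coverage)
        if d_cov <= 0:
            raise ValueError(f"degenerate dose distribution over target {base_name!r}")
        dose = dose * (base_rx_value / d_cov)
        # local boost renormalization: lift with a smoothly feathered weight
        # (>= 1 everywhere, so base coverage is only ever raised); the
        # feather dilutes the lift at the boost edge, hence a short inner loop
        for name, rx in boost_items:
            for _ in range(30):
                d_cov = _coverage_dose(dose, masks[name].member, plan.normalization_coverage)
                if d_cov >= rx * (1.0 - 1e-12):
                    break
                scale = rx / d_cov
                dose = dose * (1.0 + (scale - 1.0) * feather[name])
        if cap is None:
            converged = True
            break
        dose = _soft_clamp(dose, cap, knee)
        ok = all(
            _coverage_dose(dose, masks[name].member, plan.normalization_coverage)
            >= rx * (1.0 - 1e-12)
            for name, rx in ordered
            if not masks[name].is_empty()
        )
        if ok:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"plan {plan.plan_id!r}: cap/coverage renormalization did not converge "
            f"in {max_iter} iterations",
            stacklevel=2,
        )

    return DoseGrid(grid, np.clip(dose, 0.0, None))


def oar_dmax_report(
    dose: DoseGrid,
    oars: list[StructureMask],
    constraints: tuple[OARConstraint, ...] | list[OARConstraint] = DEFAULT_OAR_CONSTRAINTS,
) -> list[dict]:
    """Maximum dose per organ at risk, compared against its limit.

    Empty OAR masks are reported with a missing (None) Dmax rather than 0 —
    an absent structure is not a spared structure.
    """
    limits = {c.name: c.dmax_limit_gy for c in constraints}
    report = []
    for oar in oars:
        if oar.grid != dose.grid:
            raise ValueError(f"OAR {oar.name!r} is on a different grid than the dose")
        limit = limits.get(oar.name)
        if oar.is_empty():
            report.append(
                {"name": oar.name, "dmax_gy": None, "limit_gy": limit, "passed": None}
            )
            continue
        dmax = float(dose.dose[oar.member].max())
        passed = None if limit is None else bool(dmax < limit)
        report.append(
            {"name": oar.name, "dmax_gy": dmax, "limit_gy": limit, "passed": passed}
        )
    return report
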