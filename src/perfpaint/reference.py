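"""Reference cohort summary values from a published 50-patient study.

These are the reported cohort means (and where relevant SDs) from a
published single-brain-metastasis dose-painting study using the same
60/72 Gy prescription structure this package simulates. They serve as
worked-example inputs for the ratio and increment-percentage operations —
the derived percentages (volume ratios, between-plan dose increments) are
recomputable exactly from these means — and as a plausibility anchor for the
synthetic cohort defaults. They are inputs, not outputs, of this package.
"""

from __future__ import annotations

from .cohort import increment_percent

__all__ = [
    "REFERENCE_VOLUMES_CC",
    "REFERENCE_DOSE_MEANS_GY",
    "REFERENCE_OAR_DMAX_GY",
    "REFERENCE_CI_PTV_H",
    "volume_ratios_percent",
    "dose_increments_percent",
    "oar_increments_percent",
]

#: Cohort mean structure volumes (cm^3); GTV range was 8.4-118.0 cm^3.
REFERENCE_VOLUMES_CC: dict[str, float] = {
    "gtv": 34.5,
    "gtv_h": 17.0,
    "ptv": 72.0,
    "ptv_h": 41.5,
    "ptv_n": 30.5,
}

#: Cohort mean D2% / D98% / Dmean (Gy) per target and plan.
REFERENCE_DOSE_MEANS_GY: dict[str, dict[str, dict[str, float]]] = {
    "ptv": {
        "d2": {"plan1": 64.42, "plan2": 77.42, "plan3": 79.91},
        "d98": {"plan1": 61.17, "plan2": 66.27, "plan3": 65.31},
        "d_mean": {"plan1": 63.29, "plan2": 74.92, "plan3": 74.05},
    },
    "ptv_h": {
        "d2": {"plan1": 64.38, "plan2": 77.58, "plan3": 80.40},
        "d98": {"plan1": 61.74, "plan2": 73.67, "plan3": 72.37},
        "d_mean": {"plan1": 63.43, "plan2": 75.86, "plan3": 75.62},
    },
    "ptv_n": {
        "d2": {"plan1": 64.39, "plan2": 76.50, "plan3": 77.07},
        "d98": {"plan1": 60.55, "plan2": 64.89, "plan3": 63.67},
        "d_mean": {"plan1": 63.05, "plan2": 72.07, "plan3": 70.49},
    },
}

#: Cohort mean OAR Dmax (Gy) per plan.
REFERENCE_OAR_DMAX_GY: dict[str, dict[str, float]] = {
    "eye_l": {"plan1": 8.74, "plan2": 8.97, "plan3": 8.98},
    "eye_r": {"plan1": 8.92, "plan2": 9.39, "plan3": 9.42},
    "optic_nerve_l": {"plan1": 8.36, "plan2": 8.62, "plan3": 8.67},
    "optic_nerve_r": {"plan1": 7.36, "plan2": 7.66, "plan3": 7.75},
    "lens_l": {"plan1": 2.31, "plan2": 2.37, "plan3": 2.40},
    "lens_r": {"plan1": 2.07, "plan2": 2.14, "plan3": 2.15},
    "brainstem": {"plan1": 18.68, "plan2": 19.09, "plan3": 19.14},
}

#: Cohort mean conformity index of the boost target per plan.
REFERENCE_CI_PTV_H: dict[str, float] = {"plan1": 0.44, "plan2": 0.64, "plan3": 0.72}


def volume_ratios_percent() -> dict[str, float]:
    """Structure volume ratios (%) recomputed from the reference means."""
    v = REFERENCE_VOLUMES_CC
    return {
        "gtv_h_over_gtv": 100.0 * v["gtv_h"] / v["gtv"],
        "ptv_h_over_ptv": 100.0 * v["ptv_h"] / v["ptv"],
        "ptv_n_over_ptv": 100.0 * v["ptv_n"] / v["ptv"],
    }


def dose_increments_percent() -> dict[str, float]:
    """Between-plan increments (%) of the target dose indices vs plan1."""
    out: dict[str, float] = {}
    for structure, metrics in REFERENCE_DOSE_MEANS_GY.items():
        for metric, per_plan in metrics.items():
            for plan in ("plan2", "plan3"):
                out[f"{structure}_{metric}_{plan}_vs_plan1"] = increment_percent(
                    per_plan["plan1"], per_plan[plan]
                )
    return out


def oar_increments_percent() -> dict[str, float]:
    """Between-plan increments (%) of OAR Dmax for all plan pairs."""
    out: dict[str, float] = {}
    pairs = (("plan1", "plan2"), ("plan1", "plan3"), ("plan2", "plan3"))
    for oar, per_plan in REFERENCE_OAR_DMAX_GY.items():
        for ref, cmp_ in pairs:
            out[f"{oar}_dmax_{cmp_}_vs_{ref}"] = increment_percent(
                per_plan[ref], per_plan[cmp_]
            )
    return out
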