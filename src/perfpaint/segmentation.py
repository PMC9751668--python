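"""Perfusion-based classification of GTV voxels and boost-subvolume extraction.

The boost subvolume (GTV_H) is the hypoperfused part of the tumor: voxels
whose CBF falls below a fixed fraction (default one quarter) of the maximum
CBF observed within the GTV. Voxels below a small absolute floor are called
nonperfused (necrotic); they are included in GTV_H by default because the
"less than 25% of maximum" rule subsumes them, but the three-way label map
keeps the distinction so the alternative is one flag away.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import PerfusionMap, StructureMask

__all__ = [
    "SegmentationConfig",
    "PerfusionLabelMap",
    "classify_perfusion",
    "extract_gtv_h",
    "LABEL_OUTSIDE",
    "LABEL_HYPER",
    "LABEL_HYPO",
    "LABEL_NON",
]

LABEL_OUTSIDE = 0
LABEL_HYPER = 1
LABEL_HYPO = 2
LABEL_NON = 3


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholding rules for the perfusion classification.

    threshold_fraction
        Fraction of the within-GTV maximum CBF separating hypo- from
        hyperperfused voxels (strict ``<``; ties at the threshold are hyper).
    necrosis_floor
        Absolute CBF (ml/100g/min) below which a voxel is nonperfused.
    include_nonperfused_in_gtv_h
        Whether necrotic voxels join the boost subvolume.
    max_percentile
        If None, the maximum estimator is the raw within-GTV maximum (the
        literal rule); otherwise an upper percentile (e.g. 99) is used as a
        noise-robust surrogate, since a single hot voxel can distort the
        threshold.
    """

    threshold_fraction: float = 0.25
    necrosis_floor: float = 1.0
    include_nonperfused_in_gtv_h: bool = True
    max_percentile: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold_fraction < 1.0:
            raise ValueError("threshold_fraction must be in (0, 1)")
        if self.necrosis_floor < 0:
            raise ValueError("necrosis_floor must be >= 0")
        if self.max_percentile is not None and not 0.0 < self.max_percentile <= 100.0:
            raise ValueError("max_percentile must be in (0, 100]")


@dataclass
class PerfusionLabelMap:
    """Per-voxel perfusion labels over the GTV.

    ``labels`` holds LABEL_OUTSIDE outside the GTV and exactly one of
    {hyper, hypo, non} for each GTV voxel. ``max_cbf`` and ``threshold_cbf``
    record the maximum estimate and the absolute threshold used.
    """

    gtv: StructureMask
    labels: np.ndarray
    max_cbf: float
    threshold_cbf: float

    def __post_init__(self) -> None:
        if self.labels.shape != self.gtv.grid.shape:
            raise ValueError("label array shape does not match grid")
        inside = self.labels != LABEL_OUTSIDE
        if not np.array_equal(inside, self.gtv.member):
            raise ValueError("labels do not partition the GTV mask exactly")

    def mask_for(self, label: int, name: str) -> StructureMask:
        return StructureMask(self.gtv.grid, name, self.labels == label)

    def counts(self) -> dict[str, int]:
        return {
            "hyper": int(np.count_nonzero(self.labels == LABEL_HYPER)),
            "hypo": int(np.count_nonzero(self.labels == LABEL_HYPO)),
            "non": int(np.count_nonzero(self.labels == LABEL_NON)),
        }


def classify_perfusion(
    cbf: PerfusionMap,
    gtv: StructureMask,
    cfg: SegmentationConfig | None = None,
) -> PerfusionLabelMap:
    """Label each GTV voxel hyper-, hypo- or nonperfused.

    Let M be the maximum estimate of CBF over the GTV and
    T = threshold_fraction x M. A voxel is nonperfused if CBF <
    necrosis_floor, hypoperfused if necrosis_floor <= CBF < T, hyperperfused
    if CBF >= T. The three labels partition the GTV exactly, and the
    segmentation is invariant to positive rescaling of the CBF map as long
    as the necrosis floor is scaled along (the threshold is relative).
    """
    cfg = cfg or SegmentationConfig()
    if cbf.grid != gtv.grid:
        raise ValueError("CBF map and GTV mask are on different grids")
    if gtv.is_empty():
        raise ValueError("GTV mask is empty")

    values = cbf.cbf[gtv.member].astype(np.float64)
    if cfg.max_percentile is None:
        max_cbf = float(values.max())
    else:
        max_cbf = float(np.percentile(values, cfg.max_percentile))
    if max_cbf <= 0:
        raise ValueError("maximum CBF within GTV is not positive; no meaningful threshold")
    threshold = cfg.threshold_fraction * max_cbf

    labels = np.full(gtv.grid.shape, LABEL_OUTSIDE, dtype=np.uint8)
    inside = gtv.member
    v = cbf.cbf
    labels[inside] = LABEL_HYPER
    labels[inside & (v < threshold)] = LABEL_HYPO
    labels[inside & (v < cfg.necrosis_floor)] = LABEL_NON
    return PerfusionLabelMap(gtv=gtv, labels=labels, max_cbf=max_cbf, threshold_cbf=threshold)


def extract_gtv_h(
    labels: PerfusionLabelMap,
    cfg: SegmentationConfig | None = None,
    name: str = "gtv_h",
) -> StructureMask:
    """Extract the boost subvolume from a perfusion label map.

    GTV_H is the hypoperfused voxels, plus the nonperfused ones when
    ``include_nonperfused_in_gtv_h`` is set; always a subset of the GTV.
    """
    cfg = cfg or SegmentationConfig()
    member = labels.labels == LABEL_HYPO
    if cfg.include_nonperfused_in_gtv_h:
        member = member | (labels.labels == LABEL_NON)
    return StructureMask(labels.gtv.grid, name, member)
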