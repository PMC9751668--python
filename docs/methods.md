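# Methods

`perfpaint` models the perfusion-guided dose-painting workflow for single
brain metastases end to end on synthetic data. This note records the models,
the parameters that matter, the numerical conventions, and the limits of
what the synthetic pipeline can and cannot demonstrate.

## Phantom model

A phantom is an axis-aligned ellipsoidal brain containing one axis-aligned
ellipsoidal tumor (GTV) plus a fixed atlas of ellipsoidal organs at risk
(two eyes with embedded lenses, two elongated optic-nerve ellipsoids, one
brainstem), all voxelized on a shared grid. The default grid is 256×256×64
voxels at (1, 1, 3) mm — in-plane resolution and slice thickness typical of
the 3D-ASL acquisitions this workflow targets — and every component accepts
any other grid.

Perfusion inside the GTV is layered by the **normalized ellipsoidal radius**
r ∈ [0, 1] (ellipsoid-aligned, not Euclidean): nonperfused core for
r < `core_fraction`, hypoperfused mantle for r < `mantle_fraction`,
hyperperfused rim outside. Because sub-ellipsoid volume scales with r³, the
hypoperfused-plus-core volume fraction is exactly `mantle_fraction`³, which
makes segmentation recovery testable against a closed form (recovered within
±2 % of GTV volume on the default grids, the residual being voxelization).

Compartment CBF levels are configurable stand-ins, not measured values:
rim 80, mantle 12, core 0, brain background 20 ml/100g/min, additive
Gaussian noise with SD 4 clipped at zero (CBF is nonnegative). The rim level
must exceed four times the mantle level so that, noise-free, the mantle sits
below the quarter-of-maximum threshold; the constructor enforces this.

Cohort sampling draws tumor volumes **log-uniformly** over 8.4–118 cm³ —
the right-skewed draw reproduces the observation that the mean metastasis
volume (~34.5 cm³) lies well below the midpoint of the clinical range — with
axis ratios uniform in [0.6, 1], a random intracranial position (shrunk
toward the brain center until the tumor fits the brain ellipsoid and the
grid), and a per-subject hypoperfused fraction drawn around 49.3 % (SD 0.06,
clipped to [0.15, 0.85]) and converted to the radial mantle fraction by cube
root. All sampling is driven by one `numpy` generator seeded from the cohort
seed, so cohorts are bit-for-bit reproducible.

## Segmentation

The boost subvolume GTV_H is every GTV voxel with CBF strictly below
`threshold_fraction` (default 0.25) of the within-GTV maximum. Voxels below
an absolute `necrosis_floor` (default 1 ml/100g/min) are labelled
nonperfused and are included in GTV_H by default, since "below 25 % of
maximum" subsumes them; the three-way label map keeps the distinction and a
flag excludes them. Ties at exactly the threshold are hyperperfused (strict
`<`). The maximum estimator defaults to the raw within-GTV maximum — the
literal clinical rule — with an optional upper-percentile surrogate because
a single noisy voxel can otherwise distort the threshold. The segmentation
is scale-invariant (the threshold is relative) provided the absolute
necrosis floor is scaled with the map.

## Margin expansion

Margins are physical: an output voxel is a member iff its center lies within
Euclidean distance ≤ margin of some input voxel center, with anisotropic
spacing respected. Production uses `scipy.ndimage.distance_transform_edt`
with the grid spacing as `sampling`; the test suite proves it equal to a
brute-force all-pairs distance oracle on grids up to 32³. An inclusive
boundary (with a 1 ns-scale epsilon against floating-point error in the
transform) makes the single-voxel cases exactly enumerable — a 3 mm margin
around one voxel on a (1, 1, 3) mm grid yields exactly 31 voxels. PTV
(GTV + 5 mm) and PTV_H (GTV_H + 3 mm) are clipped to the brain mask by
default (standard planning practice; a flag disables it), and
PTV_N = PTV \ PTV_H holds as a voxel-level set identity. Note that margins
grow from voxel centers of the *voxelized* mask, so coarse grids
under-dilate slightly relative to the continuous dilation (≈7 % volume at
1 mm in-plane for a 12.6 cm³ tumor, more at 2 mm).

## Dose surrogate

The dose model is a deliberately transparent substitute for inverse-planned
IMRT/SIB dose calculation. Pipeline per plan:

1. **Objective map** — each voxel takes its enclosing target's prescription
   (the 72 Gy boost wins over 60 Gy); outside the PTV the dose decays as
   exp(−d/`falloff_mm`) of the distance to the PTV surface (default
   12 mm), so OARs receive distance-dependent low doses.
2. **Penumbra** — Gaussian blur with `penumbra_sigma_mm` (default 3 mm),
   anisotropy-aware.
3. **Hotspots** — for the uncapped plan style, seeded smooth positive
   perturbations (default amplitude 6 Gy) inside the boost volume.
4. **Normalization** — a global affine rescale pins the base target's
   `normalization_coverage` (default 0.95) quantile to its prescription;
   the boost target is then lifted locally with a smoothly feathered weight
   ≥ 1 (2 mm feather), iterated a few times because the feather dilutes the
   lift at the boost edge. Lifting never lowers any voxel, so base coverage
   is preserved.
5. **Cap** — a monotone compressive map that is the identity at and below
   the highest prescription (the knee) and asymptotes to the cap, so no
   voxel ever exceeds 66 Gy (plan1) / 79 Gy (plan2) while
   prescription-level coverage is untouched; the cap/renormalize loop
   therefore converges in one round and a warning is raised if it does not
   within ten.

The default prescription/cap structure: plan1 = 60 Gy to PTV, cap 66 Gy;
plan2 = 60 Gy to PTV_N + 72 Gy to PTV_H, cap 79 Gy; plan3 = plan2 without a
cap and with hotspots. Caps are 110 % of the highest prescription. All plans
nominally deliver 2 Gy fractions (recorded, never used numerically). The
surrogate makes no claim to fluence-level realism; every downstream metric
is agnostic to it, and conclusions about *absolute* dosimetric values carry
no clinical weight. What the surrogate does guarantee — caps exact, coverage
at or above the configured level, strictly higher boost dose under dose
painting — is exactly what the metric layer verifies. (Clinical reports in
this workflow sometimes normalize to 95 % coverage yet report ≥ 98–99 %
achieved; the knob is exposed rather than the inconsistency resolved.)

## Metrics

* **Dx%** — descending-sort rank convention, rank = ceil(x/100 · N), no
  interpolation: exactly testable (100 voxels at 1..100 Gy give D2% = 99,
  D98% = 3).
* **Dmean** — the volume-weighted arithmetic mean. Clinical summaries
  occasionally define the "mean" as the dose to 50 % of the volume (the
  median); both are computed and reported under distinct names (`d_mean`,
  `d50`).
* **DVH** — uniform differential bins (default 0.05 Gy) weighted by voxel
  volume; differential volumes sum to the structure volume exactly and the
  cumulative curve is monotone non-increasing from 1 at 0 Gy.
* **CI** — (V_t,ref/V_t)·(V_t,ref/V_ref) with V_ref evaluated inside a
  stated evaluation region (the brain by default) so background air cannot
  inflate conformity; CI ∈ [0, 1] with 1 iff the isodose matches the target
  voxel-for-voxel.
* **IOA** — computed from the differential DVH at bin centers; at 0.05 Gy
  bins it agrees with the voxel-wise (unbinned) oracle to < 10⁻³, and
  equals 1 iff the dose equals the prescription over every assigned target.
  Per-structure values (the K = 1 case) are what cohort tables report; under
  the conventional plan the boost structure is evaluated against the 60 Gy
  base prescription, since no boost is prescribed there (the choice is
  configurable).

## Cohort statistics

Summaries are mean ± sample SD (n − 1). Increment percentages are computed
on plan means — matching how published increments are derived from summary
tables — with a per-subject mode available. Plans are compared with one-way
ANOVA (hand-computed sums of squares so the all-constant degenerate case
takes an explicit F = 0, p = 1 branch; cross-checked against
`scipy.stats.f_oneway`) and LSD pairwise t tests on the pooled within-group
mean square with N − k degrees of freedom. The ANOVA treats plans as
independent groups even though the three plans share subjects; this mirrors
common clinical reporting but discards the pairing, so its p values are
conservative for strongly correlated metrics.

## Problem sizes and reproducibility

The acceptance script and the end-to-end tests run cohorts on a 128×128×48
grid at (2, 2, 3) mm — the same physical head extent as the
acquisition-scale default at one quarter the voxel count — with 3–10
subjects; one subject (phantom, segmentation, targets, three plans, full
metrics) takes about one second. Every stage is deterministic given the
seed; rerunning a configuration reproduces all CSV outputs byte-for-byte,
and the manifest records seed, package version and a configuration hash.

## What passing tests do and do not show

The phantom reproduces the features the method depends on — a closed
perfusion hierarchy inside the GTV, realistic volume ranges, anisotropic
grids, OARs at plausible distances — but not ASL acquisition physics,
labeling-delay effects, lesion irregularity, multi-lesion disease, or
registration error between perfusion and anatomy. The dose surrogate
reproduces prescription/cap/coverage structure, not optimizer trade-offs:
conformity indices of a real optimizer differ systematically from the
surrogate's. Passing tests therefore validate the *analysis chain* —
segmentation rule, margin geometry, metric definitions, statistics — not
clinical plan quality. Derived quantities from the bundled reference tables
(volume ratios, increment percentages) are exact arithmetic and reproduce
the published values to the printed precision.

## Known limitations

* Ellipsoidal tumors and OARs only; no irregular shapes or rotations.
* The boost renormalization can overshoot coverage well above the
  configured 95 % (feathered lifting is conservative), which real optimizers
  would trade against OAR sparing.
* Masks are voxel sets; no sub-voxel (polygon/mesh) contour geometry.
* NIfTI with diagonal affines only; DICOM-RT import/export is out of scope.
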