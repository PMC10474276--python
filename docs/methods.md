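# Methods

`rcmorph` quantifies rotator-cuff (RC) muscle size, relative contribution and
fatty infiltration (FI) in three dimensions from segmentation label maps of
clinical shoulder MRI, which typically capture only the lateral portion of
the scapula.  This note records the model, the numerical choices, what the
synthetic phantoms do and do not emulate, and the known limitations.

## Coordinate convention and inputs

Inputs are 3D integer label maps (NIfTI-1) with up to eleven regions:
humerus, scapula, clavicle, and for each of the four RC muscles
(supraspinatus, infraspinatus, teres minor, subscapularis) a muscle label
plus a paired intramuscular-fat label.  Only fat inside the muscle boundary
is labeled as fat.  The first array axis is the sagittal slice axis; after
canonicalization slice index 0 is the most lateral captured slice and the
anatomy has right-shoulder chirality.  Left shoulders are mirrored across
the sagittal plane at read time so left and right scans pool into one
analysis; this mirroring is an involution and leaves all geometric measures
unchanged.  A resolution guard warns (without failing) when sagittal spacing
exceeds 6 mm or in-plane spacing exceeds 1 mm, the quality floor assumed by
the method.

## Predicting total scapula length from lateral morphology

Comparing scans of differing coverage requires a common axis: percent
location along the *total* scapula.  Because the medial scapula is usually
not captured, its total sagittal length L is predicted from four measures
taken at the slice of peak scapular cross-sectional area (CSA):

- PD — sagittal distance (mm) from the most lateral scapular point to the
  peak-CSA slice;
- PC — the peak CSA (mm²);
- VB, HB — vertical and horizontal extents (mm) of the tight axis-aligned
  bounding box of the scapula in that slice.

The peak is searched only within the lateral half of the *captured*
scapular extent.  A second CSA peak can exist medially; it is irrelevant at
clinical coverage and is deliberately ignored.  Ties break to the most
lateral slice, which is deterministic and biases PD consistently downward.
Whether "first half" should refer to the captured extent or the (unknown)
full length is genuinely open; the captured extent is the only quantity
available at measurement time, so it is used.

L is fit by ordinary least squares with intercept on (PD, PC, VB, HB).  All
four predictors are retained in the deployed model even when only PD and PC
are individually significant; a restricted PD+PC model is available through
the `predictors` switch for sensitivity analysis.  Diagnostics (multiple r,
per-coefficient t and p, Shapiro–Wilk normality of each variable) are
stored on the fitted estimator.  A prediction below the captured extent
would imply more than 100% coverage, so it is clamped to the captured
extent and flagged.  Percent-of-length coverage is then
`captured extent / L × 100`.

## Volume curves and the three metrics

For each ROI the cumulative volume is accumulated from the most lateral
scapular voxel medially.  Cumulative values are exact at sagittal slice
boundaries (voxel count × voxel volume, in ml) and linearly interpolated
between boundaries onto the integer percent grid p = 1..100 of the
predicted length.  Values beyond the captured coverage are missing, never
extrapolated.  ROI voxels lateral to the scapular origin (possible for
teres minor insertions) fold into the first percent bin, keeping everything
indexed to scapula location.

At each defined location p, with all volumes cumulative to p and muscle
volume M(p) always including its paired intramuscular fat F(p):

- normalized muscle size: `M(p) / S(p)` where S is scapular volume
  (dimensionless; normalizes for patient size);
- relative contribution: `M(p) / Σ₄ M(p) × 100` (% of the four-muscle RC
  unit; the four values sum to 100 by construction);
- fatty infiltration: `F(p) / M(p) × 100` (% of the muscle-boundary volume
  that is fat).

A muscle with no labeled voxels at all is flagged missing and excluded from
the RC-unit denominator (its own metrics are null); a muscle genuinely
present with zero volume at p simply contributes 0%.  Scans covering less
than 30% of the predicted length are flagged as below the default analysis
threshold; 30% is the default working coverage (with 40% as a companion
setting) because partial metrics at that depth track full-coverage metrics
strongly while remaining attainable by the large majority of clinical
scans.

## Rigid registration

Full-coverage (CT-derived) label maps are aligned to partial (MRI-derived)
label maps by a rigid transform — rotation and translation only, no scaling
or shearing — maximizing overlap of the scapula masks.  Initialization is
by centroid plus principal-axes alignment, scoring all four proper-rotation
sign combinations to resolve the eigenvector sign ambiguity.  Refinement is
a Powell search over the six rigid parameters maximizing a soft Dice score
(linear interpolation of the moving mask), which is smooth in the
parameters where the hard voxel overlap is piecewise constant.  The
procedure is deterministic.  Labels are resampled nearest-neighbor only, so
label identities are never blended and no new labels appear.  The final
hard-Dice overlap is reported; if refinement fails to improve on the
initialization, the initialization is returned.  Near-integer resampling
coefficients are snapped (tolerance 1e-9) so exact identities and integer
voxel shifts reproduce the input voxel-for-voxel.

## Cohort statistics

Correlation tables use a normality-gated rule: Pearson's r when both series
pass Shapiro–Wilk at alpha = 0.05, Spearman's rank correlation otherwise.
The partial-versus-full analysis evaluates raw volume, normalized volume
and relative contribution at 10/20/30/40% lateral coverage on
complete-coverage scans and correlates each against the full-coverage
value; a metric that is constant across the cohort is reported as
undefined rather than aborting the table.  The scapula-normalization sweep
correlates cumulative scapular volume with each muscle's cumulative volume
at each location in 30..40%, overall and by sex, restricted to scans under
40 years of age to avoid confounding by age-related atrophy.

Sex × age-bin effects are tested with a two-way factorial ANOVA including
the interaction.  Type III sums of squares (sum-to-zero contrasts) are the
default because the demographic cells are generally unbalanced; Type II is
available as a switch.  Effect size is partial η² = SS_effect /
(SS_effect + SS_error).  Post-hoc comparisons are pooled-error t tests over
all level pairs within each significant main effect, Bonferroni-adjusted by
the number of pairs in that family.  Age bins are 15–29, 30–39, 40–49,
50–59, 60–69, 70–89 years.

The normative reference database stores mean, SD and n per
(sex × age-bin × muscle × metric) cell at a chosen coverage (default 30%).
Cells with fewer than two scans, or whose SD is numerically zero, are
flagged unusable; z-scores are `(value − cell mean) / cell SD` and refuse
unusable cells or ages outside the binned range.

## Synthetic phantoms

The phantom generator is the test bed for every stage.  A phantom consists
of a scapula whose per-slice CSA follows a piecewise-linear profile —
rising from a lateral start value to a single peak in the lateral half
(default at 25% of length), then tapering medially — rasterized as centered
rectangles with exact per-slice voxel counts (a trailing partial row
absorbs rounding); four disjoint muscle compartments, each one or more
constant-cross-section boxes meeting target volumes to within rounding;
intramuscular fat assigned inside each compartment i.i.d. at a specified
fraction (an `even` deterministic mode gives exact fractions for
closed-form checks; a `clustered` mode probes interpolation robustness);
and truncation to a lateral fraction of the scapular extent.  A
`medial_peak` mode places a larger CSA peak medially to exercise the
lateral-window peak search.  Generation is bit-reproducible for a fixed
spec and seed, and the ground-truth manifest (true length, full and per-1%
volumes, realized fat fractions) is recorded from the untruncated
rasterization.

Defaults describe a healthy adult shoulder: scapula length 146 mm, peak
CSA 1200 mm², muscle+fat volumes of 40/75/20/110 ml for supraspinatus/
infraspinatus/teres minor/subscapularis (teres minor spanning only the
lateral half, matching its lateral origin), fat fractions 5%, voxel spacing
4×1×1 mm.  The cohort generator layers demographics on top: 14 scans per
sex × age-bin cell, a body-size latent scaling scapula and muscles, a
configurable scapula–muscle volume coupling (default 0.9), truncation drawn
from 35–60% coverage, and injected effects mirroring the qualitative
population pattern in healthy shoulders — supraspinatus (−5%/bin), teres
minor and subscapularis (−3%/bin) size declining with age, infraspinatus FI
increasing with age (+0.6%/bin) and in females (+1.5%).  A lightweight
companion, `sample_cohort_metrics`, draws metric values directly from the
cell-level generating distributions without rasterizing volumes; the
ANOVA calibration and z-score simulations use it so thousands of replicate
cohorts stay cheap, while `generate_cohort` produces real volumes for
pipeline-level tests.

What the phantoms do **not** emulate: realistic scapular and muscle shape
(no curvature, fossae, or tendon geometry), MRI intensities and
segmentation error, spatially structured FI gradients (beyond the clustered
mode), muscle tears or retraction.  Passing tests therefore demonstrate the
correctness of the measurement and statistical machinery given accurate
segmentations, not robustness to segmentation error or pathology.

## Numerical choices

- Cumulative interpolation is linear between slice-boundary values; metrics
  on the 1% grid agree with direct depth-truncated voxel ratios to within
  one slice's volume.
- Volumes are in ml; the percent grid is the closed integer range [1, 100].
- PD is slice-center to slice-center; no sub-slice peak interpolation.
- VB/HB use the tight axis-aligned bounding box; the mapping of image row/
  column to anatomical vertical/horizontal is configurable.
- OLS requires at least predictors + 2 samples and a full-rank design.
- Registration Powell refinement: xtol 1e-4, ftol 1e-7, max 20 iterations;
  phantom studies recover perturbations up to 20°/20 mm within 1° and one
  voxel.
- Problem sizes in the test-bed simulations (phantom grids of roughly
  30–40 slices, cohorts of 12–504 scans, 25–1000 Monte-Carlo seeds) were
  chosen as the smallest sizes at which the checked statistical properties
  are stable.

## Limitations

- The length model is linear and population-agnostic; no sex- or
  age-specific length models are provided.
- Percent-of-scapula indexing discounts variation in muscle origin (the
  teres minor starts at the lateral border); partial teres minor metrics
  inherit this caveat.
- The registration objective is Dice on label masks, suitable for label-map
  inputs but not a general intensity registration.
- The reference database is a per-cell Gaussian summary; no covariate-
  smooth normative modeling (e.g. growth-curve methods) is attempted.
- FI beyond the captured coverage is unknowable from a partial scan;
  metrics are never extrapolated medially.
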