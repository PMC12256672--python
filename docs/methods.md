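# Methods

This note documents the models, conventions, and numerical choices
behind `rtcohort`, and what the synthetic test data can and cannot show.

## Coordinate and voxel model

All geometry lives in the DICOM patient coordinate system in mm, with
axial slices and identity direction cosines only; oblique series are
rejected rather than silently resampled. A grid is `(origin, spacing,
shape)` where `origin` is the *center* of voxel (0,0,0); value arrays
are indexed `[z, y, x]`. A voxel is the closed axis-aligned box around
its center. Dose is float Gy in memory; the stored-integer + scaling
representation of RT Dose objects is an I/O detail (31-bit depth on
write, ~5e-10 relative round-trip error).

## Rasterization

A voxel belongs to a structure on a slice when its center lies inside an
odd number of that slice's polygons (even-odd rule), so inner contours
carve holes. The point-in-polygon test is a vectorized crossing-number
count. Centers exactly on an edge are resolved by a deterministic
positive perturbation of the polygon (relative magnitude 1e-9), so
on-edge centers count as inside and results never depend on float
tie-breaking. Contour planes must match a grid plane within half the
slice spacing; anything else is an error naming the offending z.

Surfaces are the centers of foreground voxels with at least one
background 6-neighbor, the grid boundary counting as background — the
standard voxel-based convention for HD95/MSD. Volumes are voxel counts
times voxel volume, for consistency with mask-based DSC. Whether a
treatment-planning system would use mesh or voxel surfaces for the same
quantities is system-specific; the voxel dialect is fixed and documented
here.

## Dose metrics

Doses are sampled at voxel centers by trilinear interpolation. Up to 5%
of a structure's voxels may fall outside the dose grid (clinical grids
often crop); they are dropped with a logged count, more is an error.
`D_Mean` is the arithmetic mean of the sampled doses. `D_p%` (default
p = 2%) is an order statistic: the k-th largest sampled dose with
k = ceil(p·n) — the minimum dose in the hottest p% of the volume,
taken literally. Planning systems frequently interpolate a binned DVH
instead; the order-statistic dialect is exact, reproducible, and exactly
homogeneous under dose rescaling, which is what the pipeline's
delivered/planned rescale correctness rests on. DVH curves are exact
empirical survival functions evaluated on a bin grid (default 0.01 Gy);
metrics are always computed from raw doses, never from binned curves.

HD95 pools the two directed nearest-surface distance sets before taking
the 95th percentile (linear interpolation between closest ranks), and
MSD is the mean of the same pooled set; both are therefore symmetric.
The pooled set is sorted before averaging so MSD is *exactly* symmetric
despite float summation. Two empty structures compare as DSC 1 /
distances 0 with a `degenerate` flag, keeping cohort summaries visible
but unpoisoned. Cohort deviation summaries use the sample SD (n−1).

## STAPLE

Raters are modeled as independent noisy channels with sensitivity p_j
and specificity q_j over a latent binary truth with fixed prior
prevalence f (initialized to the mean rater foreground fraction). EM
alternates the per-voxel consensus probability W_i and the M-step
updates of (p, q); iteration stops when max|Δp, Δq| < 1e-6 or after 200
iterations (then: result + warning). Parameters are clamped to
[1e-6, 1−1e-6] and the E-step runs in the log domain. For tractability
the sums run over the bounding box of the rater union dilated by one
voxel; the all-background voxels outside share one closed-form W and
enter the M-step analytically, so the result equals full-grid EM (the
test suite checks this against an independent naive implementation).
Initialization p = q = 0.99 is the conventional near-perfect-rater
start. The fused mask is {W ≥ threshold}, threshold 0.5 by default;
output volume is monotone non-increasing in the threshold.

On stacks built from mixed dilations and erosions of one structure,
strict-majority voting lands at the lower median contour while
STAPLE-at-50% — which credits dilated raters with high sensitivity —
lands above the truth volume: voting under-estimates, STAPLE
over-estimates. This is asserted on constructed stacks only; it is a
property of the fusion rules, not a clinical claim.

## Pipeline conventions

- **Pseudonyms** are fixed-prefix zero-padded sequence numbers assigned
  by sorted source id — human-auditable; the salt enters only UID
  remapping (keyed BLAKE2 hash truncated into a numeric UID under a
  fixed private root, collision-checked per run).
- **Reference fingerprint**: "center point" = centroid of the voxelized
  structure (robust to contour vertex density); the CT number check
  reads the voxel nearest that centroid and demands integer equality,
  since the same voxel is read on both sides of the pipeline. The mean
  dose stored at Setup is the course sum over listed plans; the research
  -side expectation multiplies each plan's share by delivered/planned.
- **Cleanup** is idempotent: plan ids already matching the template are
  recognized and not rescaled twice. Zero delivered fractions zero the
  dose and flag (interrupted courses must surface in QC, not crash).
  Organ aliases resolve by whitespace/underscore-insensitive exact match
  first, then ordered regex, first match wins.
- **Tolerances**: reference mean dose 0.1 Gy, centroid 0.5 mm, volume
  flag at mean ± 3 SD with ≥ 20 training cases per stratum. Values
  exactly on a boundary pass; only strictly outside flags.

## The synthetic phantom

Each case is a cylindrical body (HU 40) with two lung ellipsoids
(−700), an ellipsoidal heart (70), a curved posterior esophagus tube
(25), and a branched airway (lumen −1000) on a 96×96×64 grid at 2.5 mm
isotropic spacing — large enough for stable surface metrics, small
enough for sub-minute per-case processing. Organs carry distinct HU so
the reference threshold backend can find them. Organ volumes are
targeted exactly: ellipsoid semi-axes scale by the cube root, tube radii
by the square root of the requested/base volume ratio. The airway
structure is the lumen only; at 2.5 mm voxels a 2 mm wall is not
resolvable and a lumen-only truth keeps backend volumes commensurate
with truth volumes.

Cohorts draw per-organ volumes from per-sex normal distributions
(defaults: heart 800±80 / 650±65 cm³ M/F, proximal bronchial tree
45±7 / 38±6, esophagus 40±6 / 34±5; roughly realistic magnitudes with
~10–15% spread). Clean patients are drawn from the central ±2.5 SD so
that QC outcomes on a generated cohort are decided entirely by the
error-injection ledger; `volume_outlier` injections place a volume at a
stated k·SD. Every fifth course has 30 of 33 fractions delivered so the
rescale path is always exercised. Generation is a pure function of the
spec and seed — identical inputs give byte-identical DICOM files.

Injectable errors mirror real curation failures: un-extractable
(locked) files, duplicate plans appearing at injection, plan-id
collisions after renaming, uniform dose offsets, structure shifts,
single-voxel CT corruption, volume outliers, and unexpected organ
names. One error may legitimately produce findings in more than one QC
(a missing plan also fails the downstream plan count); the detection
property is therefore stated per patient: the set of patients flagged
anywhere equals the ledger, and each error trips the check designed for
it.

What the phantoms do **not** emulate: CT texture and noise, anatomical
variability beyond volume scaling, contouring-style differences between
observers, oblique or non-uniform grids, and any treatment-machine
metadata. Passing tests therefore demonstrate the correctness of the
pipeline mechanics, metrics, and QC logic — not the clinical accuracy
of any autosegmentation method; the threshold backend in particular
performs far better on phantoms (DSC ≈ 0.98 for the heart) than any
method would on patients, because the phantom organs are exactly the
structures it thresholds for.

## Problem sizes

The default test suite runs cohorts of 2–10 phantoms per scenario plus
one 50-case ledger-validation run; the acceptance script uses a 10-case
clean cohort, a 20-case error cohort, and 120 000 simulated volumes for
the QC-coverage estimate. These sizes give stable statistics (binomial
SE of the coverage estimate ≈ 0.015 percentage points) while keeping a
full run in minutes on one CPU.

## Known limitations

- Only axial, identity-orientation, uniform-spacing series; no plan
  summation across differing dose grids beyond voxel-wise addition on a
  shared grid.
- DICOM conformance is the pragmatic subset the pipeline itself reads
  and writes; private tags carry delivered fractions and plan links.
- STAPLE is binary, single-structure, with a fixed global prior; no
  multi-label or spatially varying prior variants.
- The volume QC is deliberately the simple mean ± 3 SD screen; learned
  QC models are out of scope and only have a plugin seam
  (`register_backend`-style) to attach to.
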