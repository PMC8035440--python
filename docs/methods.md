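# Methods

## Overview

`fcdensity` implements a resting-state fMRI analysis in which every
gray-matter voxel is scored by how many other gray-matter voxels its BOLD
time course correlates with above a fixed threshold — its *functional
connectivity density* (FCD) in a binarized correlation graph — split into a
local component (connections within a 6 mm sphere) and a long-range
component (connections beyond it).  Per-subject maps are normalized,
smoothed, compared between two groups with a pooled-variance t test under
Monte-Carlo cluster-extent correction, and each surviving cluster's mean
FCD is evaluated as a group classifier by ROC analysis.  A synthetic-data
generator supplies two-group cohorts with planted connectivity so the full
chain is testable without any acquisition.

## Preprocessing

Per subject, in fixed order:

1. **Volume dropping.** The first `n_drop = 10` volumes are discarded
   (signal equilibration), together with the matching motion rows; the
   default 240-volume run becomes 230 volumes.
2. **Motion screening.** A subject is excluded when the maximum absolute
   translation exceeds 1.5 mm on any axis or the maximum absolute rotation
   exceeds 1.5°, evaluated on the retained volumes.  The comparison is
   strict (`>`): exactly 1.5 mm is retained.  Excluded subjects appear in
   the exclusion log and in no downstream output.
3. **Nuisance regression.** Ordinary least squares per voxel on an
   intercept plus 30 regressors: the Friston-24 motion expansion (6
   rigid-body parameters, their one-lag copies with a zero first row, and
   the squares of both sets) and the whole-brain, white-matter and CSF mean
   signals with their first-difference derivatives (zero first row).  The
   residual is kept.  Rank-deficient designs are repaired by dropping
   dependent columns (pivoted QR) with a logged warning.  The intercept
   guarantees exactly zero-mean residuals, which simplifies the correlation
   stage.
4. **Detrend + bandpass.** Linear detrend per voxel, then a zero-phase
   frequency-domain window passing 0.01–0.1 Hz with cosine-tapered
   transitions (taper half-width two frequency bins, at least 2 mHz).  A
   zero-phase filter cannot lag one voxel relative to another, which would
   bias the correlations computed next.  Contracts: an in-band tone keeps
   > 90% amplitude; tones at twice the band-edge distance and linear ramps
   are suppressed below 10%; filtering twice changes in-band amplitude by
   < 1%.

Regression precedes filtering, following the narrative order of the
procedure the pipeline reproduces.

## FCD mapping

For each gray voxel `v`, edges are the gray voxels `u ≠ v` with Pearson
`r(v, u) > r_threshold` (strict; default 0.3).  Local FCD counts edges with
world-space Euclidean distance ≤ `radius_mm` (default 6 mm, inclusive at
exactly 6 mm); long-range FCD counts the rest; their sum is the voxel's
total degree — a conservation law asserted on every test instance.
Self-correlation is excluded; zero-variance series contribute no edges and
are logged.  Distances go through the grid affine, so anisotropic grids are
handled.

Two implementations exist deliberately: the production path streams
correlations in voxel blocks (the full correlation matrix is never
materialized) and computes local counts from the precomputed lattice-ball
offsets; a brute-force path materializes the full correlation and distance
matrices.  Exact integer agreement between the two is part of the test
contract.

Raw counts are divided by the within-mask mean ("grand-mean scaling"), then
converted to Z scores using the population SD (divide by N), making the
combined transform scale-free.  Maps are then smoothed with a Gaussian
kernel of 6 mm FWHM (σ = FWHM / (2√(2 ln 2)) per axis, converted to voxel
units).  Smoothing is mask-renormalized — the masked map and the mask are
convolved separately and divided — so edge voxels average only over in-mask
neighbours instead of being diluted toward zero.  An all-zero or constant
count map is an error (no connections above threshold / degenerate SD)
rather than a silent zero map.

## Group statistics and cluster-extent correction

Within-group maps are summarized by a voxel-wise one-sample t (sample SD,
df = n−1; zero-variance voxels get t = 0 and are flagged); the
between-group contrast is the pooled-variance Student t (A − B,
df = nA+nB−2).  Voxels are thresholded at the two-tailed critical t for
voxel-level p < .01, and connected components are formed separately for
positive and negative voxels with 26-connectivity (configurable to 6/18).

The extent threshold comes from a Monte-Carlo null: simulate Gaussian noise
volumes on the mask, smooth, standardize within the mask, threshold at the
two-tailed z cutoff, and record the maximum cluster size per iteration
(1000 by default, seeded).  The reported threshold is the smallest extent
`k` with `P(max size ≥ k) ≤ cluster_p` (default .05).  Clusters at least
that large are reported with size, peak |t| (lexicographic voxel-index
tie-break for determinism), peak world-mm coordinate and sign, sorted by
|peak t|.  Anatomical labelling of peaks is out of scope; coordinates only.

**Smoothness entering the null.**  The null's smoothness defaults to a
per-contrast estimate from the residual maps (each subject map minus its
group mean) using the classic first-difference estimator: along each axis,
`FWHM = d·√(−2 ln 2 / ln ρ)` with `ρ = 1 − var(Δ)/(2·var)`.  A fixed FWHM
can be configured instead.  The estimate is used because binarized
degree-count maps carry intrinsic spatial correlation on top of the applied
6 mm kernel (neighbouring counts share edges), and simulating at the
applied FWHM alone (measured ≈ 6.0 vs estimated ≈ 6.5 mm at the default
synthetic conditions) demonstrably under-sizes null clusters.

**Known limitation.**  At desk scale the null degree counts are sparse
(mean local degree well below 1 on a 16³ grid), so the smoothed maps behave
like shot noise: sparse spikes convolved with the kernel.  Such leptokurtic
fields produce clumpier excursion sets than any Gaussian field with the
same autocorrelation, so a Gaussian-noise null — the procedure implemented
here — remains somewhat anticonservative in this regime: the measured
probability that a null cohort yields at least one significant cluster in
either FCD map sits near 0.10 at nominal per-map cluster-p .05 (it would be
≈ 0.0975 even for a perfectly calibrated pair of independent maps).  This
mirrors the well-documented behaviour of cluster-extent simulations on
non-Gaussian data.  A label-permutation null would calibrate exactly but is
a different procedure and is not implemented.

## ROC analysis

Per surviving cluster, each subject's mean smoothed, normalized FCD over
the cluster voxels is a score.  AUC is the Mann–Whitney statistic scaled to
[0, 1] with ties counted one half, computed by explicit pairwise counting
and oriented so AUC ≥ 0.5 (the favoured group is recorded; exact ties break
toward the higher-mean group).  The 95% CI uses DeLong's
structural-components variance (per-subject means of the pairwise kernel;
sample variances over positives and negatives); a seeded bootstrap
(percentile, 2000 resamples) is available as an alternative.  The p-value
tests AUC = 0.5 by the normal approximation with the DeLong SE.  Accuracy
is banded "low" for AUC < 0.7 and "excellent" for AUC ≥ 0.7 (values above
0.9 remain "excellent", consistent with how such values are described in
the literature the banding comes from).  Degenerate inputs (all pairwise
comparisons equal) are flagged, with AUC 0.5 and a collapsed CI.

**Circularity caveat.**  Clusters are selected by the same contrast the ROC
then evaluates, so these AUCs are optimistically biased; the pipeline
prints this warning with its results.  They describe the selected regions,
not out-of-sample diagnostic accuracy.

## Synthetic cohorts

The generator emulates the emulated study's design: two groups (default 32
subjects each), 240 volumes at TR = 2 s, 3 mm isotropic grid (desk-scale
default 20×20×20), concentric-shell tissue masks (gray core, white shell,
CSF rim, all inside a spherical whole-brain mask).

Planted structure comes in two forms.  A *local hub* is a sphere of gray
voxels sharing one band-limited (0.01–0.1 Hz) Gaussian source; a
*long-range pair* is two distant gray patches sharing a source.  A planted
voxel's series is `√s·source + √(1−s)·noise_sd·e` with `e` unit-variance
AR(1)-plus-white noise (AR coefficient 0.3 by default), so at
`noise_sd = 1` the expected correlation between two voxels sharing a source
at share `s` is exactly `s` — the analytic ground truth the calibration
tests assert (|mean r − s| < 0.05 at T = 2000).  Non-planted brain voxels
are pure noise; a baseline of 100 and a slow per-voxel linear drift
(scaled by `noise_sd`) exercise the detrending and nuisance stages.  Motion
traces are smoothed random walks rescaled to SD `0.15·motion_severity` mm
(or degrees) per parameter: severity 0 is an all-zero trace, severity ≈ 10
exceeds the 1.5 mm screening limit with high probability.  Everything is
deterministic given the spec seed, with subject `(group, index)` keyed
separately so cohorts are byte-for-byte reproducible.

Group differences are planted as share differences (default 0.8 in group A
vs 0.0 in group B for both one hub and one pair), chosen for test power at
n = 10 + 10 rather than clinical realism — no effect sizes are available to
emulate.  What the generator does *not* model: physiological
(cardiac/respiratory) noise, spatially correlated scanner noise, EPI
distortion, anatomical variability, or any disease process.  Passing tests
therefore demonstrate the pipeline's correctness and statistical behaviour
under its stated noise model, not performance on real acquisitions.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline at
desk-scale grids (20³ for recovery, 16³ for null calibration; ~550–1100
gray voxels) with n = 10 + 10 subjects and the full T = 240, and the
Monte-Carlo null at 1000 iterations; these sizes preserve the method's
regime (T, voxel size, thresholds) while keeping a complete run in minutes.
Other conventions: correlations use exact zero-mean unit-norm series dot
products; degenerate correlation (zero variance) means "no edge"; Z scores
use population SD; peak ties break lexicographically; all RNGs are
explicit `numpy` generators seeded from configuration — there is no hidden
global state.
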