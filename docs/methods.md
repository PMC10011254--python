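# Methods

## Kinetic simulation

Tissue time-activity curves follow the two-tissue compartment FDG model
with free (`C_f`) and phosphorylated (`C_b`) pools. Rate constants per
tissue (K1 in ml/(min·g); k2–k4 in 1/min; blood volume fraction V_B
dimensionless) are the published values carried in
`kinetics.TISSUE_PARAMS`; lesion heterogeneity uses three parameter sets
(Levels I–III), the background tissue is normal lung, and entries reported
as absent are taken as 0 (irreversible trapping for the lesion levels).

The arterial input is the Feng 4-exponential population curve. The
absolute amplitude of the input cancels in every reported quantity because
the phantom is normalized to lung = 1; only the curve *shape* matters. The
measured whole-blood signal is approximated by plasma (`C_blood = Cp`),
with no metabolite correction — at 70 min post injection the blood term
contributes a few percent at most through V_B ≤ 0.1.

When the input function exposes its exponential decomposition the
compartment system is solved in closed form: the 2×2 rate matrix is
eigen-decomposed and each modal response is convolved analytically with
each `t^p·e^{λt}` input term. Arbitrary callable inputs (and near-defective
rate matrices) fall back to stiff numeric integration (LSODA,
rtol 1e-10). The analytic path is cross-checked against an independent
Radau integration to 1e-6 relative tolerance in the test suite.

With these defaults the Level I/II/III lesion-to-lung activity ratios at
70 min are ≈ 10.9 : 10.1 : 6.6. Because a population input curve is an
assumption rather than a measured quantity, the strict ordering
Level I > Level II > Level III > 1 is treated as the hard invariant and the
ratio values as approximate.

## Phantom geometry and degradation

A lesion is an irregular blob: a spherical signed-distance field perturbed
by a smoothed Gaussian random field (relative amplitude 0.35, correlation
length 0.8 cm), with the iso-level calibrated by bisection so the mask
volume matches the requested volume. The default cohort is 13 lesions with
volumes log-spaced over 3.5–55 cm³ on a 48×200×200 grid of
0.50×0.41×0.41 cm³ voxels. The three activity levels partition the lesion
concentrically — voxels ranked by depth (distance to the lesion surface),
core = Level I — in equal thirds by default. The spatial arrangement of
heterogeneity inside real tumors varies; concentric shells are the
simplest arrangement consistent with a hot, hypoxia-free core and are not
a claim about biology. A seeded random partition can be substituted by
editing the level assignment.

Respiratory motion is a rigid sinusoidal translation of the whole volume:
diaphragm amplitude 1.5 cm along z, anterior-posterior 0.5 cm along y, a
5 s cycle split into 10 bins, and the motion-included image is the mean of
the 10 displaced copies (uptake assumed constant over a cycle). The static
reference is bin 3, i.e. per-bin displacements are taken relative to that
intermediate phase, which makes the static lesion mask a subset of the
motion-union mask by construction. Shifts use linear interpolation, which
conserves interior activity exactly.

Image degradation is an image-domain stand-in for the projection /
reconstruction chain: Gaussian PSF blur → Poisson resampling at
`noise_scale` expected counts per unit activity per voxel (default 30) →
2 mm post-reconstruction Gaussian filter. The effective PSF (default
12 mm FWHM) lumps scanner resolution, reconstruction smoothing and
partial-volume losses into one kernel; it is set so that the
post-degradation lesion-to-background contrast of the motion-included
cohort sits in the 3–4.5 range typical of reconstructed FDG lung lesions.
A single isotropic kernel cannot simultaneously match the (higher)
static-cohort contrast, which ends up slightly above that window; the
trade-off was resolved in favor of the motion cohort, which drives the
robustness analysis. The stand-in reproduces resolution loss and count
noise but not attenuation, scatter, reconstruction non-negativity bias or
spatially varying resolution.

Initial masks emulate user interaction deterministically: the rectangle
mask is the ground-truth bounding box grown by 3 voxels per axis; the
irregular mask dilates the ground truth by a seeded, spatially varying
radius of 1–4 voxels (hole-filled). Both contain the ground truth.

## Segmentation methods

All methods operate on the voxels of the initial mask only, and the
largest 26-connected component of the raw result is retained (single
primary lesion assumption). Results are always subsets of the initial
mask.

**41MAX** thresholds at 41% of the in-mask maximum; scale invariant by
construction.

**ST** (contrast-oriented threshold) iterates
`T = a·mSUV70 + b·BG` where mSUV70 is the mean of the region above 70% of
the current maximum and BG the mean of a background shell (initial mask
dilated by 3 voxels, minus the mask) unless an explicit background region
is given. The calibration constants a, b are scanner specific in the
underlying method; defaults are 0.5/0.5 and configurable. Iteration stops
at a fixed point of the mask.

**AP** clusters in-mask intensities by affinity propagation (scikit-learn
message passing; similarity = negative squared intensity difference,
preference = median similarity, damping 0.5). Intensities are first
quantized to at most 32 levels (each represented by its members' mean) and
the levels are clustered; every voxel inherits its level's cluster. The
quantization keeps the O(n²) message passing fast and, more importantly,
sets a sensible exemplar granularity: clustering thousands of
near-duplicate raw intensities makes the preference comparable to
within-population dissimilarities and shatters tight intensity populations
into many micro-clusters. Instances with few distinct values are clustered
exactly. The reported grouping defaults to the cluster with the hottest
exemplar; the largest-cardinality cluster is available via
`SegConfig(ap_rule="largest")` (in a generous initial mask the largest
cluster is usually background, which is why hottest is the default).

**MASAC** is a two-phase region-based active contour (Chan–Vese energy)
evolved with the morphological level-set scheme, initialized from the 41%
threshold mask and confined to the initial mask (outside voxels are pinned
to their mean so the front has nothing to gain by crossing). The contrast
weight λ (default 3) sets the data-fidelity : curvature balance; since the
morphological scheme applies curvature as a discrete smoothing pass, λ is
realized as one smoothing pass per ⌈λ⌉ data iterations. Convergence is
declared when the state after a data phase repeats, and that data-phase
equilibrium is returned — the post-smoothing state transiently erodes
small lesions and is not the energy minimizer of the discrete cycle.

## Consensus and metrics

ConSeg includes a voxel when at least k of the individual contours include
it; the default k = 3 is a strict majority of four methods (the 2-of-4 tie
convention is configurable, and k = 1 / k = n give the union /
intersection). AveSeg averages *metric values* (MATV, RE, DSC) over the
four methods per case and mask condition; a mean-probability contour
(`average_contour`) is provided as the contour-space alternative.

MATV is voxel count × voxel volume. RE and DSC are computed against the
motion-union ground truth for motion-included cohorts and the static
(bin-3) mask otherwise. TRT uses the symmetric-denominator relative
difference; for signed metrics (RE) the denominator can approach zero, in
which case (|denominator| < 1e-9) the value is reported missing rather
than unbounded. DSC of two empty masks is treated as undefined, not 1.

## Statistics

The Friedman test uses the rank statistic with the average-rank tie
correction; the default p-value refers it to χ²(k−1), matching the
convention of standard statistical software, and an exact within-block
permutation enumeration is available (`method="exact"`) for small
samples. Post hoc pairwise Wilcoxon signed-rank tests handle zero
differences by the Pratt method; zero-free samples of n ≤ 15 use exact
enumeration of the signed-rank distribution with average ranks (the
common exact implementations reject ties), larger or zero-containing
samples the normal approximation. Bonferroni adjustment multiplies raw
p-values by the number of pairs, capped at 1. Box summaries use linear
interpolation between order statistics for quartiles, whiskers at
1.5·IQR, and outlier flags beyond the whiskers.

## Problem sizes and determinism

The default study — 13 cases, both mask conditions, four methods plus
consensus — completes in about a minute on one CPU at the default
48×200×200 grid; unit tests use 32×64×64 grids. Every stochastic stage
(lesion shape, noise realization, irregular mask) draws from seeds derived
deterministically from the study seed via seed sequences, so identical
configurations produce byte-identical reports.

## Known limitations

* No anthropomorphic anatomy: the background is uniform lung; liver,
  myocardium and marrow kinetics ship with the package but no organ
  geometry places them. Clinical initial masks drawn by humans are not
  modeled beyond the two synthetic mask families.
* The degradation model is image-domain; reconstruction-specific bias
  (OSEM non-negativity, subset artifacts, TOF) is absent, so absolute
  accuracy numbers are tied to this simplified imaging chain and should be
  read comparatively (method vs method), not as scanner predictions.
* Motion is rigid; real diaphragm motion deforms the lung.
* AP here clusters intensity only; adding spatial coordinates to the
  similarity would change its behavior in heterogeneous lesions.
* The active-contour energy is the classic two-phase Chan–Vese form; other
  region-based energies would need their own implementation of the data
  term.
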