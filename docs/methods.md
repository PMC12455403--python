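# Methods

`dwiclust` implements a voxelwise normative-mapping pipeline for diffusion
tensor metrics and the downstream clinical question: does surgical removal of
the largest diffusion-abnormality cluster predict postoperative seizure
freedom?  This note records the models, the parameters that matter, and the
numerical choices, in the package's own terms.

## Normative maps and z-scoring

For one metric (MD by default; AD, RD and FA differ only in background and
expected abnormality direction) the per-voxel mean and sample SD (denominator
n−1) are computed across healthy controls on a common voxel grid.  A voxel is
valid when it lies inside the analysis mask, outside any exclusion mask, and
its control SD exceeds `sd_floor` (10⁻⁶ metric units) — degenerate voxels
would otherwise produce unbounded z.  Patients are z-scored voxelwise against
the map of their own scanner cohort only; cross-cohort scoring raises an
error, because scanner differences would read as abnormality.

Assumptions worth stating: control values are treated as Gaussian per voxel;
no age/sex covariates are modelled; with n controls the held-out z is
t-distributed rather than normal, inflating its SD by roughly
√((n+1)/n)·√((n−1)/(n−3)) (≈ 1.06 at n = 30).  The leave-one-out calibration
test bounds this inflation (aggregate SD within [0.9, 1.1]) rather than
pretending it away.

Sidedness: MD/AD/RD abnormalities are increases, FA abnormalities decreases;
the z-map records a direction and `one_sided()` produces the non-negative
abnormality score (clamped at 0, or |z| for the two-sided option) that the
enhancement consumes.

## Probabilistic threshold-free cluster enhancement

True abnormalities are spatially coherent; isolated voxel exceedances usually
are not.  The enhancement walks `n_thresholds` equidistant thresholds h_i on
[0, z_max] and, at each, labels connected suprathreshold components.  For a
voxel in a cluster of extent c at threshold h_i, an enhanced exceedance
probability is computed by Bayes' rule:

    pi_i(c) = f(c | h_i) · Q(h_i) / m(c),      m(c) = ∫ f(c | h) φ(h) dh

with Q the standard-normal survival function (prior exceedance), φ the
standard-normal density, and f(c | h) the Gaussian-random-field cluster-
extent density: P(C ≥ c | h) = exp(−β(h) c^{2/3}), β set so the mean extent
matches the expected suprathreshold volume over the expected cluster count
(Euler-characteristic density), parameterised by the field smoothness (FWHM)
and the search volume.  A cluster far larger than the null expectation at h_i
makes pi_i ≪ Q(h_i) (evidence up); an isolated voxel at a high threshold is
noise-typical and gets pi_i > Q(h_i) (evidence down).

The per-threshold −log pi_i are accumulated over all h_i ≤ z(v) with
trapezoid weights plus a fractional term for the partial last interval, and
the sum is mapped back to a z scale by inverting the identical accumulation
applied to the uninformative terms −log Q(h_i).  Consequently a flat
likelihood gives the identity map *by construction* — the calibration
invariant that fixes the output scale — and the test suite verifies it to
within 2% (measured ~10⁻⁷).

Numerical choices:

- **Validity floor** `grf_min_z = 1.3`: the Euler-characteristic density is
  invalid below |z| = 1 and the extent model unreliable near it, so
  thresholds below 1.3 are made exactly uninformative (posterior = prior).
  This also removes severe discretization noise from the fragmentation of
  the near-percolating low-threshold component.
- **Threshold count 400**: cluster merges make c(h) a step function, so the
  discretization converges first-order.  At 400 levels, doubling the count
  changes z_enh by < 1% at every voxel on the synthetic patient field; at
  100 levels the change reaches several percent, which is why the default is
  denser than the common usage of this method family.
- **Smoothness**: a single isotropic FWHM per subject, estimated from the
  subject's own z-map by the first-differences random-field estimator
  (FWHM = d·√(−2 ln 2 / ln R) per axis, geometric mean, floored at half a
  voxel) unless supplied explicitly.
- The marginal m(c) integrates the likelihood against φ with the likelihood
  held flat below the validity floor and above the ladder top, so a flat
  likelihood integrates exactly to itself.

Known limitation: on a smooth *null* field, moderately large coherent
structures are common, and the enhancement lifts coherent near-threshold
structure above the z = 3 cut — total suprathreshold volume can grow even
though isolated single-voxel exceedances are reliably suppressed.  Enhanced
maps thresholded at a fixed uncorrected z are therefore not a
familywise-error-controlled inference; in this pipeline the threshold feeds
a volume-ranking whose head (the largest cluster) is dominated by the
planted/pathological signal, which is what the recovery tests measure.

## Clusters and the substantial-cluster cut

Voxels with enhanced z > 3 (configurable) are labelled with 26-connectivity
(6/18 available; the same connectivity is used inside the enhancement) and
ranked by extent, ties broken by lexicographically smallest voxel index.
Cluster volume is reported in voxels and mm³.

The rank-ordered volume sequence is split once by a change-point scan under
a gamma observation model: every break position is scored by the summed
two-segment gamma maximum likelihood (shape and rate free per segment,
Newton iteration on the shape), and the best break is accepted only when it
beats the one-segment fit by 2 log-likelihood units; otherwise — and always
with a single cluster — only the largest cluster is substantial.  The shape
parameter is capped at 100 (CV ≥ 10%): the cap gives singleton segments a
finite likelihood, keeps the degenerate-segment bonus below the acceptance
penalty, and, being scale-free, preserves scale invariance of the break
position.  The scan runs on volumes as-is (not logs).  With moderately
dispersed homogeneous sequences the two-segment model's extra flexibility
can still clear the penalty, so per-subject substantial counts run into the
low teens at this package's noise levels — the clinical claim never rests on
the exact count, and count comparisons between outcome groups are rank-based.

## Resection overlap

Overlap is exact voxel counting on the common grid: a cluster is *resected*
if ≥ 1 voxel intersects the resection mask.  The largest-cluster resected
fraction is binned NONE (0), SMALL (0 < f ≤ 0.30], MID, LARGE [0.70, 1] —
outer boundaries inclusive.  Each subject falls in exactly one category:
largest resected; largest spared but another substantial cluster resected;
largest spared, others present, none resected; largest spared and no other
substantial cluster.

## Outcome statistics

Outcomes are yearly ILAE classes; seizure-free means class 1–2.  Survival
uses time to first year with ILAE ≥ 3 (integer years 1–5; relapse followed
by remission still counts at first relapse), censoring at the last available
follow-up.  Kaplan–Meier curves and two-sided log-rank tests come from
lifelines; 2×2 tables use Pearson chi-squared with Yates continuity
correction (the convention that reproduces the published statistics — the
uncorrected statistic does not); rank-sum comparisons use the tie-corrected
normal approximation without continuity correction, so identical samples
give p = 1 exactly; proportions carry 90% Wilson score intervals.  No
multiple-testing correction is applied; p-values are reported unadjusted.

## Synthetic cohort

The generator provides the statistical structure the analysis assumes, not
anatomy:

| parameter | default | meaning |
|---|---|---|
| grid | 32³ at 2 mm | common voxel grid (small enough to run the full pipeline in seconds per subject) |
| n_controls / n_patients | 30 / 60 | cohort sizes |
| background_mean | 0.8·10⁻³ mm²/s | MD-like background |
| noise_sd | 4·10⁻⁵ mm²/s (5% of background) | marginal SD of the smooth control field |
| smoothness_fwhm_mm | 6 | Gaussian kernel FWHM of the field (periodic convolution, exactly unit-normalised) |
| planted_effect_delta | 4 | planted raise in control-SD units |
| planted_radii_mm | 6, 4, 3 | ellipsoid radii, one dominant cluster |
| spurious_cluster_rate | 2 | mean count of 1–2-voxel exceedances |
| p_seizure_free (resected / spared) | 0.83 / 0.55 | year-1 Bernoulli rates by whether the largest planted cluster is resected |
| relapse hazards (resected / spared) | 0.05 / 0.12 | per-year relapse while seizure-free |
| attrition_per_year | 0.08 | follow-up drop probability per later year |

Resection masks are spheres (radius 10 mm) placed by line search along a
random ray from the largest planted cluster's centroid so the measured
overlap hits a per-patient target within ±0.05; target 0 guarantees exact
disjointness, optionally centring the sphere on another planted cluster to
populate the spared-but-other-resected category.  Everything derives from
one integer seed via `SeedSequence`, so cohorts are bit-reproducible.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: anatomy and tissue boundaries, partial-volume effects,
scanner/site effects (a second cohort is just a second generator run),
registration error, age/sex structure, lesion pathology beyond a uniform
intensity raise, and within-year outcome timing.

The change-point recovery experiment draws the two volume segments from
gamma distributions with a 20× mean ratio and shape 8 (CV 0.35), with draws
conditioned on non-interleaving: at much higher dispersion the large
segment's draws land inside the small segment's range and no break exists at
the planted index to recover — the experiment is only well-posed when the
planted segments are actually separated.

## Problem sizes in the test and acceptance runs

Tests use 8³ volumes for labeling oracles, 16³–32³ for unit behaviour, 48³
for the enhancement's Monte-Carlo properties (50 seeds), 30-control
leave-one-out calibration at 32³, 500 change-point sequences, 50 end-to-end
patients for cluster recovery, and 200 outcome replicates at n = 200.  The
analysis scripts run a 30-control / 40-patient cohort; the acceptance script
re-derives its quantities at the sizes printed in its output (e.g. 2000
outcomes per group for rate estimates).  These sizes were chosen so the full
pipeline is exercised end to end while any single script or test file
completes in minutes on one CPU.
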