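# dwiclust

Voxelwise diffusion-MRI abnormality clusters, resection overlap, and
surgical-outcome statistics.

## The problem

In drug-resistant focal epilepsy, surgery succeeds only when the
epileptogenic zone is removed — and diffusion-weighted MRI (dwMRI) sees
tissue abnormalities (notably mean-diffusivity increases) that conventional
presurgical imaging misses.  `dwiclust` implements the analysis that links
the two: map each patient's voxelwise diffusion abnormality against a
healthy normative baseline, extract coherent abnormality clusters, measure
how much of them the surgery removed, and test whether removal predicts
postoperative seizure freedom.  It is written for imaging researchers who
have co-registered tensor-metric volumes (MD/FA/AD/RD in a common space such
as MNI-152), binary resection masks, and yearly ILAE outcome classes.

Because no patient imaging is publicly released for this analysis, the
package ships a first-class synthetic cohort generator that reproduces the
statistical structure the pipeline assumes — smooth control fields, planted
abnormality clusters with one dominant component, resection masks with
controlled overlap, and outcomes whose seizure-freedom probability depends
on whether the largest cluster was resected.  Every stage is tested against
that generator's ground truth.

## The method

For a subject volume x and per-voxel control mean μ and SD σ (sample SD,
n−1, per scanner cohort):

    z(v) = (x(v) − μ(v)) / σ(v)

z-maps are enhanced by **probabilistic threshold-free cluster enhancement**:
across equidistant thresholds h_i, each voxel's exceedance probability is
updated by Bayes' rule with a Gaussian-random-field cluster-extent
likelihood,

    π_i(c) = f(c | h_i) · Q(h_i) / ∫ f(c | h) φ(h) dh ,

the −log π_i are accumulated over h_i ≤ z(v), and the sum is mapped back to
a z scale such that an uninformative likelihood yields the identity map.
Voxels with enhanced z > 3 form clusters (26-connectivity), ranked by
volume; a gamma change-point scan over the ranked volumes separates
**substantial** clusters from small, potentially spurious ones.  The
resected fraction of each substantial cluster is exact voxel counting
against the resection mask ("resected" = any overlap), and outcomes are
compared with Kaplan–Meier curves, log-rank tests, Yates-corrected
chi-squared tables, rank-sum tests, and 90% Wilson intervals.  See
`docs/methods.md` for assumptions and numerical details.

## Worked example

The numbered scripts under `analysis/` run the study end to end on the
synthetic cohort (volumes under `scratch/`, tables under `results/`):

```
$ python analysis/01_simulate_cohort.py
wrote cohort to scratch/cohort
30 controls, 40 patients (22 with the planted largest cluster resected, 18 spared)

$ python analysis/02_abnormality_maps.py
normative map from 30 controls, 12568 valid voxels
median smoothness 5.3 mm; median abnormal voxels 173 raw -> 228 enhanced (z > 3.0)

$ python analysis/03_detect_clusters.py
40 subjects, 449 clusters; substantial clusters per subject: min 1, median 7, max 14

$ python analysis/04_resection_overlap.py
categories: {'LARGEST_RESECTED': 21, 'SPARED_OTHER_RESECTED': 11,
             'SPARED_NONE_RESECTED': 7, 'SPARED_NO_OTHER': 1}
largest-cluster resected fraction (when > 0): median 39%, IQR 32%

$ python analysis/05_outcome_analysis.py
largest_spared: 63% seizure-free at year 1 (90% CI 44-79, n=19)
largest_resected: 76% seizure-free at year 1 (90% CI 59-88, n=21)
log-rank resected vs spared: chi2=2.81, p=0.094
substantial-cluster count, seizure-free vs not: p=0.70
```

Reading the output: patients whose largest abnormality cluster was (even
partly) resected are seizure-free more often at one year (76% vs 63% here;
at this demonstration size of 40 patients the log-rank test is suggestive
rather than significant — the power analysis in the test suite shows the
contrast is detected in >95% of 200-patient cohorts), while the *number* of
substantial clusters carries no outcome information (p = 0.70), matching the
design of the generator.

The same pipeline is scriptable through the CLI
(`dwiclust simulate|normative|subject|cohort|report`) or the library
(`dwiclust.run_cohort`).

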