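# Methods

`votrsa` re-implements, as a tested pipeline over synthetic data, a two-track
analysis of hierarchical orthographic coding in ventral occipitotemporal
cortex (vOT): univariate GLM contrasts across four character-likeness
conditions, and searchlight representational similarity analysis (RSA)
relating multivoxel pattern geometry to logo-grapheme and semantic model
RDMs, with group inference, gradient profiling, and a validation (exclusion)
path. No scanner data ship with the package; a synthetic cohort generator
produces phantoms whose statistical structure matches the study design, so
every stage is testable end to end.

## Experimental model

Four stimulus classes span the orthographic hierarchy of Chinese characters:
real words (RW), pseudowords (PW, legal radical combinations without lexical
entry), false words (FW, radicals at illegal positions) and stroke
combinations (SC, scrambled strokes). The design is event-related: 40 trials
per condition, 600-ms presentations, inter-stimulus intervals uniform on
4–6 s, TR = 0.72 s, with a fixation baseline. Stroke count, pixel fraction
and (donor) word frequency are matched across conditions — the generator
enforces this by giving every condition the same shuffled multiset of
property values, so the matching report (max pairwise standardized mean
difference ≤ 0.2) passes by construction.

## Theoretical RDMs

* **Logo-grapheme model** (RW, PW, FW; SC carries no logo-graphemes):
  dissimilarity between two stimuli is one minus the ratio of shared basic
  units. "Ratio of shared units" is implemented as the Dice coefficient
  2|A∩B|/(|A|+|B|), which reduces to shared/size for the equal-size two-radical
  sets that dominate the design; Jaccard is available as a configuration
  alternative and coincides with Dice at the values 0 and 1. Tokens are
  opaque strings; no Unicode decomposition is attempted.
* **Semantic model** (RW only, since PW/FW are meaningless): one minus the
  cosine similarity of d = 300 word-embedding vectors, values in [0, 2].
  Embeddings are consumed as input; the generator fabricates them with an
  8-dimensional latent factor plus isotropic noise so cosine similarities
  have realistic spread rather than concentrating at zero.

All RDMs share one vectorization — lower triangle, row-major, diagonal
excluded — so neural and model vectors always pair identical (i, j) entries.

## First level

The canonical double-gamma HRF (response delay 6 s, undershoot delay 16 s,
unit dispersions, ratio 6, 32-s support, scaled to unit peak) is convolved
with per-event boxcars on a 16× oversampled grid and sampled at scan times.
Designs carry six motion regressors, a discrete-cosine drift basis with a
128-s cutoff (conventional default; configurable) and an intercept. Fixation
is the implicit baseline, so "condition versus fixation" is the condition
regressor's beta. Estimation is voxelwise OLS with df = T − rank(X);
rank-deficient designs raise an error naming the collinear columns.

Trial-wise estimation is least-squares-all: one GLM with one column per
RW/PW/FW trial (120 columns for the default design). SC trials are modelled
as a single nuisance condition column so their variance is absorbed without
entering the RSA.

The five activation contrasts are condition-beta differences: lexical
(RW−PW), word-form (PW−FW), abstract orthography (PW−RW), radical (FW−RW),
and basic visual (SC−RW).

## Group level

Activation: one-sample t over subject contrast-effect maps, two-tailed p,
Benjamini–Hochberg FDR at q = .05 over in-mask voxels, then a strict
cluster-extent rule (connected components of size > 10 retained;
18-connectivity by default, 6/26 configurable). Peaks are reported in mm via
the affine. Gradient profiles average a map within equal-width bins of the
y (posterior→anterior) mm coordinate inside the left fusiform mask.

Searchlight RSA: at every ROI voxel, the neural RDM is one minus the Pearson
correlation between trial beta patterns over a 6-mm-radius sphere; spheres
use in-ROI voxels only and centers with fewer than 10 such voxels are NaN
(edge spheres over a handful of voxels give unstable correlations). The
representation value is the Spearman rank correlation (average ranks for
ties) between neural and model lower-triangle vectors, Fisher-transformed
(z = atanh ρ, with |ρ| = 1 clipped at 0.999999 so group tests stay finite).
Group inference is a positive one-tailed one-sample t on z, p < .05
uncorrected, then the same "> 10" extent rule. Behavioral analysis is a
one-way repeated-measures ANOVA per measure (no sphericity correction; df
(k−1, (k−1)(n−1))) plus all six pairwise paired t tests with Bonferroni
family size 6.

Validation path: subjects with PW accuracy below 50% are excluded, then
error trials are dropped; neural and model RDMs are subset to the same
stimuli, which preserves pair alignment by construction.

## Synthetic cohorts

The phantom anatomy is an integer-labelled volume (default 40×48×38 at 2 mm)
with four mirror-symmetric region boxes per hemisphere along ascending y:
inferior occipital, then posterior, middle and anterior fusiform, separated
by 4-voxel gaps (wider than the searchlight radius, so sphere patterns never
mix subregions), inside a background "brain" slab. The affine centers the
grid on the origin with y as the posterior→anterior axis.

Generative model per subject: every brain voxel's per-trial response
amplitude is baseline (5) + condition-mean shifts + planted pattern
structure + N(0, 1) amplitude noise. Pattern plants give each in-label voxel
a fixed random linear weighting of the label's feature source (logo-grapheme
indicator vectors or embedding vectors), z-scored across the condition's
trials and scaled by the plant amplitude (default 2) and a per-subject
responsiveness factor (1 + 0.2·N(0,1), shared across regions, which couples
regions across subjects the way between-subject correlation analyses
require). Amplitudes drive boxcar·HRF time courses; AR(1) noise (coefficient
0.3, unit innovation SD), a 128-s cosine drift and a constant offset are
added; the motion table is small smoothed noise (regressors exercise the
GLM; no motion corruption is injected). Plant amplitudes have no empirical
anchor in the source study; they are calibrated for clear recovery at n = 20
and are synthetic by construction.

The default plant layout mirrors the dissociation under study: logo-grapheme
structure in the left middle fusiform for RW and PW, in the left anterior
fusiform for RW only (alongside the RW semantic code), in the right middle
fusiform for RW, and bilaterally in inferior occipital cortex for RW/PW/FW;
condition-mean shifts make posterior FG FW-selective, middle FG
PW-selective, anterior FG RW-selective and inferior occipital SC-selective,
producing the posterior-to-anterior activation gradient. Behavioral
generation mirrors the published condition ordering (PW least accurate,
slowest), with subject-level accuracy/RT heterogeneity sized so the
repeated-measures F statistics and the ~10% error rate are of realistic
magnitude and a realistic fraction of subjects falls below the 50% PW
criterion.

All randomness flows from one master seed through named substreams (roster,
events, patterns, noise, behavior), so any stage regenerates independently
and byte-identically.

### What the phantom does and does not emulate

It reproduces the design's trial structure, the planted representational
geometry, temporally autocorrelated noise, slow drift, and response/accuracy
statistics. It does not emulate spatial noise correlations, susceptibility
dropout, motion corruption of the data, anatomical variability, or
preprocessing (data are generated "preprocessed"). Passing tests therefore
demonstrate that the pipeline recovers known structure under the design's
timing and noise budget — not that it is robust to every artifact of real
acquisitions.

## Problem sizes

Cohort-level checks run on a reduced grid (26×44×22 at 2 mm, ~25k voxels,
180-voxel subregions, ~1.4k searchlight centers): the planted-recovery
cohort uses 20 subjects through the full BOLD→GLM→searchlight path, and the
Type-I-error calibration uses 100 null cohorts of 10 subjects drawn at the
trial-beta level (the generator's amplitude-level shortcut, which skips BOLD
synthesis and GLM estimation — components whose correctness is established
separately against exact oracles). The full default grid remains available
through the generator and CLI.

## Numerical choices and edge cases

* Spearman uses average ranks; undefined correlations (constant ranks, zero
  pattern variance) propagate as NaN and are excluded from group tests with
  a warning count.
* BH step-up treats NaN p values as non-rejections while keeping them in the
  family size m.
* Cluster extraction orders output clusters by size (ties by discovery
  order); "size > 10" is strict and applied after voxelwise thresholding.
* Exact permutation p for cross-region Spearman at n ≤ 9, asymptotic beyond.
* Zero residual variance yields infinite t at the affected voxels, left to
  the caller to flag.

## Interpreting the liberal RSA threshold

Searchlight z maps are spatially smooth by construction: neighboring 6-mm
spheres at 2-mm voxels share most of their voxels, so chance-significant
voxels under the p < .05 uncorrected rule arrive as connected blobs that can
exceed the 10-voxel extent rule. Monte-Carlo nulls in this package quantify
that: the voxelwise one-tailed positive rate is calibrated at 5%, but a
majority of null replicates still contain at least one surviving cluster.
Consequently (a) the extent rule should not be read as family-wise control,
and (b) region-level claims are operationalized by coverage: a subregion
counts as expressing an effect when surviving clusters cover more than half
of its voxels, which planted codes satisfy at Dice ≈ 1 while chance blobs
(typically 10–30 voxels against 180-voxel subregions) do not.

## Known limitations

* Trial-wise estimation is least-squares-all only; an LSS variant is out of
  scope.
* No crossnobis/Mahalanobis dissimilarities, noise whitening, model
  reweighting, or surface-based searchlight.
* No permutation-based cluster inference or TFCE; multiplicity control is
  BH-FDR (activation) or uncorrected + extent (RSA), as in the analysis
  being reproduced.
* The atlas path (integer labels, nearest-neighbor resampled upstream) is
  exercised only through the phantom's own label volume.
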