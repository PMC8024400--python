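# Methods

## The model under study

`netstate` implements a pipeline for asking whether cognitive tasks evoke
distinct, decodable network states in block-design fMRI, and whether the
fidelity with which an individual expresses those states relates to their
behavioural performance.  The pipeline runs, in order: first-level block
GLMs and group activation maps (conjunction/union algebra over tasks),
watershed parcellation of statistical volumes, task-pairwise similarity
measures, FIR-residual dynamic functional connectivity (dFC), multi-way
ECOC classification of the 12 tasks with repeated subject-level held-out
validation, and individual-differences analyses (performance index,
per-subject classifiability, boosted-tree prediction from network
features).

Because the pipeline is validated without any MRI data, a synthetic cohort
generator plants known structure for every stage to recover.

## Synthetic cohort generator

The generator emulates the study design it targets: `n_subjects` (60 at
full scale) each perform 12 tasks in separate runs of three 1-minute blocks,
each preceded by 20 s of rest, sampled at TR = 2 s (120 frames per run).

**Task states.**  Each task t has an activation profile a_t (ROI space) and
a connectivity perturbation Δz_t (Fisher-z edge space), both mixtures of
three components with configurable weights:

* a *shared* component common to all tasks (domain-general activation;
  within-network coupling change),
* a *factor prototype* shared by tasks loading on the same psychometric
  factor (3 factors, 4 tasks each; loading rows are non-negative and
  unit-norm with the dominant factor near 0.9),
* a *task-unique* component (sparse signed edge pattern, biased toward
  between-network edges with bias 0.85 by default; activation on a random
  ROI subset).

ROIs belong to 7 networks (contiguous blocks).  The baseline (rest)
correlation structure has within-network r = 0.25 and between-network
r = 0.06.  Sparse connectivity patterns place ~0.4·R (factor) and ~0.25·R
(unique) edges per task — scaling edge counts with the ROI count R rather
than with the edge count keeps the perturbation's spectral norm bounded
relative to the baseline's smallest eigenvalue, so positive definiteness
holds with margin across sizes.  Patterns are redrawn (up to 25 times,
amplitudes unchanged) until every condition correlation matrix is positive
definite; a `PositiveDefiniteError` with a report is raised only if the
requested scale cannot be achieved at all.

**Signal generation.**  Per run, frames are drawn from the condition
correlation matrix (rest = baseline; task = tanh(z_base + φ_s·Δz_t)) with
AR(1) smoothing (ρ = 0.3, mimicking BOLD autocorrelation; the stationary
covariance is preserved).  Activation enters as a canonical double-gamma
HRF-convolved boxcar scaled by φ_s·a_t, plus white measurement noise
(SD 0.25 by default, in units of the unit-variance network signal).

**Fidelity and behaviour.**  φ_s ~ Uniform(0.3, 1) scales both the
activation and connectivity state expression.  Behavioural scores are
affine in φ with additive noise (SD 0.3), so the first principal component
of the score table can recover φ — the only property the
individual-differences claims require.

**Calibration.**  Amplitudes were chosen once so that 12-way classification
on a 24-subject / 40-ROI cohort lands between chance (8.3%) and ceiling:
activation features reach F1 ≈ 0.6, dFC ≈ 0.45, and the stack ≈ 0.68.
Absolute values are properties of the synthetic conditions, not estimates
of what real data would give.

**What the generator does not emulate:** head motion, physiological noise,
scanner drift, spatial autocorrelation, hemodynamic variability across
regions, or non-stationary task states within a block.  Passing tests
demonstrate that the pipeline recovers planted structure under its own
generative assumptions — not that real fMRI satisfies those assumptions.

## Numerical and design choices

* **Group maps.**  One-sample t per voxel, one-sided (activation > 0);
  voxel-level Benjamini-Hochberg FDR.  The minimal-cluster rule is
  deterministic: clusters form on the relaxed map (uncorrected p < 0.01,
  positive t, 26-connectivity); the minimal size is that of the smallest
  relaxed cluster containing an FDR-significant voxel; the mask keeps FDR
  voxels in clusters at least that large.  This reading preserves FDR
  monotonicity in alpha and reduces to "all positive-t voxels" in the
  no-threshold limit.
* **Watershed.**  Priority-flood from local-maximum plateaus (one seed per
  plateau, lexicographically smallest voxel); frontier ties break by
  lexicographic voxel index, making the labelling bit-reproducible.
  Undersized ROIs merge into the neighbour with the highest shared-boundary
  statistic; isolated ones are discarded with a warning.  Defaults:
  26-connectivity, min_size 10, no smoothing.
* **FIR/dFC.**  One indicator regressor per post-onset lag per task
  (lag window = block frames + 8), OLS residuals.  Task windows shift by
  2 frames (~4 s hemodynamic delay); the first 2 rest frames after each
  task offset are discarded.  Per block: Pearson r over residual frames →
  Fisher z; dFC edge = z_block − z_rest.  The rest baseline pools rest
  frames across the subject's runs by default: rest is a task-independent
  steady state, and a single run's ~20 s windows (~24 usable frames) give a
  z noise of ~0.22 per edge, which at desk scale swamps the planted
  contrast (bounded by positive definiteness) and destroys the stack's
  advantage.  A per-run baseline remains available (`baseline="run"`).
* **Classification.**  ECOC over linear SVMs (C = 1, features z-scored on
  training statistics, no tuning); OVA = 12 learners, OVO = 66; decoding by
  minimal aggregate hinge loss, ties to the lowest class index.  Splits are
  by subject (75/25), repeated 100 times at full scale; null models scramble
  training labels within subject (preserving each subject's task multiset).
  The internal 5-fold CV estimate uses event-level folds, which makes it
  optimistic relative to held-out subjects — the qualitative pattern the
  protocol is designed to expose; stack stage-1 folds are subject-grouped so
  the out-of-fold PBS are subject-naive.
* **Stack.**  Stage 1 per metric: subject-grouped internal 5-fold CV
  produces out-of-fold positive binary scores (PBS = the 12 signed OVA
  decision values).  Stage 2: an ECOC model on the concatenated PBS
  (2 metrics × 12 = 24 features).  At test, each stage-1 fold model scores
  the test events and the 5 stage-2 predictions are combined by majority
  vote (ties to the lowest label).
* **Sparse selection.**  Leave-one-subject-out L1-logistic OVA models; the
  penalty is the weakest in a fixed grid keeping ≤ 5% of weights nonzero
  (recorded in the output manifest).  Positive and negative nonzero weights
  are binarised independently, averaged across tasks then models; the top
  set is the 99.9th percentile of each frequency map.
* **Performance index.**  Columns z-scored, PC1 via SVD, sign fixed so the
  mean task loading is non-negative, scores z-scored.  Outlier rule for
  classifiability: accuracy below chance + 2/36, or more than 3 SD below
  the cohort mean.
* **Boosted trees.**  Least-squares gradient boosting, learning rate 1.0;
  grid over max branch-node splits {1, 2, 3, 5} × trees {3, 5, 10, 25}
  (bracketing the converged (3, 3) structure), scored by leave-one-out MSE
  with a single spec selected by the outer grid; importance from a
  full-sample fit of the selected spec (inspection only, not
  cross-validated).

## Problem sizes

Unit tests run on a 12-subject / 20-ROI cohort; end-to-end evaluations use
24 subjects / 40 ROIs (780 edges), the package's standard evaluation scale.
The dFC planted-edge recovery check uses 10-minute blocks with no
measurement noise so that correlation sampling error (≈ n^-1/2 per window)
shrinks below the 0.05 Fisher-z tolerance.  Full 60-subject generation with
a voxel layer is supported but not exercised by the default suite.

## Known limitations

* Desk-scale dFC decoding is weaker than activation decoding because the
  planted connectivity contrast is capped by positive definiteness at small
  ROI counts while per-event correlation noise from 30-frame windows is
  irreducible; real cortical data at 200 ROIs occupies a different regime.
* The cluster-level correction is a deterministic minimal-size rule, not a
  random-field or permutation cluster test.
* The saliency similarity channel accepts an externally supplied matrix
  only; no saliency model is included.
* MDDM/CRTX-style external ROI sets are consumed as label volumes, not
  re-derived.
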