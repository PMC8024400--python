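# netstate

Task-evoked network-state decoding for block-design fMRI.

## The problem

Cognitive tasks are thought to be supported not by fixed brain modules but
by transient, heavily overlapping network states: each task perturbs the
brain's resting connectivity architecture in its own way, and how reliably
an individual expresses these task-optimised states may relate to their
cognitive performance.  `netstate` is a pipeline for testing these ideas
quantitatively.  It takes block-design BOLD signals (ROI x time matrices,
optionally a voxel layer) with event tables and behavioural scores, and
asks three questions:

1. Can the task a person is performing be decoded from the activation
   pattern (BA) or the task-minus-rest connectivity change (dFC) of a
   1-minute block?
2. Does the similarity of two tasks' evoked states track their similarity
   in behavioural-psychometric space?
3. Do individuals whose states are more accurately classified also perform
   better behaviourally?

It is written for methods researchers in network neuroscience who want a
tested, ground-truth-validated reference implementation of this analysis
style, without needing any MRI download: a synthetic cohort generator
plants task-specific network states with known factor structure and a
per-subject fidelity parameter φ, so every pipeline stage can be checked
against what was planted.

## What is inside

* `netstate.synthetic` — cohort generator: 12 tasks x 3 one-minute blocks
  with 20 s rests at TR 2 s; task states = shared + factor-prototype +
  task-unique mixtures in activation and Fisher-z connectivity space;
  behaviour coupled to φ.
* `netstate.activation` — block GLM with canonical double-gamma HRF,
  per-block betas, group t-maps with BH-FDR + minimal-cluster correction,
  conjunction / union / k-way overlap algebra, tSNR QC.
* `netstate.parcellation` — deterministic priority-flood watershed of
  statistical volumes; ROI signal extraction.
* `netstate.similarity` — psychometric RBF kernel S = exp(−pD²), Dice
  overlap, activation-pattern correlation with PCA scree, one-tailed
  Pearson association tests with BH-FDR families.
* `netstate.connectivity` — FIR removal of the mean evoked response,
  block-wise dFC (task-block Fisher z minus pooled rest baseline), and the
  7-within + 21-between network reduction to 28 features.
* `netstate.classification` — ECOC multi-way classification (OVA/OVO linear
  SVMs, hinge-loss decoding, no tuning), repeated 75/25 subject-level
  held-out evaluation with scrambled-label nulls and empirical
  p = (b+1)/(m+1), two-stage BA+dFC stacking, pairwise binary analysis,
  meta-class evaluation with class-size-preserving permutations, and sparse
  L1 connection selection.
* `netstate.individual` — behavioural performance index (PC1 of the task
  scores), per-subject classifiability (correct blocks out of 36),
  accuracy-PI association, and boosted regression trees predicting the PI
  from the 28 network features with a leave-one-out grid search.

## Worked example

```python
import netstate as ns

cohort = ns.make_cohort(ns.SimConfig(n_subjects=12, n_rois=20, seed=7))
ba  = ns.ba_feature_table(cohort)
dfc = ns.dfc_feature_table(cohort)

res = ns.repeated_heldout_eval(dfc, n_rep=10, seed=0)
print(f"dFC 12-way F1 (held-out): {res.dist.true_scores.mean():.3f}")
print(f"null (scrambled labels):  {res.dist.null_scores.mean():.3f}")
print(f"5-fold CV estimate:       {res.cv_scores.mean():.3f}")
print(f"empirical p:              {res.p:.3f}")

stack = ns.stack_heldout_eval({"BA": ba, "dFC": dfc}, n_rep=10, seed=0)
print(f"stack F1 (held-out):      {stack.dist.true_scores.mean():.3f}")

accs = ns.subject_classifiability(dfc.groups, res.event_tested, res.event_correct)
pi = ns.performance_index(cohort.behaviour)
row = ns.accuracy_pi_association({"dFC": accs}, pi).iloc[0]
print(f"accuracy-PI correlation:  r = {row.r:.2f}, right-tail p = {row.p:.4f}")
```

Output:

```
dFC 12-way F1 (held-out): 0.359
null (scrambled labels):  0.091
5-fold CV estimate:       0.583
empirical p:              0.091
stack F1 (held-out):      0.528
accuracy-PI correlation:  r = 0.90, right-tail p = 0.0000
```

Reading the numbers: the 12 tasks are decoded from single 1-minute blocks
of connectivity change well above the 0.083 chance level, while matched
null models trained on scrambled labels sit at chance; the within-training
cross-validated estimate (0.583) is optimistic relative to truly held-out
subjects (0.359); stacking activation and connectivity beats either metric
alone; and subjects whose blocks classify more accurately have a higher
behavioural performance index — by construction, since the generator
couples both to the planted fidelity φ.  The empirical p here is 1/(m+1)
with m = 10 repetitions, its smallest attainable value.

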