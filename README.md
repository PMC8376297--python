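# fcpipe

Whole-brain functional connectome analysis for studies of cognitive
impairment and recovery: Fisher-z connectivity construction from ROI
time series, **network-based statistics** (NBS) for group differences,
**connectome predictive mapping** (CPM) of psychomotor test scores,
consensus **psychomotor network** (PMN) extraction, and **moderated
regression** of the brain-behavior slope — plus a synthetic-cohort
generator that plants known effects so every stage can be validated
against ground truth.

The package is aimed at researchers analyzing resting-state fMRI
cohorts with a case-control and pre/post-treatment design (for example,
cirrhosis patients with or without a history of overt hepatic
encephalopathy, scanned before and after liver transplantation), and at
methodologists who want a tested, scriptable re-implementation of the
NBS + CPM analysis stack.

## The statistics at the core

**Connectivity.** For each subject, Pearson correlations between all
pairs of N region-averaged BOLD series are variance-stabilized with the
Fisher transform, `z_ij = atanh(r_ij)`, giving a symmetric zero-diagonal
matrix whose upper triangle is an edge vector of length N(N-1)/2
(6670 for the 116-region AAL parcellation).

**NBS.** Edge-wise two-sample t tests are thresholded at a stringent
primary level (p < 1e-4, one-tailed); connected components of
suprathreshold edges are scored by their size M (in edges) against a
permutation null of the *maximal* component size, giving a family-wise
corrected `p = (1 + #{max_k >= M}) / (K + 1)` over K permutations.

**CPM.** Edges whose z correlates with a behavioral score at p < 0.01
in the training split are pooled (positive and negative tails
separately) into a network strength — the mean z over the selected
edges — and a line from strength to score, fit on training subjects,
predicts held-out subjects under fivefold cross-validation. Edges
selected in every fold form the consensus network; the union of the
DST-positive and NCT-negative consensus networks is the PMN.

**Moderation.** `score ~ strength + group + strength x group` by OLS,
with 95% bias-corrected percentile bootstrap CIs for the unstandardized
coefficients, tests whether group membership changes the
brain-behavior slope.

See `docs/methods.md` for assumptions, defaults, and numerical details.

## Worked example

Simulate a three-group cohort (32 controls, 36 + 28 patients with
paired pre/post sessions) with a planted 17-edge disrupted subnetwork
(`delta_z = 0.8`), behavior coupled to an 18-edge psychomotor
subnetwork, and a group-moderated slope, then run the full comparison
design:

```python
from fcpipe.synthetic import SimulationConfig, simulate_cohort
from fcpipe.pipeline import run_study

cfg = SimulationConfig(
    n_regions=116,
    group_sizes={"HC": 32, "nonOHE": 36, "OHE": 28},
    delta_z=0.8,
    moderation_gamma=12.0,
    behavior_noise_sd=2.0,
    seed=7,
)
cohort = simulate_cohort(cfg)
report = run_study(cohort, n_perm=1000, n_boot=2000, seed=7)
```

Printing the key stages of `report` gives:

```
HC_vs_nonOHE_pre: component of 17 edges / 18 nodes, corrected p = 0.0010
HC_vs_OHE_pre: component of 17 edges / 18 nodes, corrected p = 0.0010
HC_vs_OHE_post: no significant components
CPM DST (positive tail): r = 0.855, p = 4.6e-10
CPM NCT (negative tail): r = 0.919, p = 1.2e-13
PMN: 20 edges over 23 nodes
moderation (DST): interaction = 6.91, 95% BC CI [-0.21, 15.20], p = 0.1126
```

Reading this: NBS recovers the planted 17-edge disruption in both
patient groups before treatment at the smallest attainable corrected p
(1/1001), and correctly finds nothing after treatment, when the planted
effect is absent. CPM predicts both scores from held-out subjects (DST
through the positive tail, NCT through the negative tail, matching the
planted sign conventions), and the consensus union reassembles the
psychomotor network (20 edges: the 18 planted plus 2 chance selections).
The moderated regression estimates the planted interaction of 12 as 6.9
with a wide bias-corrected CI — an honest reflection of how little
power n = 36 provides for interaction terms.

The same stages are available as a CLI over delimited-text cohorts:

```sh
fcpipe simulate --out cohort/ --seed 7 --delta-z 0.8
fcpipe nbs cohort/ --group-a HC --group-b OHE --n-perm 10000 --seed 1
fcpipe cpm cohort/ --score DST --seed 1
fcpipe report cohort/ --seed 1 --out report.json
```

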