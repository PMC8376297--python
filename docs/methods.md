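# Methods

`fcpipe` implements a whole-brain functional-connectivity analysis of
cognitive recovery: connectome construction from region-averaged BOLD
series, network-based statistics (NBS) for group differences,
connectome predictive mapping (CPM) of psychomotor scores, consensus
"psychomotor network" (PMN) extraction, and moderated regression of the
brain-behavior slope. A synthetic-cohort generator supplies ground
truth for every stage, so the statistical behavior of the whole
pipeline can be validated end to end.

## Connectivity construction

ROI time series (T timepoints x N regions, sampling interval default
2.5 s) are linearly detrended per column and band-pass filtered to
0.01-0.08 Hz with a zero-phase forward-backward Butterworth filter,
order 2 per pass. The filter family is a design choice — the common
default in resting-state pipelines — and the pass/stop behavior quoted
in the tests (gain >= 0.9 at 0.05 Hz, <= 0.1 at 0.19 Hz for TR 2.5 s)
is stated against it. Forward-backward filtering needs generous edge
padding at these frequencies: we pad with five cycles of the low band
edge (capped at T-1 samples), which makes the filter time-reversal
symmetric to better than 1e-8; scipy's default padding of a dozen
samples leaves visible edge transients. A degenerate low edge of 0 Hz
falls back to a plain low-pass of the same order.

Nuisance regression projects each ROI column onto the span of an
intercept, the confound columns (typically white-matter and CSF means
plus six motion parameters), and their backward-difference temporal
derivatives; linearly dependent columns are dropped with a warning.
Band-pass before regression is the default order; the reverse order is
available (`preprocess(..., order="regress_first")`). Discarding
initial equilibration volumes is the caller's choice
(`--discard-volumes`), never implicit.

Connectivity is the pairwise Pearson correlation mapped through the
Fisher z transform, `z = atanh(r)`, with r clipped to +/-(1 - 1e-10) so
z stays finite (clipping is logged). The diagonal is identically zero
and excluded everywhere. The strict upper triangle in row-major order
defines the canonical edge vector of length N(N-1)/2 — 6670 dimensions
for the 116-region AAL parcellation (78 cortical, 12 subcortical, 26
cerebellar regions); the vectorize/matricize round trip is bit-exact.

## Network-based statistic

Edge-wise two-sample t tests (pooled-variance Student by default; Welch
optional; a paired mode uses one-sample t on within-subject differences)
are computed at every included edge. The inclusion mask keeps edges
whose mean z is significantly nonzero in at least one group
(per-group one-sample t, Bonferroni alpha/E, default alpha 0.05); it is
computed once on the observed grouping and held fixed across
permutations. Edges with one-tailed p below the primary threshold
(default 1e-4) form a graph; its connected components, sized in
*edges*, are the candidate effects. The null distribution of the
maximal component size comes from relabeling permutations (sign flips
in paired mode) that repeat the identical t-threshold-component
procedure. The component finder is an array-backed union-find,
cross-checked in the tests against a brute-force depth-first-search
oracle.

The corrected p for an observed component of size M is the add-one
permutation estimator `(1 + #{max_k >= M}) / (K + 1)`, which cannot be
zero and counts ties conservatively. A `paper_literal` flag switches to
the plain proportion of permutations whose maximum strictly exceeds M,
which is the form sometimes quoted in applied work but can return an
invalid p of 0.

## Connectome predictive mapping

For a training cohort, every edge's z values are Pearson-correlated
with the behavioral score; the correlation p equals the simple
regression slope p, so one implementation covers both phrasings. Edges
with p < 0.01 (default) split by the sign of r into a positive and a
negative tail. A subject's network strength over an edge set is the
arithmetic mean z. Under k-fold cross-validation (default fivefold,
shuffled partition from the run seed, recorded for audit), edges are
selected on the training split only, an OLS line from train strength to
train score predicts the held-out subjects, and the pooled out-of-fold
predictions are correlated with the observed scores (`r_pred_obs`, with
the usual t-based p; a permutation option re-runs the whole CV on
shuffled scores because CV correlations violate independence
assumptions). A fold whose tail is empty predicts its training-mean
score, keeping the partition total; this is logged loudly.

The pooled `r_pred_obs` is deliberately the same statistic the
validation step of the underlying method computes, but it is *not*
null-centered at small n: each fold's intercept embeds its training
mean, which is exactly anti-correlated with the held-out scores within
a fixed sample. At n = 32, k = 5 the null mean is about -0.09. The
fold-averaged within-fold correlation (`fold_average_r`) removes the
between-fold intercept variation and is centered under the null
(measured mean approximately -0.003 over 900 shuffled runs); it is the
statistic used for calibration checks, while `r_pred_obs` remains the
reported effect size.

Consensus edges are those selected in every fold for a tail. The PMN
combines the DST-positive and NCT-negative consensus sets by union with
per-edge provenance (disjoint sets of 6 and 12 edges combine to 18); an
intersection mode exists but is not the default. Applying a fixed
network to a new cohort is a simple regression of score on strength,
reported as slope (score units per unit z), Pearson r, and F on
(1, n-2) df, tied by `F = (n-2) r^2 / (1 - r^2)`.

Sign conventions follow the tests they serve: a higher Digit Symbol
Test (DST) score is better, so DST uses the positive tail; a higher
Number Connection Test (NCT) completion time is worse, so NCT uses the
negative tail.

## Group statistics and moderation

Two-sample t tests (raw or summary-statistic form, pooled or Welch)
cover the behavioral and network-strength comparisons. The moderated
regression fits `score ~ 1 + strength + moderator + strength:moderator`
by OLS with a binary moderator (an optional second moderator expands to
the full three-way term set). Predictors are mean-centered before the
interaction is formed — this changes only the lower-order coefficients,
never the interaction. Confidence intervals are bias-corrected (BC, not
BCa — no acceleration term) percentile intervals from nonparametric
case resampling, default 10,000 resamples at the 95% level; the bias
factor z0 uses the midpoint tie convention so BC reduces exactly to the
percentile interval when the bootstrap median equals the estimate.
Resamples missing a moderator level leave the interaction inestimable
and are redrawn (counted). The bootstrap solves all resampled normal
equations in one batched operation, so 10,000 resamples cost tens of
milliseconds.

## Synthetic cohorts

The generator emulates the study design the pipeline expects: healthy
controls (n = 32) plus two patient groups (n = 36 and 28; 23 + 13 in
the paired post-treatment session), a connected disrupted subnetwork
(default 17 edges) whose connectivity is lowered by `delta_z` in
patients before treatment, an optional hyperconnected subnetwork added
after treatment, and a psychomotor subnetwork (default 18 edges,
disjoint from the disrupted set by construction) whose strength drives
the scores.

Defaults, chosen once for realistic magnitudes: base edge z ~
N(0.3, 0.15); i.i.d. edge noise SD 0.1 z; `delta_z` 0.5 (the power
scenarios in the validation suite use 0.8); a per-subject latent shift
on the psychomotor edges with SD 0.15 z, which gives subjects genuine
strength differences for the behavioral coupling to act on; DST =
47.8 + 46 x (strength - base strength) + N(0, 7) and NCT =
40.4 - 46 x (strength - base strength) + N(0, 7), so the generator's
R^2 is about 0.5 and the score means and spreads resemble published
healthy-control values; the moderated group's slope differs by
`moderation_gamma`. Connected planted edge sets are grown from a random
spanning tree over a sampled node subset.

Two modes: **direct-z** (default) writes the Fisher-z edge values
directly, giving exact effect control; **time-series** draws
multivariate-normal BOLD series whose correlation is the tanh of the
subject's target z matrix, shrunk convexly toward the identity by the
smallest factor achieving a minimum eigenvalue of 1e-3 (factor
recorded), and exercises the Pearson/Fisher estimation path. One root
seed drives everything; per-subject streams are keyed by a subject
counter so enlarging a cohort never reshuffles existing subjects.

What the generator does *not* emulate: hemodynamic response shape,
scanner noise spectra, motion artifacts, site or age effects, and any
spatial structure beyond the planted subnetworks. Passing tests
therefore demonstrate the statistical machinery is correct and
calibrated under the stated model, not that the pipeline is robust to
real-world confounds.

## Validation design and problem sizes

The test suite validates, at sizes chosen to keep the full run around a
minute: family-wise error of NBS (200 null cohorts, two groups of 20,
50 regions, primary threshold relaxed to 1e-2 for desk-scale power, 200
permutations; rejection rate must sit in the binomial band
[0.01, 0.09]); planted-network recovery (50 seeds, delta_z 0.8 on 17
edges, 30 + 30 subjects, 500 permutations; >= 90% edge coverage with
<= 10% extras at corrected p <= 0.01 in at least 45 seeds); CPM null
calibration (100 score shuffles, |mean fold-averaged r| <= 0.05) and
signal recovery (mean pooled r >= 0.4 over 50 seeds at generator R^2
0.5; >= 0.99 noiseless); component-finder equivalence with a DFS oracle
on 1,000 random graphs; and BC bootstrap interval behavior (95% CI
covers a zero interaction in 93-97% of 200 cohorts at 1,000 resamples;
a true interaction of 12 at n = 36 is estimated with < 5% mean bias).
`scripts/acceptance.py` recomputes the same quantities from scratch for
any seed.

## Known limitations

- The moderated regression treats the moderator as binary; continuous
  moderators are out of scope.
- No covariate adjustment (age, sex) inside CPM; the underlying
  protocol reports none.
- The paired NBS mode assumes complete pre/post pairs; subjects missing
  a session are dropped from that contrast.
- Time-series mode draws temporally white signals; empirical FC
  converges to the target as T grows, but autocorrelation-induced
  variance inflation of r is not modeled.
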