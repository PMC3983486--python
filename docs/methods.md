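# Methods

## The task model

The package models a feedback paradigm with 80 trait adjectives (40
positive, 40 negative), presented over 4 runs of 20 adjectives each; within
a run every adjective appears twice, once for the *self* target and once
for the *other* target, in randomly intermixed order, and adjectives are
allocated to runs at random per participant.  First and second ratings are
integers on a 1–8 Likert scale; feedback is displayed on a fixed decimal
grid.  The grid is defined as {1.0 + 0.3k : k = 0…23} ∪ {8.0}: the step
sequence starting at 1.0 reaches 7.9, and the scale endpoint 8.0 is
included as an extra point so that both printed ends of the rating scale
are attainable.

### Feedback engine

Feedback discrepancies are the manipulated independent variable.  The
engine draws, per trial:

* with probability `zero_discrepancy_probability` (default 0.07) a
  "confirmation" value — the grid point nearest the first rating.  Exact
  zero discrepancies are only attainable when the first rating is itself a
  grid point (1, 4, 7 or 8); for other ratings the confirmation value sits
  0.1–0.2 away and the trial remains classifiable;
* otherwise a discrepancy magnitude uniform over grid-step multiples in
  `discrepancy_magnitude_range` (default 0.3–3.6, mean ≈ 1.95), pointed in
  the desirable direction on the reverse-coded scale with probability
  `desirable_probability` (default 0.5).

The target value is formed on the raw scale (direction flipped for
negative traits), clamped to [1.0, 8.0] and snapped to the nearest grid
point (ties to the lower point).  Snapping moves a value at most 0.2 and
never across the first rating, so the drawn desirability direction is
preserved; clamping at the scale ends can collapse a discrepancy to zero
(a desirable draw for a trait already rated 8).  Zero discrepancies from
both routes together average ≈ 5–6 per 80 trials per target at the
defaults, matching the exclusion counts the design aims for.  All
arithmetic happens on the raw scale: the reverse-coded counterpart of a
grid value (9 − v) is generally *not* a grid value (9 − 1.3 = 7.7), which
is harmless because reverse-coded values are used only for ordering and
scoring, never displayed.

## The cohort model

Participants belong to four groups (culture German/Chinese × place
Berlin/Beijing, default sizes 27/24/28/25).  Questionnaire covariates —
interdependent and independent self-construal (1–7), Rosenberg self-esteem
(10–40), perceived similarity (1–8) — are drawn from per-group truncated
normals with means and SDs set to the study conditions the generator
emulates (Chinese more interdependent, Germans more independent and higher
in self-esteem).

### Update model

Behaviour follows linear partial adjustment on the reverse-coded scale:

```
second = clamp(round(first + α_cell · (feedback − first) + ε), 1, 8),
ε ~ N(0, update_noise_sd²)
```

with one update fraction α per (target × desirability) cell.  The
per-condition relative absolute mean update is then an approximately
unbiased estimator of α, which makes parameter recovery a direct check of
the scoring layer.  Cell fractions are composed on the logit scale so they
stay in [0, 1]:

```
logit(α_cell) = logit(base_cell) + culture_offset
                + slope · (interdependence − 3.57)
                + ε_participant + ε_participant,cell
```

Defaults: base α 0.40 (desirable) and 0.09/0.13 (self/other undesirable);
culture offsets ∓0.12 logits (Chinese update more); interdependence slope
0.4 logits per scale point; shared participant noise sd 0.5 and
cell-specific noise sd 1.0.  The two noise components were calibrated once
against the between-participant SDs of the condition scores (~0.15–0.25)
and the near-zero correlation those SDs imply between a person's desirable
and undesirable updating: heterogeneity is mostly cell-specific rather
than a single conformity disposition.  Under this calibration the
desirability main effect is essentially always significant at p < 0.001,
the culture effect has partial η² ≈ 0.05–0.07 and ~65–75% power at
α = 0.05 across replicates, and interdependence correlates with overall
updating at r ≈ 0.25–0.31 — the qualitative pattern the analysis layer is
meant to detect, at realistic effect sizes.

First ratings are round-and-clamp Gaussian draws with reverse-coded means
5.60 (self) and 5.35 (other), trial-level sd 1.4, plus a participant-level
mean shift (sd 0.5); the self > other difference reproduces the positivity
bias in initial self-views.  Recollections are the feedback plus Gaussian
noise (sd 2.3 self, 2.6 other), clamped and snapped to the grid; because
clamping at the scale ends compresses errors, these sds yield realized
mean absolute memory errors ≈ 1.35 (self) and ≈ 1.5 (other) — the raw sd
is deliberately larger than the target error level.  Missing responses are
injected independently for first rating, second rating and recollection at
`response_missing_probability / 2` each (default total 0.04), giving ~3
missing-response exclusions per 80 trials per target.

### What the generator does and does not emulate

It emulates: the design constants and trial counts; condition-dependent
partial updating with a desirability gap and a culture gap; the
interdependence–conformity link; self > other positivity in first ratings;
better memory for self-related feedback; realistic exclusion counts.  It
does **not** model trait-specific semantics (adjectives are exchangeable
labels), sequential or run-order effects, systematic response styles
(e.g. scale-end avoidance), or any coupling between memory accuracy and
updating.  Passing tests therefore validate the *pipeline* — scoring,
exclusion accounting, inference — under a known generative model, not the
psychological claims themselves on real data.

## Scoring rules

Exclusions are applied in order: trials missing the first or second rating
are excluded from update scoring first; among complete trials those with
zero feedback discrepancy are excluded (they cannot be classified as
desirable or undesirable), so the two exclusion counts never overlap and
`n_final + n_missing + n_zero` equals the 80 scheduled trials per target.
Trials missing only the second rating are retained for memory scoring when
a recollection is present; trials missing a recollection are excluded from
memory means only (not scored as maximal error).  The relative score is
the ratio of means — |mean update| / mean discrepancy — never the mean of
per-trial ratios, and a constructed test case verifies the two genuinely
differ.  The aggregator accepts fractional second ratings so that exact
worked examples (a 30%-updater scoring 0.3 in every cell) can be expressed
without rounding artefacts.

## Inference layer

All within factors are two-level, so the split-plot ANOVA is computed by
exact contrast decomposition: for each subset of within factors, a
per-participant contrast variable is formed (the empty subset is the
participant mean) and submitted to an OLS Type III ANOVA with sum-to-zero
contrasts over the between factors.  This tests every within effect
against its own subject × effect error stratum — the classical univariate
mixed-model F tests, with no sphericity issue at two levels.  Type III
(unweighted-means) tests were chosen because the between design is
unbalanced; a consequence verified in the tests is that results match an
independent mixed-ANOVA implementation exactly on balanced designs, while
weighted-means implementations differ slightly on unbalanced ones.
Between-subject error df is N − (number of between cells): 100 for groups
27/24/28/25, 53 for 27/28.  Partial η² is SS_effect/(SS_effect+SS_error)
within the effect's own stratum.  Participants with any missing within
cell are dropped listwise.

Correlations use Fisher-z confidence intervals
tanh(atanh r ± z_{1−α/2}/√(n−3)); group comparisons use Fisher's
independent-samples z; dependent correlations sharing a variable use
Williams' t with df = n − 3 (the modified, recommended variant of the
classical dependent-correlation test); incremental variance uses the
R²-change F with denominator df = n − k_full − 1.  All p-values are
two-sided and come from exact t/F/normal distributions; permutation and
simulation oracles appear only in the tests (CI coverage 93–97% and
Williams type-I error 3–7% at nominal 5% are asserted there).

## Numerical choices and degenerate inputs

* Grid snapping breaks ties toward the lower grid point
  (deterministic).
* A zero-variance sample in the one-sample t off the null reports an
  infinite t with p = 0 rather than an error.
* A within contrast that is identically zero (e.g. duplicated cells)
  reports F = 0, p = 1, partial η² = 0 instead of 0/0.
* Empty condition cells yield NaN scores and the participant is dropped
  listwise by the ANOVA; constant inputs to correlations raise.
* Logit composition clips base fractions to (1e−9, 1−1e−9) so that exact
  α = 0 and α = 1 are representable in recovery runs.
* Tables serialize at fixed precision (ratings integer, grid values one
  decimal, scores six decimals) so identical configurations and seeds
  produce byte-identical files.

## Problem sizes used in validation

Parameter recovery runs 100 participants × 160 trials per generating
fraction; the ±0.05 recovery band holds across α ∈ {0, 0.25, 0.5, 0.75, 1}
with trial noise sd 0.5.  The worst case is α = 0, where folding |mean
update| over sampling noise inflates the estimate by ≈ +0.05 — an inherent
property of the absolute-value score near zero, not an implementation
artefact; boundary rounding similarly attenuates α = 1 by ≈ 0.02.
Calibrated-simulation checks use 200 replicates of the 104-participant
design (100 in the acceptance script); correlation-machinery calibration
uses 2000 Monte-Carlo replicates.

## Known limitations

* The generator's desirability effect is somewhat stronger (partial
  η² ≈ 0.6–0.7) than is typical of real cohorts, because trial-level
  response noise is the only within-cell noise source.
* Rounding to integer Likert responses attenuates extreme update
  fractions near the scale boundaries; the recovery tests quantify this.
* The split-plot ANOVA supports only two-level within factors (by design —
  contrast decomposition is exact there); multi-level within factors would
  require sphericity machinery that this paradigm does not need.
* Zero-discrepancy "confirmation" feedback is only exactly
  zero-discrepant for first ratings on the grid; see the feedback-engine
  section.
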