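# Methods

This note documents the models, estimation procedures, simulators and design
choices behind `metacog`, in the spirit of the methods documentation of
packages such as `statsmodels` or `msprime`: what is computed, under which
assumptions, with which defaults, and what the synthetic-data tests do and do
not establish.

## The estimation problem

On every trial of a two-alternative forced-choice (2AFC) task an observer
chooses one of two alternatives and then rates confidence in that choice on a
continuous 1–6 scale. Two distinct abilities are in play:

* **Type-1 sensitivity (d′)** — how well the observer discriminates the two
  stimulus alternatives.
* **Type-2 sensitivity** — how well the observer's *confidence* discriminates
  their own correct from incorrect choices.

`metacog` estimates **meta-d′**: the type-1 sensitivity that an SDT-ideal
metacognitive observer would need in order to produce the observed confidence
data. Because meta-d′ is expressed in d′ units, the ratio **meta-d′/d′**
("M-ratio", called `efficiency` throughout the package) is a
performance-controlled index of metacognitive efficiency: 1 is ideal, values
below 1 indicate information lost between the decision and the confidence
report, and values above 1 indicate a confidence report drawing on better
evidence than the decision itself.

## Type-1 model

Equal-variance Gaussian SDT with the "right" alternative as the signal class:

* hit rate H = P(respond right | right), false-alarm rate F = P(respond
  right | left);
* d′ = z(H) − z(F), criterion c = −(z(H) + z(F))/2;
* extreme proportions are replaced by 1/(2N) and 1 − 1/(2N) per stimulus
  class (N = trials in that class), keeping both estimates finite.

## Type-2 (meta-d′) model and fit

Continuous confidence is first reduced to `nbins` (default 4) within-session
quantile bins, pooled over both responses and all blocks of a session.
Binning is by ranks: ties are kept together, and a tie group whose ranks
straddle a quantile boundary is assigned wholesale to the lower bin
(implemented by binning on minimum ranks). The mapping is deterministic,
order-invariant and monotone in the rating; a constant confidence vector
degenerates to a single bin with a warning.

The sufficient statistic is the response × accuracy × bin count table. The
meta-level observer is again equal-variance Gaussian with separation
`meta_d`, and its type-1 criterion is constrained to the same *relative*
position as the empirical one: `meta_c = (c/d′) · meta_d`. Response-
conditional type-2 criteria fan outward from `meta_c` (`nbins − 1` per
response side, mirror-ordered). The fitted probabilities are the rating
probabilities conditional on stimulus and response, and the objective is the
multinomial log-likelihood of the count table.

Numerical choices:

* every cell is padded with `1/(2·nbins)` before fitting (a standard
  regularization for zero cells); the reported log-likelihood is evaluated on
  the unpadded counts at the fitted parameters;
* criteria are parameterized as ordered log-increments away from `meta_c`,
  which enforces the mirror ordering by construction;
* the joint optimization (L-BFGS-B, likelihood tolerance 1e-10) is restarted
  from three fixed initial points (meta_d at 0.3·d′, d′ and 2·d′) and the
  best optimum is kept;
* `meta_d` is searched in [−5, 5] d′ units; a solution on the bound is
  flagged `"at_bound"`;
* non-positive d′, or confidence concentrated in a single bin per response,
  yields a flagged fit with undefined efficiency instead of an exception;
  negative fitted meta-d′ is retained as a value but excluded from log-scale
  analyses.

The unit tests check the fitted meta-d′ against an independent profiled
grid-search maximizer (criteria re-optimized at each fixed meta-d′ on a
0.005-step grid) to within 0.01 on randomized count tables.

## Generative observer model

The simulators exist because the patient data that motivate this design are
not publicly deposited; all downstream stages are therefore validated by
parameter recovery on synthetic cohorts with known ground truth.

Each trial produces latent evidence `E ~ Normal(±μ, 1)`, sign encoding the
correct side. The decision reads one copy of the evidence and confidence
another; a single signed parameter `confidence_noise_sd` controls true
metacognitive efficiency:

* `σ ≥ 0`: confidence copy = `E + Normal(0, σ²)` → efficiency below 1;
* `σ = 0`: confidence copy = decision copy → the SDT-ideal observer,
  efficiency 1;
* `σ < 0`: decision copy = `E + Normal(0, σ²)` while confidence reads the
  clean `E` → efficiency above 1 (the standard generative route to
  super-optimal M-ratios).

Confidence is the distance of the confidence evidence from the decision
criterion, signed toward the chosen response, cut by five fixed thresholds
into the six rating categories. The continuous slider value within a
category is a *deterministic monotone readout* of the same evidence (its
normal-CDF quantile within the category interval), so the rating is a
strictly increasing function of the confidence evidence. A uniformly random
within-category jitter was considered and rejected: re-binning such ratings
into four quantiles splits categories at random, which measurably degrades
even the ideal observer (fitted M-ratio ≈ 0.91–0.94 instead of 1) and would
contradict the model's own definition of ideality.

An optional lapse rate (uniform random response, ≤ 0.1; default 0) is
supported.

### Perception task

Staircased dot discrimination: a reference circle of 50 dots against a
variable circle of 50 ± Δd dots, Δd driven by a one-up two-down staircase
(one dot harder after two consecutive correct, one dot easier after each
error), Δd clamped to [1, 49] so both circles stay within the task's
1–100-dot display bound. Mean evidence is `dot_gain · Δd` with
`dot_gain = 0.147` per dot, calibrated so the staircase settles near
Δd ≈ 4 dots with long-run accuracy ≈ 71.6 % — bracketing the √½ ≈ 70.7 %
convergence point of the two-down-one-up rule. A session is 200 recorded
trials in 8 blocks of 25; the staircase carries across blocks. Each session
is preceded by a discarded 50-trial burn-in from an initial Δd of 15,
standing in for the practice-phase titration, so recorded trials start in
the staircase's stationary region (with a 25-trial burn-in, early trials are
still too easy and session accuracies drift above the nominal band).

### Memory task

Recognition memory after word-list study: 200 trials in 4 blocks of 50, one
block at 0.5 min study, two at 1 min, one at 1.5 min, in per-session random
order. A 50-word study list is simulated abstractly as 50 memory-strength
draws (no lexical content); each test trial compares the studied word's
strength against a new foil's, and the normalized old-minus-new difference
is the decision evidence, signed by the side of the old word. Mean evidence
per study time defaults to 0.44 / 0.61 / 0.71 (expected accuracies ≈ 0.67 /
0.73 / 0.76), rising with study time as in this design's typical data; the
mapping is configuration-overridable.

### Controlling true efficiency

The closed-form map `efficiency ≈ 1/√(1+σ²)` (and `√(1+σ²)` for the
decision-noise route) is only a first approximation — confidence noise also
creates confidence/response disagreements, so realized efficiency falls
faster than the closed form predicts (e.g. the σ that the closed form
associates with 0.46 actually yields ≈ 0.31). Two simulation-based controls
are therefore provided:

* `calibrate_confidence_noise(target, …)` — bisection on the signed σ using
  replicate 10⁵-trial simulated sessions with common random numbers,
  accurate to ~0.01–0.02 in realized efficiency; domain-specific, because
  the memory task pools blocks of unequal d′, which shifts the curve;
* `calibrated_sigma_map(…)` — an interpolated inverse of the σ → efficiency
  curve measured once on a fixed grid (cached per observer configuration);
  this is the default control for cohort generation so that the recorded
  ground-truth efficiencies are honest generative targets.

Supported efficiency targets span [0.1, 1.5].

## Cohorts and group analysis

A cohort specification lists groups (label, size, per-domain generative
efficiency mean ± SD); every subject completes one perception and one memory
session, with all randomness derived from a single seed. The bundled
example cohort mirrors the motivating lesion-study design: groups of 7
(frontal, selectively reduced perceptual efficiency), 11 (temporal) and 19
(control) subjects.

Group-level analysis:

* **log-efficiency and exclusions** — natural log of the M-ratio, defined
  only for positive ratios; non-positive fits are retained as raw values but
  excluded from log-based analyses and from the DGI, with a per-subject
  exclusion log. (Natural log is a choice; the DGI is base-invariant up to a
  constant factor.)
* **Domain-general index** — `DGI = |log Mp − log Mm|` per subject, where
  Mp and Mm are the perceptual and memory M-ratios; 0 means perfectly
  consistent metacognition across domains.
* **Bootstrap CIs** — percentile intervals of the resampled mean, default
  100,000 resamples, resampling unit = subject. Note that for small n the
  percentile interval of a mean runs slightly narrow (coverage ≈ 93–94 % at
  n = 30 for nominal 95 %); this is a known property of the percentile
  method, reproduced faithfully here.
* **Group tests** — one-way ANOVA and Kruskal–Wallis omnibus tests, pairwise
  pooled-variance t and Wilcoxon rank-sum tests, all two-tailed and
  unadjusted for multiple comparisons. Groups too small for a test yield
  explicit not-computable markers.
* **Group × domain interaction** — each subject contributes exactly one
  log-efficiency per domain, so the interaction is tested as a group
  contrast on the per-subject difference `log Mp − log Mm` (mean difference
  for two groups, one-way F for more), against a 10,000-permutation null
  obtained by permuting subjects across groups. A mixed model adds nothing
  at this granularity because no further random-effects structure is
  identifiable from one value per subject per domain; the permutation
  reference also avoids distributional assumptions. Its false-positive rate
  is checked at 5 % ± 2 % over 400 null cohorts.
* **No covariate adjustment** (IQ, gender, lesion volume) is performed; the
  report states this explicitly.

## Problem sizes used in the checks

Large-sample checks (ideal-observer calibration, chance floor, staircase
convergence) use 10⁴–10⁵ simulated trials. Cohort-recovery checks use 50
subjects × 200 trials per domain — the task's actual session length — where
a single subject's fitted M-ratio has SD ≈ 0.25–0.33, so cohort means carry
a Monte-Carlo SE of ≈ 0.04. Null-calibration checks use 400 simulated
cohorts (8 subjects/group, 300 permutations each) and 2,000 bootstrap
replications (2,000 resamples each).

## What the synthetic tests do and do not show

The generator reproduces the *statistical* structure of the two tasks:
session lengths and block designs, staircase dynamics and difficulty range,
study-time-dependent memory accuracy, a continuous 1–6 confidence scale, and
independently controllable decision accuracy and confidence-accuracy
coupling. Passing recovery tests show that the estimation chain is
consistent and well-calibrated *under this generative model*.

They do not show that real observers satisfy the model: human confidence
exhibits slow drifts, sequential dependencies, idiosyncratic scale use,
lapses and criterion instability, none of which are modelled (beyond an
optional uniform lapse). Word identity, display timing and response-input
details of the tasks are likewise out of generative scope. Results on real
data therefore inherit the usual caveats of meta-d′ analyses; the package's
guarantees are about the estimator, not about the observer.

## Known limitations

* Response-conditional meta-d′ (separate meta-d′ per response), hierarchical
  or Bayesian meta-d′ variants, and unequal-variance SDT are out of scope.
* The meta-d′ model assumes a stable d′ within a session; the staircase
  keeps difficulty near its convergence point but residual Δd variation
  makes the ideal observer fit at ≈ 0.98–1.02 rather than exactly 1.
* Efficiency targets outside [0.1, 1.5] are rejected rather than
  extrapolated.
* The percentile bootstrap's small-n undercoverage is inherited by design
  (the percentile method is the method being provided).
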