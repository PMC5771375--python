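# Methods

## The decision model

`magdiff` analyses two-alternative magnitude-comparison (MC) data — children
judging which of two single-digit numerals, or which of two dot sets, is
larger — with an unbiased Wiener diffusion model. Evidence `X(t)` starts at
`a/2` between absorbing boundaries 0 (error) and `a` (correct), drifts at
mean rate `v` with unit diffusion coefficient, and the first boundary crossed
determines the response and the decision time `Td`. The observed response
time is `T = Td + Ter`, with `Ter ~ U(t0 − st0/2, t0 + st0/2)` absorbing
encoding and motor time. Under these conventions

- `P(correct) = e^{av} / (1 + e^{av})` — depends on the product `a·v` only;
- `E[Td] = (a / 2v) · tanh(av/2)`, with limit `a²/4` as `v → 0`.

This four-parameter model (`a`, `v`, `t0`, `st0`) deliberately omits
inter-trial variability of drift and start point: those parameters need
thousands of trials per subject to estimate and add nothing at a few dozen
trials, while the `st0` window absorbs mild RT contamination. `v` is read as
task ability, `a` as response caution (the speed–accuracy tradeoff setting),
which is what makes the decomposition scientifically useful: median RT and
accuracy each confound the two.

### First-passage numerics

The defective first-passage density/CDF use both classical series, switched
at normalised time `τ = t/a² = 0.12`:

- small-time: method of images; the CDF is obtained term-by-term, each image
  contributing a signed, drift-adjusted inverse-Gaussian CDF evaluated
  through `log_ndtr` so reflection factors `e^{2vc}` never overflow;
- large-time: spectral series, integrated term-by-term.

At the crossover both representations agree to better than 1e−10 with the
truncations used (images |k| ≤ 5 in the vectorised path, |k| ≤ 2 in the
compiled scalar path where the first neglected image is below 1e−12;
spectral odd k ≤ 15). The upper (correct) boundary is obtained from the
lower-boundary series by the reflection `v → −v`, valid for the unbiased
start point.

The uniform `Ter` convolution is computed by 12-point Gauss–Legendre
quadrature of the decision-time CDF over the (zero-clipped) window divided
by `st0`; the integrand is smooth and monotone, and the convolved signed CDF
matches the empirical CDF of 10⁶ simulated trials to < 0.002 (tests). The
`st0 → 0` limit is handled as a pure shift. Simulation is exact inverse-CDF
sampling (boundary from the closed-form accuracy, decision time by bisection
of the conditional first-passage CDF to ~1e−8 s); model-implied quartiles
are found by bracketing bisection to 1e−6 s, either over the boundary-pooled
RT distribution or correct responses only (both quartile conventions are in
circulation for fit-assessment scatter plots, so the mode is an argument).

## Estimation

Per subject and task the four parameters minimise the Kolmogorov–Smirnov
distance between the model's and the empirical *signed*-RT CDF (error
responses at `−rt`, correct at `+rt`; the value at 0 is the error rate).
The KS objective is robust to residual contaminants and its bias does not
grow with the trial count, unlike maximum likelihood — the decisive property
at 23/45 trials per task. Optimisation is Nelder–Mead (scipy's simplex
constants; also provided as a numba-compiled kernel that is parity-tested
against the reference path) with 5 restarts: a closed-form EZ-diffusion
start (variance/accuracy inversion with edge-corrected accuracy
`(n−0.5)/n`, `st0` initialised at `t0/2`) plus 4 seeded log-normal/normal
perturbations of it. Bounds: `a ∈ [0.2, 4]`, `v ∈ [−6, 6]`,
`t0 ≥ 0.05 s`, `st0 ≥ 0`, and the support-edge feasibility constraint
`t0 − st0/2 ≤ min observed RT` enforced by penalty. Note that `t0` itself
may exceed the fastest RT when `st0 > 0` — bounding `t0` by the minimum RT
(a tempting shortcut) measurably biases `a` upward. Objective tolerance
1e−5; identical data + seed give bit-identical results; fits with fewer
than 10 trials are refused.

KS fitting at these trial counts is noisy — that is a property of the
design, not the optimiser: at 5,000 trials the estimator recovers
`a` and `v` to ±0.02 and `t0` to ±0.01 s, while at 23/45 trials recovery
correlations are ~0.5–0.7 (`a`, `v`) and ~0.85+ (`t0`), reproducing the
qualitative reliability ordering seen in split-half estimates (non-decision
time most reliable, drift rate least in the symbolic task).

## Weber fraction

Non-symbolic accuracy is additionally summarised by the approximate-number-
system Weber fraction under linear scalar variability: numerosity `n` is
represented as `N(n, (wn)²)`, so
`P(correct) = Φ(|n1 − n2| / (w·√(n1² + n2²)))` — a function of the
numerosity ratio only. `w` is estimated per subject by Bernoulli maximum
likelihood on a dense grid (step 0.005) over `[0, 3]` with golden-section
refinement; boundary optima are flagged. The estimator is consistent but
right-skewed at 45–48 trials (mean recovery ≈ +0.15 above a true 0.77, 5%
of replicates at the upper boundary; the median is unbiased to ±0.06), and
fitted `w` is a monotone convex transform of the accuracy pattern, so its
Pearson correlation with mean accuracy on a full synthetic cohort is ≈
−0.83 while the rank correlation is ≈ −0.97.

## Preprocessing

The first symbolic test item and first three non-symbolic test items behave
as warm-up and are excluded (23/45 analysable items); designed practice
items carry `item_index ≤ 0` and are always dropped. RTs below 250 ms or
above 4 s are discarded with strict inequalities (an RT of exactly 0.250 s
survives). A subject is excluded entirely if, in either task, strictly more
than half of the post-practice items fell outside the limits; the
denominator is the post-practice count, and practice removal precedes the
cutoffs (the original protocol's ordering is not documented; this choice
is recorded here, not asserted as theirs). Missing descriptives (no correct
trial) propagate as NaN and subjects drop pairwise per analysis. RTs are
stored in seconds at millisecond precision.

## Inference

- **Cohen's d**: pooled-SD, with a large-sample normal CI using
  `SE = √((n1+n2)/(n1·n2) + d²/(2(n1+n2)))`; this reproduces the reference
  interval (0.36, 0.87) for the symbolic drift-rate contrast, so it is
  labelled the primary CI construction.
- **Welch's t** with Satterthwaite df; group-comparison p-values are
  Bonferroni–Holm adjusted as one family, with the Weber fraction excluded
  from the family (its near-collinearity with mean accuracy would
  double-count one test).
- **Williams' t** (df = n − 3) compares an achievement correlation between
  the two tasks (two dependent correlations sharing the achievement
  variable).
- **Split-half reliability**: odd/even split by item order within task,
  both halves refitted, half-estimates correlated across subjects,
  Spearman–Brown stepped up (`2r/(1+r)`). The split rule is a package
  choice; nothing in the protocol prescribes one.
- **Mixed (split-plot) ANOVA** for task (within) × group (between), one
  value per subject and task: group tested against subject-within-group
  error, task and interaction against the subject×task error. Sums of
  squares are the sequential weighted-means decomposition, exact here
  because every subject contributes both tasks; it agrees with
  `pingouin.mixed_anova` to machine precision on balanced and unbalanced
  data (cross-checked in tests). The primary effect size is classical
  `η² = SS_effect / SS_total` (total over both strata) — the variant
  consistent with the small published values (0.039, 0.006) — with partial
  η² also emitted.

## Synthetic cohorts

The generator emulates the study population: 272 control ("con") and 81
dyscalculic ("dys") children, per-group/per-task diffusion parameters drawn
normally around the published group means/SDs and clipped to validity
bounds, plus a per-subject latent achievement factor with standardised
loadings (+0.32/+0.30 on drift, −0.26/−0.04 on boundary separation
symbolic/non-symbolic, smaller negative loadings on `t0`/`st0`) chosen so
achievement correlations of the published magnitude (|r| ≈ 0.2–0.3) emerge;
the same parameter correlates 0.5 across tasks (a documented placeholder —
the real cross-task covariance is unknown). Weber fractions are drawn
around 0.77/0.85 (con/dys), negatively coupled (−0.8) to non-symbolic
drift.

Item designs follow the task protocols: 24 symbolic test items, distances
1–6 four times each, single-digit pairs, larger side counterbalanced, 3
practice items; 48 dot items, 12 per ratio bin {1.2, 1.4, 1.6, 2.6} within
±0.05, dot counts 5–21, half flagged size-controlled, 2 practice items.
Non-symbolic drift scales with the item's log numerosity ratio, normalised
so the subject's configured `v` is the design-average drift (the analysis
still fits one `v` per subject×task, as the protocol assumes). Optional
contaminants replace a configurable fraction of responses with fast guesses
(U(0.05, 0.25) s, random correctness) and slow outliers (U(4, 8) s),
defaults matching the observed removal fractions (~1.01% / ~1.25%).

**What the generator does not emulate** — and hence what green tests do not
certify about real data: item-level drift variation in the symbolic task,
fatigue, post-error slowing, attention lapses beyond the `st0` window,
pixel-level dot-size/area control (carried as a flag only), and — most
consequentially — the published group SDs describe *fitted* parameters, so
using them as the true-score distribution and then re-estimating adds
estimation noise a second time. Synthetic-cohort effect sizes on fitted
parameters are therefore attenuated relative to the published ones (the
sign pattern and the ANOVA conclusions at full cohort size are preserved,
and are what the acceptance checks assert).

## Problem sizes

Default analyses run the full cohort (353 subjects, 23 + 45 trials each,
~7 minutes for the complete pipeline including split-half refits on one
CPU). Parameter-recovery checks use one 5,000-trial fit plus 50 subjects
per task at the study's trial counts; distributional validation uses 10⁵–10⁶
simulated trials per parameter set. Unit tests shrink cohorts to 8–15
subjects, which exercises every code path at a few seconds per test.

## Known limitations

- KS estimation at 23 symbolic trials is intrinsically noisy; per-subject
  symbolic estimates should be interpreted only in aggregate.
- The Weber estimator's small-sample skew means cohort means of `w`
  overstate the population mean; medians are preferable at n ≤ 50 trials.
- The mixed ANOVA uses the weighted (sequential) decomposition; with the
  heavily unbalanced groups a Type-III convention would differ slightly for
  the task main effect (not for group or interaction at two levels).
- `validate_input` enforces the trial schema but cannot detect semantically
  wrong stimulus metadata (e.g. mislabelled ratio bins).
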