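# Methods

This note records the models implemented in `murtree`, their assumptions,
the numerical conventions, and what the synthetic-data experiments do and do
not demonstrate.

## Outcomes and predictors

The unit of analysis is one edition of a mass gathering (MG).  Patient
encounter forms (PEFs) are pooled per edition:

* `PPR = 10,000 · n_patients / attendance`, counting every encounter dated
  on an official event day regardless of missing fields.  Inclusion is by
  calendar date, not 24-hour windows; encounters dated the day before or
  after an official day are excluded (they occur at camping festivals).
* `TTHR = 10,000 · n_transfers / attendance`, counting only dismissals
  `hospital_by_ambulance`.  A missing dismissal counts as non-transfer: the
  dominant "back to the event" destination is the one most plausibly left
  blank, so the conservative reading keeps TTHR from being underestimated
  by the model while accepting a slight overestimate in the source data.

Rates are carried at full precision and rounded (half away from zero, one
decimal) only for reporting.

Nine categorical/dichotomous predictors enter the PPR tree: MG category
(six levels), attendance class, age class, number-of-days class, timing,
indoor, bounded, camping, alcohol.  The continuous inputs are binned a
priori, never dichotomized by the tree:

* attendance: half-open bins [0, 10k), [10k, 20k), [20k, 30k), [30k, 100k),
  [100k, 1M), [1M, ∞).  The published class labels overlap at the
  boundaries, so a convention is required; half-open-right is consistent
  with the documented class assignments of a 12,000- and a 37,000-visitor
  edition.
* age class from the non-missing encounter ages (≈77% of PEFs):
  mixed/family overrides everything when Q1 < 21 y with IQR > 20 y, or
  Q1 < 18 y with IQR > 15 y; otherwise median < 16 → children, 16–30 →
  young adults, > 30 → middle adults.  Quantiles use linear interpolation
  (NumPy default).
* days: 1, 2, 3+.

Missing attendance is resolved by exactly two rules — a single interior gap
takes the mean of the adjacent editions; sold-out editions after an observed
sold-out first edition copy its attendance — anything else is an error, and
every imputed value carries a provenance flag.  No other field is imputed.

## The tree engine

`CartRegressor` grows an anova regression tree over categorical predictors.
At each node the split maximizing
`SSE(parent) − SSE(left) − SSE(right)` is found by exhaustive enumeration of
proper non-empty level subsets (supported to 12 levels; six occur here).
The classic sort-by-node-mean shortcut is implemented as a verified
optimization (`method="mean_sort"`) and must agree with the enumeration;
ordered predictors (attendance, days, alcohol, hospital bins) admit only
order-respecting cuts.  A split is kept when its reduction is at least
`cp × SSE(root)` (cp interpreted rpart-style as a proportional lack-of-fit
bound, default 0.01), the node has at least `minsplit` observations, node
depth (root = 0) is below `maxdepth`, and children have at least `minbucket`
(default 1) observations.  Nodes are heap-numbered (root 1, children 2k,
2k+1); leaf predictions are node means, so within-leaf residuals sum to
zero and `R²(train) = 1 − SSE(tree)/SSE(root)` equals the squared
observed/predicted Pearson correlation on the training data.

Ties are broken deterministically: equal reductions prefer the variable
earlier in column order, then the lexicographically smallest left level
set; subset enumeration places the node's first observed level on the left
so each partition is visited once.

**Surrogates.**  At every split, each other variable's best mimicking
partition is ranked by agreement — the fraction of node cases sent the same
way as the primary split, among cases with both variables observed (for
nominal variables the optimal assignment is per-level; for ordered ones
both directions of every cut are scanned).  Surrogates that do not beat the
majority-direction baseline are discarded.  Prediction routes a missing or
unseen level through the first applicable surrogate, else the majority
direction.  Variable importance credits each variable's primary-split
reductions plus agreement-weighted reductions for its surrogate roles,
normalized to percent; the agreement weighting is this package's
definition, chosen because the upstream convention is not fully specified.

**Cross-validation and selection.**  `cross_validate` assigns balanced
folds by a seeded permutation (the fold seed is a recorded configuration
value), regrows the tree on each training fold at the same configuration,
and scales the pooled held-out squared error by the full-data root SSE
(xerror); `xstd` is the delta-method standard error of that ratio.
`CartGridSearch` evaluates every (minsplit, maxdepth) pair — 16 × 8 = 128
with the default ranges — and selects minimal xerror, breaking ties toward
fewer leaves, then the smaller parameter pair.  The one-standard-error rule
is deliberately not used.  Because the greedy split at a node depends only
on that node's data, and cp/minbucket are fixed across the grid, the search
grows one maximal tree per fold (minsplit = range minimum, maxdepth = range
maximum) and derives every configuration by truncation; a test asserts
exact equivalence with direct per-configuration growth.  Folds are shared
across the grid so configurations are compared on identical resamples.
Per-fold trees are regrown at a fixed configuration rather than pruned
along an rpart-style cp sequence; the two protocols need not agree
bit-for-bit.

## Temperature adjustment

Temperature has no sensible cut point in the Belgian summer range, so it
stays out of the tree and enters as a linear post-hoc correction fitted on
the only event with daily attendance (9 editions × 4 days = 36 day-level
points): OLS of daily PPR on the daily 24-h average (`t_av`) or daily
maximum (`t_max`).  The fitted slope `b` transfers proportionally to any
outdoor event held entirely within June–September:

    PPR_adj = PPR_tree + PPR_tree / PPR_ref · b · (T − T_pivot)

with `PPR_ref` the reference event's tree-predicted PPR and
`T_pivot = (PPR_ref − intercept)/slope`, so the adjustment vanishes exactly
at the pivot for every event, and the additive correction scales linearly
in `PPR_tree`.  Multi-day events use the unweighted mean temperature over
official days.  Conventions: an event straddling May 31–June 1 is not
adjusted (all official days must fall in June–September); an adjusted value
below zero (possible at unseasonably low temperatures under the linear
form) is floored at 0; heat index / humidity is deliberately out of scope.
TTHR is never adjusted — `check_temperature_association` (two-sided slope
test at α = 0.05) documents the absence of a TTHR–temperature association
at the reference event, and the pipeline records the verdict in the bundle.

## Cascaded TTHR model

TTHR uses the same engine and the same 128-point grid protocol over 12
candidates: the nine base predictors, the PPR tree's terminal node id
(entered as a categorical label, which is how the cascade is reported — the
numeric leaf mean is carried alongside but is not a default predictor), and
hospital distance/time binned into ordered classes (≤5 / 5–15 / >15 km;
≤10 / 10–20 / >20 min, overridable).  Refitting from a serialized PPR tree
with the same seed reproduces the TTHR tree exactly.

## Validation

R² is the squared Pearson correlation between observed and predicted
outcomes.  It is invariant to affine transforms of the predictions —
association, not agreement — which the test suite asserts explicitly; the
±25% deviation bands (inclusive boundary) complement it, with >50%
over/under-prediction flagged and zero-observed events reported separately
as undefined ratios.  The 95% CI uses the Fisher z transform on r with
SE = 1/√(n−3), endpoints squared, clipped to [0, 1], lower bound 0 when the
r interval straddles zero; near r² = 0 the squared-endpoint interval is
conservative, and a seeded bootstrap percentile interval (2000 resamples)
is available as an alternative (the method is recorded in every report).
Validation is pure evaluation from the serialized bundle: the crude,
t_av- and t_max-adjusted PPR variants and the (never-adjusted) TTHR are
reported for development, temporal or external data categorized with the
development class definitions.

## The synthetic registry generator

`murtree.synthetic` emulates the registry shape the pipeline targets — it
is the test bed, not a copy of any real data:

* 28 series × 7 editions by default (≈ the 194-edition development scale),
  with per-category series counts allocated by largest remainder from the
  development category mix (the emulated registry has fixed category
  counts; a multinomial draw can produce a category with a single short
  series, which no cp-bounded protocol can isolate).
* Ground-truth PPR surface over (category, days): leaves 12 / 60 / 120 /
  183 / 273 per 10,000, city festivals lowest and 3+-day outdoor music
  highest; indoor dance and sports events share a leaf, as do outdoor EDM
  and short outdoor music (183, which doubles as the reference event's
  leaf).  Between-leaf gaps are sized so every generating split clears the
  cp = 0.01 bound with comfortable margin at the default noise: a surface
  whose gap contributes less than 1% of total SSE is unrecoverable by the
  selection protocol itself, regardless of noise, so recoverability is a
  design constraint of the ground truth, not a tuning of the tests.
* TTHR surface keyed to the PPR leaves: 0 / 1.5 / 3.0 / 5.9 per 10,000
  (indoor EDM highest), gaps again sized for the smallest category.
* Event-level dispersion: expected PPR × a mean-preserving lognormal whose
  additive standard deviation is `noise_sd` (default 40 per 10,000, chosen
  once so the default registry's development R² lands in the
  0.6–0.8 band typical of such registries), floored at 2 per 10,000; then
  Poisson patient counts and binomial-style transfer counts.  Both noise
  stages can be switched off, giving the exact-recovery oracle: with zero
  noise and temperature pinned at the pivot, aggregated PPR equals the
  generating surface up to count rounding and the selected tree's leaves
  biject onto the generating profiles.
* Encounters carry ages from per-class mixtures calibrated so the age
  classifier reproduces the intended class, with 23% missing ages; 10% of
  non-transfer dismissals are blanked (transfers are never blanked, keeping
  the TTHR ground truth recoverable — the real-world caveat that missing
  dismissals may hide transfers is documented rather than simulated).
* Daily temperatures follow a seasonal sinusoid with noise (or a pinned
  constant); outdoor June–September events receive the generating linear
  temperature transfer (slope 7.6 per °C on t_max, pivot 25.6 °C,
  reference 183) in their expected PPR.
* Attendance is lognormal per category with a 10,000 floor (the
  development-set eligibility rule).  The heavy default noise leaves a
  thicker low tail of event PPRs than the 3.9 minimum observed in the real
  registry; realism checks are therefore made in bulk, not per event.

What passing the synthetic suites shows: the engine finds exact greedy
optima (verified against brute-force enumeration and against rpart), the
selection protocol recovers a recoverable piecewise-constant surface from
200 events in ≥90% of seeds with unbiased leaf means, the temperature
transfer recovers its generating slope within 5% and is exactly neutral at
the pivot, and the cascade recovers a TTHR surface keyed to PPR leaves.
What it does not show: performance on real registries, whose within-event
temporal dynamics (rising PPR across multi-day events), non-exchangeable
encounter days, reporting artifacts and unrecorded care-post characteristics
are deliberately not modelled.

## Parameter-recovery harness

The recovery experiments use 40 series × 5 editions (n = 200), temperature
pinned at the pivot, and noise sd 6 per 10,000 — 12.5% of the smallest
between-leaf gap (48), inside the ≤25% envelope where recovery is claimed.
At the envelope boundary (sd 12) the lognormal noise reaches cv = 1 at the
lowest leaf and its outliers start to defeat the cp bound (structure
recovery ≈87/100), an artifact of additive-noise phrasing applied to a
multiplicative noise law.  Structure recovery means the selected tree's
partition refines the generating partition (every generating split present;
extra splits permitted).  Leaf means are compared to truth within two exact
generating standard errors (noise² plus the Poisson term): with a per-group
estimated sd the z = 2 margin is anticonservative by construction (t-effect
plus skew).  At the frozen seeds the harness measures structure 100/100 and
per-leaf coverage 93–99%.

## Numerical conventions and degenerate inputs

Constant outcomes: a single-node tree is returned; rel error and xerror are
undefined and signalled (`UndefinedStatisticError`), never reported as 0.
Constant temperature makes the daily fit undefined; a constant daily PPR
returns slope 0, r² 0, p 1.  R² of a constant vector is undefined and
signalled.  An adjustable event without temperature raises rather than
silently passing the crude prediction through.  Floating-point split ties
are resolved at 1e-12 relative tolerance.  All stochastic components
(generator, fold assignment, bootstrap) draw from explicit seeds and are
bit-reproducible.

## Known limitations

The engine handles categorical predictors only (by design); continuous
predictors must be categorized upstream.  xerror is computed by regrowing
at a fixed configuration per fold, not by cp-sequence pruning, so xerror
values are not bit-comparable with rpart's `xerror` column (the selected
trees agree on clean fixtures).  The Fisher-z interval for R² is
approximate near 0 and 1.  The generator's event days are exchangeable
within an event and its weather is a smooth seasonal field — both
simplifications relative to real registries.
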