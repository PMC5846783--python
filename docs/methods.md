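# Methods

This note documents the statistical machinery of `rarethin`, the design
choices made where several defensible options existed, and what the
synthetic-data generator does and does not emulate.

## Survey data model

The observational unit is the *effort segment*: nominally 10 km of
transect flown under homogeneous conditions, carrying a protocol tag
(`line` or `strip`), a half-width (the effective strip width, ESW, for
line transects; the physical half-strip, 0.2 km in the emulated seabird
protocol, for strip transects) and a covariate vector.  The searched area
is `length × 2 × half_width` km²; its log enters every count model as an
offset, so the covariate part of the linear predictor is a density in
individuals/km².  One sighting is one *group* of animals; a segment may
hold several sightings; the model response is the summed group size
(individuals) per segment.  Missing covariates are a hard validation
error — segments are defined as condition-homogeneous and complete, so
imputation would hide upstream processing faults.

Displayed percentages use round-half-up to one decimal; retained-sighting
counts under thinning use round-half-up in decimal arithmetic
(`(1−rate)·n` evaluated exactly, so 10% retained of 1,455 is 145.5 → 146
rather than the binary-float 145.4999… → 145).

## Count families

All three families are parameterised by a log-linked mean:

* **NB2**: `Var = mu + mu²/theta`, `theta > 0` estimated by ML.
* **Tweedie** (`1 < p < 2`): compound Poisson–gamma with
  `P(Y=0) = exp(−mu^{2−p}/(phi(2−p)))` and a continuous density on the
  positives, evaluated by the series expansion around its dominant index:
  terms `W_j` are summed in log space over a window
  `j ∈ [1, j* + 12√j* + 25]` with `j* = y^{2−p}/((2−p)phi)`, which keeps
  the relative truncation error far below 1e−10 across the magnitudes
  that occur in practice.  The implementation agrees with
  `mgcv::ldTweedie` to ten decimals on a frozen reference grid.
* **ZIP**: mixture `P(0) = (1−pi) + pi e^{−lam}`,
  `P(k≥1) = pi·Pois(k; lam)`, with the presence probability tied to the
  density predictor through `pi = expit(theta0 + exp(theta1)·eta)` —
  `exp(theta1)` keeps the slope positive, so presence probability is
  nondecreasing in predicted density (lower-density areas are more likely
  to yield false zeros).  The standard mixture (not a hurdle) is used.
  `eta` is the full linear predictor including the effort offset.  The
  ZIP mean — and therefore its predicted density — is `pi·lam`.

As `p → 1` the Tweedie distribution concentrates on the integer lattice;
the correct Poisson-limit statement (and the one the tests assert) is that
the *mass* in `[k−½, k+½]` approaches the Poisson pmf.  The density
*value* at integer `y` does not approach the pmf, because the lattice
spikes have width of order `phi(p−1)`.

## GAM fitting

Smooths are **unpenalised natural cubic splines with fixed df = 3**:
boundary knots at the training min/max and interior knots at the 33.3/66.7
percentiles (computed on the standardised covariate, which keeps the
design well conditioned), columns centred to zero training mean, linear
extrapolation beyond the boundary knots by construction.  With the df
fixed there is no smoothness selection; `edf` is simply the coefficient
count (1 + 3 per term).

Fitting maximises the exact family log-likelihood:

* NB and ZIP: L-BFGS-B on `(beta, log theta)` / `(beta, theta0, theta1)`
  with analytic gradients, warm-started from a Poisson IRLS fit of the
  mean structure; up to three attempts (continue-from-stall, then a
  jittered restart).
* Tweedie: for each `p` in `{1.05, 1.10, …, 1.95}` the deviance-minimising
  `beta` is found by IRLS (the `beta` MLE given `p` is independent of
  `phi`), `phi` by one-dimensional ML, and the profile likelihood picks
  `p̂` (ties broken toward 1.5), after which `phi` is refined.

**Convergence** is declared when the infinity norm of the gradient of the
*per-observation mean* negative log-likelihood falls below 1e−5.  The
tighter 1e−6 target is handed to the optimiser, but the ZIP likelihood is
near-flat in `theta0` at its optimum whenever fitted `lam` is large
(`e^{−lam} ≈ 0` makes `P(0) ≈ 1−pi`), and double precision bottoms out
around 2e−6 on full-scale data; 1e−5 separates genuine stalls from that
numerical floor.

`cov_beta` is the inverse observed information of the coefficients at the
optimum, family parameters held fixed (analytic for NB and Tweedie,
finite differences of the analytic gradient for ZIP), symmetrised and
eigenvalue-clipped to positive semidefinite.  Prediction variance is
first-order delta-method propagation, `(dmu/deta)²·xᵀΣx`; uncertainty in
the family parameters is ignored (no recipe beyond the two-term variance
decomposition below was available, and the coefficient term dominates).

Deviance is `2(llsat − ll)` under the fitted family; *explained* deviance
compares against an intercept-plus-offset null refitted with the family
parameters **frozen** at the alternative's estimates — per-fit free
parameters make null deviances incomparable (they can even come out
negative).  Model ranking uses `GCV = n·D/(n−edf)²`; near-exact GCV ties
(within 10 significant digits) resolve to fewer variables, then
lexicographic order, and non-converged fits rank last.

## Prediction maps

Daily predictions on the grid use unit searched area (so values are
densities).  A cell-day is **masked** whenever any model covariate lies
outside that covariate's training range — masking, not clamping: beyond
the data there is no prediction.  The survey-period map is the cellwise
mean over days, valid only where every day is valid (a day-count-dependent
mean would confound the averaging).  The CV map combines the population
variance of the daily means across days with the mean of the daily
delta-method variances:

```
CV = 100 · sqrt( var_days(mean_d) + mean_d(var_d) ) / mean
```

The square-root convention is the default (a CV without it is a
variance-to-mean ratio, which has the wrong units);
`uncertainty_cv(..., sqrt_convention=False)` exposes the literal ratio.

## Thinning experiment

Thinning deletes a random sample (without replacement) of the sighting
records at rate `r`, keeping every effort segment — rarity under constant
effort.  Retained count = round-half-up(`(1−r)·n`).  Replicate `(rate i,
index j)` draws its RNG from `SeedSequence(master_seed, spawn_key=(i, j))`,
so any single replicate can be reproduced in isolation and a full rerun is
bit-identical.  Each replicate refits every family **with the baseline's
covariates** (selection is a baseline-only step; the experiment isolates
the effect of sighting loss from specification change).

Scoring: the raw per-cell MSE between two density maps is available, but
experimental models are scored on **standardised** maps — each map divided
by its mean over the jointly valid cells — against the baseline, and
`MSE_ref` is the same quantity between the intercept-only (homogeneous)
map and the baseline.  The reason is structural: thinning at rate `r`
scales fitted densities by roughly `(1−r)` while the survey's spatial
pattern is what a surviving model should preserve; on the raw scale
virtually no 90 %-thinned model could ever beat `MSE_ref`, and a model
that collapses to a flat map would score exactly `MSE_ref` rather than
spuriously beating it.  MaxEnt replicates are scored by AUC of their
logistic map over the full dataset's presence/absence segments, against
0.5.  Replicates that fail to converge are excluded from the means and
from the proportion-better denominator and reported as failure counts.
Summaries report the mean, median and standard error of the scores per
rate × model, the proportion of replicates beating the reference, and
averaged replicate maps with their across-replicate CV.

## MaxEnt

Background = the covariate vectors of all effort segments (the survey's
sampled environment; the balanced design is what makes presence-only
modelling defensible here).  Features per variable: a [0,1]-scaled linear
term plus forward and reverse hinges at 20 equally spaced background
quantiles.  The fit maximises the mean log Gibbs probability of the
presences over the background minus an L1 penalty
`lambda_j = reg · max(sd_j, 0.05)/√m` (presence-sample standard error,
floored).  The default multiplier is 1.5: one standard error leaves
roughly a third of pure-noise features active, and 1.5 is the smallest
round value at which a presence sample drawn from the background itself
reliably produces the flat (≈0.5 everywhere) logistic output it should.
Optimisation is deterministic convex minimisation with the weights split
into positive and negative parts (exact L1 handling, no sampling).
Logistic output: `tau·e^h/(1−tau+tau·e^h)` with
`h = w·f(x) − log Z + H` and `tau = 0.5` by default.  AUC uses the
Mann–Whitney convention (ties count ½).

## Synthetic generator

The generator emulates the *statistical structure* of a two-season aerial
survey of a shelf system, not its geophysics:

* **Environment**: 0.05° grid (coarser for quick experiments); depth rises
  offshore across a wide shallow shelf (Channel-like, ~half the domain
  under 200 m) to a sharp break and abyssal water, plus smoothed noise;
  slope is its gradient.  Dynamic fields (SST mean/variance/gradient, SSH
  mean/sd, current intensity) are smoothed Gaussian fields (correlation
  length ~0.4°, far above cell size) evolving as AR(1) day-to-day walks
  (lag-1 ≈ 0.85), with a seasonal SST cycle; SST is clipped to [5, 25] °C.
* **Design**: zig-zag east–west legs climbing through latitude in two
  seasonal passes, cut into 10-km segments (terminal pieces may be
  shorter), truncated at exactly the requested segment count — 3,320 for
  the dolphin-like preset, 3,501 for the auk-like one.
* **Taxa**: the broad taxon has a temperature dome near 16 °C, SSH
  preferences and a weak bimodal depth use spanning the full range; the
  narrow taxon is restricted to shallow water (log-intensity drops by
  more than 5 between 50 m and 2,000 m) with cold-water and frontal
  preferences.  Response amplitudes were set so the full-scale baseline
  models reproduce explained deviances in the ranges observed in the two
  emulated case studies (broad ≈ 39/44/15 % and narrow ≈ 45–54/41–54/15–20 %
  for NB/TW/ZIP).  The intercept is calibrated analytically so the
  expected sighting count equals the target (277 / 1,455) exactly.
* **Sightings**: encounter × group size — group counts per segment are
  Poisson (optionally NB) in the calibrated intensity; group sizes are
  zero-truncated NB2 with means derived from the emulated totals
  (14,477/277 ≈ 52.3 and 16,658/1,455 ≈ 11.5 individuals per group).
  Thinning operates on groups; models see individual counts, which are
  therefore strongly overdispersed.  `simulate_counts` instead draws
  segment responses directly from one of the three families for
  matched-family recovery checks with exact truth.

**What the generator does not emulate.**  Real remote-sensing covariates
(compositing, gaps), detection-function estimation (the ESW is an input),
coastline geometry, and spatial autocorrelation of encounters beyond what
the smooth environment induces.  One structural consequence: with Poisson
group encounters the number of presence segments cannot exceed
`Σ(1−e^{−λ})` < expected sightings, so the narrow scenario realises ~25 %
presence segments where the emulated auk table implies ~40 % (which would
require at most one sighting per segment).  Passing tests therefore
demonstrate correctness and the qualitative robustness ordering on data
with realistic overdispersion and habitat contrast, not calibration to any
particular real survey.

## Problem sizes

Recovery checks run 20 seeds per family on the full 3,320-segment design.
Experiment-level properties use reduced replication on scaled scenarios —
1,200 segments / 420 sightings with 3 rates × 20 replicates for the error
growth and reproducibility checks, and matched 1,660-segment / 200-sighting
broad and narrow scenarios with 4 rates × 12 replicates × 5 seeds for the
family-robustness ordering — sizes chosen to keep the full suite in the
ten-minute range on one CPU while leaving every property comfortably
resolved.  The ordering statistic (the smallest rate at which a family's
proportion-better drops below ½, compared across families with ties
allowed) follows the experiment's formalisation of "Tweedie retains skill
longest"; the mean MSE is heavy-tailed at small replication, so the
acceptance script reports median-based monotonicity alongside the
proportions.

## Known limitations

* Unpenalised 3-df smooths with a log link can and do produce explosive
  refits at extreme thinning (tens of positives, 13 coefficients); this is
  a finding the experiment is designed to expose, not an artefact to
  suppress, but it means raw MSE summaries are heavy-tailed.
* The ZIP parametrisation is weakly identified where fitted means are
  large and zeros can be attributed to either component; its depth-tail
  response in the narrow scenario is essentially unidentified.
* MaxEnt is a deliberately small re-implementation (linear + hinge,
  logistic output); no clamping, jackknife, or output-format parity with
  the java software.
* The delta-method CV ignores family-parameter uncertainty and cross-day
  covariance of predictions.
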