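# rarethin

**How many sightings does a species distribution model need?**

`rarethin` is a toolkit for *sighting-thinning experiments* on segmented
transect surveys of marine megafauna.  Rare species yield few sightings per
unit effort, and it is rarely clear whether a habitat model fitted to such
data can be trusted.  The package answers that question empirically: start
from a survey with plenty of sightings, fit a *baseline* model, then delete
a growing fraction of the sightings at random (keeping every kilometre of
effort) and measure how quickly each model family's predictions degrade
relative to its baseline — and, crucially, relative to the prediction of a
*homogeneous* spatial distribution, the point at which the model stops
being worth using at all.

It is aimed at habitat modellers and survey designers working with
line-/strip-transect data (aerial or shipboard), and at anyone who needs a
defensible minimum-sample-size rule before fitting SDMs to rare-species
data.

## The models

Counts of individuals on 10-km effort segments are modelled as

```
E[y_i] = exp( beta_0 + sum_v s_v(x_iv) + log A_i ),     A_i = L_i * 2 * w_i
```

with `s_v` unpenalised natural cubic splines (3 df each, at most 4
covariates), and `A_i` the searched area — segment length times twice the
effective strip width (line transects) or the physical half-strip (strip
transects) — so `exp` of the covariate part is a density in
individuals/km².  Three residual families are fitted by exact maximum
likelihood:

* **NB-GAM** — negative binomial (NB2), size `theta` estimated jointly;
* **TW-GAM** — Tweedie compound Poisson–gamma, `1 < p < 2` profiled over a
  grid, dispersion `phi` by ML (positive mass at zero plus a continuous
  positive density: the natural family for zero-heavy biomass-like counts);
* **ZIP-GAM** — zero-inflated Poisson whose presence probability is
  logit-linear in the density predictor,
  `pi = expit(theta_0 + exp(theta_1) * eta)`, so sparsely populated areas
  have a higher chance of producing false zeros.

A presence-only **MaxEnt** model (linear + dense hinge features, L1
penalty, logistic output at prevalence 0.5) is fitted against the survey's
own effort segments as background.  Candidate covariate sets (all subsets
of size 1–4 surviving a |r| > 0.7 collinearity screen) are ranked by
GCV = `n·D/(n − edf)²`.

Experimental (thinned) models are scored on a prediction grid by the mean
squared difference between the standardised (mean-1) prediction map and
the baseline's, compared with **MSE_ref**, the same quantity for an
intercept-plus-offset-only ("homogeneous") model; MaxEnt is scored by AUC
against 0.5.  A synthetic survey generator provides broad-habitat
(dolphin-like: 3,320 segments, ~277 sightings of ~52-individual groups)
and narrow-habitat (auk-like: 3,501 segments, ~1,455 sightings of
~11-individual groups) scenarios with known truth, so the whole pipeline
is testable without the (undeposited) original aerial-survey data.

## Worked example

```python
from rarethin import (build_scenario, CountGAM, ThinningPlan,
                      run_experiment, summarize_experiment)
from rarethin.gam import ModelSpec

scen = build_scenario("narrow", seed=1, n_segments=1200, target_sightings=420,
                      resolution=0.25, days=(0, 6, 180, 186))
print(scen.dataset.bookkeeping(scen.taxon_name))
# Bookkeeping(n_sigh=445, n_z=934, pct_z=77.8)

res = CountGAM.from_survey(scen.dataset, scen.taxon_name, "tweedie",
                           variables=("depth", "sst_mean", "sst_grad",
                                      "ssh_mean")).fit()
print(res.summary())
# Count GAM (tweedie), n = 1200, edf = 13
# converged: True   log-likelihood: -1469.942
# deviance: 6482.657   GCV: 5.52119
# family parameters: p = 1.35, phi = 10.32
# term                            coef          se
# intercept                    -1.5184      0.1341
# s(depth).1                  -16.3006      1.5950
# ...
```

445 sightings were simulated on 1,200 segments (77.8% zero segments); the
Tweedie fit profiles the power to `p = 1.35` and the steep `s(depth)`
coefficients encode the taxon's shallow-water restriction.  Now thin:

```python
specs = {f: ModelSpec(family=f, variables=("depth", "sst_mean", "sst_grad",
                                           "ssh_mean"))
         for f in ("negbin", "tweedie", "zip")}
plan = ThinningPlan(rates=(0.5, 0.9), n_replicates=10, master_seed=1)
result = run_experiment(scen.dataset, scen.taxon_name, specs, plan, scen.grid())
print(summarize_experiment(result))
#   model  rate  retained  score_mean  reference  proportion_better
#  negbin   0.5       223    9.115909   1.697652                0.6
#  negbin   0.9        45   30.272234   1.697652                0.4
# tweedie   0.5       223    0.442179   1.665202                0.9
# tweedie   0.9        45    8.692391   1.665202                0.6
#     zip   0.5       223   18.495511  24.182685                0.8
#     zip   0.9        45   52.278678  24.182685                0.5
```

At 50% thinning (223 sightings) 9 of 10 Tweedie refits still predict the
baseline pattern better than a homogeneous distribution
(`score_mean 0.44 << MSE_ref 1.67`), while the NB refits are already
unstable (mean MSE 9.1, only 6 of 10 better than homogeneous).  At 90%
(45 sightings) the Tweedie model is the only family whose mean error is
within an order of magnitude of its reference — the robustness ordering
that motivates recommending Tweedie GAMs (with ~50 sightings as a
conservative floor) for rarely sighted taxa.

A thin CLI mirrors the library: `rarethin simulate`, `rarethin validate`,
`rarethin select`, `rarethin experiment --config config.yml`.

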