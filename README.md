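# tricot

Design and analysis of **tricot** ("triadic comparison of technology
options") on-farm trials — the citizen-science approach in which each
participating farmer grows a package of three masked crop varieties drawn
from a larger set of *t* entries and reports, per trait, which performed
best and which worst.

The package is aimed at breeders, agronomists and quantitative scientists
running decentralised variety trials. It covers the whole trial lifecycle:

- **Trial design** — A-optimal triadic incomplete block designs with
  balanced replication and concurrence, sequential block ordering for
  staged distribution, and the closed-form relative efficiency
  `E = t/(t-1) · (k-1)/k` used to express plot counts as *equivalent
  experimental units* (EEU) for cost comparison against a randomized
  complete block design (RCBD).
- **Ranking data** — decoding best/worst answers into complete 3-item
  rankings (best first, unmentioned entry second, worst last),
  rank-breaking into pairwise comparisons, CSV I/O and connectivity checks.
- **Worth estimation** — Plackett–Luce models: each item has a worth
  `w_i = exp(θ_i)` and the probability that item *i* is ranked first in a
  set *S* is `w_i / Σ_{l∈S} w_l`, applied sequentially down the ranking.
  Fitting is by minorize–maximize updates with Newton polishing, with
  quasi-variances, the probability of outperforming a check
  `w_i/(w_i + w_check)`, Bayesian-bootstrap risk assessment (reliability
  of each entry versus the check), Bradley–Terry fits on broken pairs, and
  item-covariate regression `θ = Xβ`.
- **Covariate trees** — model-based recursive partitioning of rankings on
  farm covariates (typically seasonal agroclimatic indices), with a
  Plackett–Luce model per leaf and per-location top-*k* variety
  recommendations.
- **Agroclimatic indices** — longest dry (< 1 mm), wet (> 1 mm) and hot
  (> 35 °C) spells and mean diurnal temperature range over a crop season.
- **Metric fusion** — combining log-worths with a metric trait measured on
  a plot subset: shrunken per-item means regressed on log-worth yield
  "enhanced" estimates that track the true trait values better than the
  sparse metric data alone.
- **Simulation** — exact Plackett–Luce ranking sampling via Gumbel latent
  utilities, full synthetic trials with known truth, and power analysis
  for the number of farms.

## Worked example

```python
from tricot import (TrialTruth, simulate_trial, fit_plackett_luce,
                    risk_assessment)

truth = TrialTruth(("CHECK", "V1", "V2", "V3", "V4", "V5"),
                   (0.0, 0.8, 0.4, 0.0, -0.4, -0.8))
trial = simulate_trial(truth, n_farms=150, seed=42)

res = fit_plackett_luce(trial.rankings)
print(res.summary())
```

```
Plackett-Luce model results
=======================================================
n_rankings:    150    log-likelihood: -239.0208
converged:    True    iterations: 11    max|grad|: 4.64e-14
       log_worth   worth      se
CHECK     0.3203  0.1975  0.1598
V1        0.7701  0.3097  0.1665
V2        0.3496  0.2034  0.1625
V3       -0.0538  0.1359  0.1611
V4       -0.3194  0.1042  0.1641
V5       -1.0668  0.0493  0.1885
```

150 farms ranking triads of 6 entries recover the planted worth ordering:
`log_worth` is the mean-zero log-worth θ, `worth` the normalized
probability of being ranked first among all six, `se` the standard error
of θ. Risk assessment against the check, from 200 Bayesian-bootstrap
refits:

```python
draws = res.bayesian_bootstrap(n_draws=200, seed=42)
print(risk_assessment(draws, "CHECK").round(3))
```

```
       reliability  lower90  upper90
item
CHECK        0.000    0.000    0.000
V1           0.960    0.032    0.909
V2           0.530   -0.388    0.506
V3           0.045   -0.826   -0.038
V4           0.010   -1.059   -0.200
V5           0.000   -1.840   -1.075
```

`reliability` is the fraction of bootstrap draws in which the entry's
log-worth exceeds the check's — V1 beats the check in 96% of draws, with a
90% interval for θ_V1 − θ_CHECK of (0.03, 0.91), so V1 would be advanced;
V2 is indistinguishable from the check. The single-contest probability is
`res.prob_outperform("V1", "CHECK")` → 0.611.

Design efficiency and cost-effectiveness for a 155-farm trial of 11
varieties versus a 300-plot RCBD benchmark:

```python
from tricot import relative_efficiency, equivalent_units, cost_effectiveness

relative_efficiency(11, 3)        # 0.7333...  -> printed 0.73
round(equivalent_units(465, 11, 3))  # 341 EEU from 3 x 155 = 465 plots
cost_effectiveness(1517.18, 341)  # 4.45 currency units per EEU
```

## Command line

The `tricot` console script exposes the same pipeline:
`tricot design`, `tricot efficiency`, `tricot costs`, `tricot simulate`,
`tricot analyze`, `tricot tree`, `tricot recommend`, `tricot report`.
Every stochastic command takes `--seed`; exit codes are 0 (success),
2 (validation failure) and 3 (model failure).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes the closed-form relative efficiency of the 11-variety,
block-size-3 triadic design by generating such a design with the package
and evaluating the efficiency formula, and writes the result as JSON.

## Documentation

See `docs/methods.md` for the statistical models, their assumptions,
default parameters, numerical choices and known limitations.
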