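# Methods

This note documents the models and procedures implemented in the package,
the defaults that matter, the numerical choices, and what the simulation
based tests do and do not establish.

## The tricot data model

A trial distributes *b* packages (blocks) of *k* = 3 masked entries from a
set of *t*. Package slots are labelled A/B/C; the design file carries the
slot→item map so farmer answers can be decoded without revealing entry
names. A best/worst answer over a triad determines a complete strict
ranking (the unmentioned entry is second). Ties are not representable:
the elicitation forces a strict order, and a trait with a missing best or
worst answer yields no ranking rather than a partial one (no imputation).

Rank-breaking expands a ranking of *m* items into its m(m−1)/2 implied
pairwise outcomes. Identifiability of worth estimation requires the
comparison graph to be connected; the package checks weak connectivity of
the undirected co-occurrence graph and refuses disconnected input, naming
the components.

## Trial design

The relative statistical efficiency of an incomplete block design with
block size *k* against complete blocks is taken as the closed form

    E = t/(t−1) · (k−1)/k ,

which assumes plot heterogeneity plays no role (no intra-block correlation
modelling). Plot counts discounted by E give equivalent experimental units
(EEU = E · n_plots); cost-effectiveness is total cost / EEU and design
comparisons report the percent saving 100·(1 − cost_a/cost_b). Reporting
rounds currency to 2 decimals, percentages to integers (half away from
zero) and EEU to the nearest integer; all internal computation is at full
precision. The guaranteed minimum replication in a balanced design is
floor(n_farms · k / t) readings per entry.

Designs are scored by the A-criterion on the information matrix
C = diag(r) − N·Nᵀ/k (N the item×block incidence): the A-score is the mean
of reciprocals of the t−1 nonzero eigenvalues of C, and the canonical
efficiency factor is their harmonic mean divided by the average
replication r̄ = bk/t. For a balanced incomplete block design (BIBD) the
canonical efficiency equals the closed form E exactly; this identity is
used as a cross-check at (t,b) = (4,4) and (7,7).

The generator uses random balanced initialisation (a round-robin deal of
shuffled item sequences, so replication spread ≤ 1, with count-preserving
repair of within-block duplicates) followed by first-improvement hill
climbing on the A-score over single-item swaps between blocks, which
preserve replication; ties are broken on concurrence spread. Default 10
restarts; fully deterministic given the seed. Blocks are then ordered for
sequential distribution by a greedy rule: repeatedly append the block
minimising the running replication spread, ties broken by original block
index. Inside large simulations the package uses the balanced initialiser
without hill climbing — the local search costs O(b²k²)
eigen-decompositions and contributes nothing to the statistical questions
those simulations answer.

## Plackett–Luce worth estimation

Each item has worth w_i = exp(θ_i); a ranking is modelled as sequential
Luce choices without replacement. θ is identified up to an additive
constant; the package constrains mean(θ) = 0 (rather than a reference
item) so per-item uncertainty summaries are symmetric in the items.

Fitting combines Hunter-style minorize–maximize updates (monotone in the
log-likelihood, globally stable) with projected-Newton polishing in the
contrast space once the MM step change falls below 1e-4 (MM alone crawls
when one worth dominates). Convergence tolerance 1e-8 on the
log-likelihood change, iteration cap 500. The covariance of θ is the
pseudo-inverse of the observed information projected onto the mean-zero
subspace.

**Separation.** An item that is never beaten (or never wins a choice
stage) has an infinite-MLE direction. Such items are always flagged in the
results; parameter values are clamped at |θ| ≤ 30 so arithmetic stays
finite. An optional pseudo-item regulariser (a ghost item that beats and
loses to every real item with weight 0.1) keeps estimates finite and is
OFF by default; the power simulation and the metric-fusion pipeline switch
it on because their bootstrap loops must converge for every draw.

**Quasi-variances.** Per-item surrogates q_i are found by least squares on
log(q_i + q_j) against log Var(θ_i − θ_j) over all pairs; the worst-pair
relative error on the variance scale is always reported. The two-item case
is underdetermined (one constraint, two unknowns); the symmetric
minimum-norm solution q_1 = q_2 = v_12/2 is used.

**Bayesian bootstrap.** Ranking weights are drawn from a flat Dirichlet
(gamma(1) draws normalised to sum n), the model is refit per draw from a
warm start at the MLE; draws that fail to converge are excluded with a
reported count. Default 200 draws. The risk-assessment table reports, per
item, the reliability (fraction of draws with θ_item > θ_check) and the
central 90% interval of θ_item − θ_check; the check against itself has
reliability 0 by convention. Quasi-variances and the bootstrap are exposed
independently; risk assessment composes only the bootstrap draws.

**Win rate.** The observed per-ranking win fraction against the check is
provided as `win_rate`; this is an interpretation of the informal notion
(the model-based counterpart is the Luce probability w_i/(w_i+w_check)).

**Rank-breaking caveat.** A Bradley–Terry fit on broken pairs recovers the
same item ordering but treats the three pairs from one triad as
independent, so its nominal standard errors are anti-conservative
(smaller than the Plackett–Luce fit's). The test suite asserts this
direction; p-values from naive rank-breaking should not be trusted.

**Item covariates.** θ = Xβ with X an item×feature matrix of full column
rank, maximised over β by BFGS with the analytic gradient; β's covariance
comes from Xᵀ(−H)X. With saturated one-hot features the implied θ equals
the unconstrained fit.

## Plackett–Luce trees

At each node the model is fitted and per-ranking score contributions (the
gradient of each ranking's log-likelihood at the node estimate) are
computed. For each covariate, a maximally-selected two-sample statistic —
the maximum over candidate thresholds of the squared norm of the left-side
score sum, scaled by n_L(1 − n_L/n) — is calibrated by permutation
(default 199 draws, seeded) and Bonferroni-corrected across covariates.
This deliberately replaces the asymptotic M-fluctuation calibration of
classical model-based recursive partitioning: identical intent, exact at
small n, and far easier to verify. The node splits when the smallest
adjusted p-value is ≤ α (default 0.05), both children hold at least
`minsize` rankings (default 30) and the depth is below `maxdepth`
(default 3, echoing the shallow trees seen in practice). The split point
maximises the summed child log-likelihood over at most 50 quantile-spaced
candidate midpoints. Rows equal to a threshold route left; rows with
missing covariates are dropped with a logged count.

## Agroclimatic indices

Longest in-window runs of dry (precip < 1 mm), wet (precip > 1 mm) and hot
(tmax > 35 °C) days, and mean diurnal temperature range (tmax − tmin).
Thresholds are strict exactly as stated; a day at exactly 1 mm belongs to
neither spell. "Hot" is defined on tmax (whether the original analyses
used tmax or the daily mean is not stated; tmax is the conventional
summer-day definition). The season window is [start, start+length) and
indices are invariant to data outside it. Missing days break runs; an
all-missing input yields spell 0 with a warning.

## Metric fusion

Per-item estimates from a measured plot subset are shrunken means: grand
mean + n_i/(n_i + λ)·(item mean − grand mean), with λ = σ²_e/σ²_g from the
one-way method of moments and a documented fallback λ = 1 when the
between-item variance estimate is non-positive. This reproduces the
shrinkage structure of a one-way mixed-model BLUP without a mixed-model
dependency. Calibration is OLS of these estimates on the log-worths from
the full ranking data; the fitted values are the "enhanced" estimates.

`simulate_fig6` runs the whole pipeline on synthetic trials: true item
effects ~ N(0, σ²_g), plot values add N(0, σ²_e) noise, farms rank their
three plots by observed value (normal noise gives near-PL, not exactly PL,
rankings — an intentional misspecification stress test), and a random plot
subset is "measured" (topped up so every item has ≥ 1 plot). Defaults — 12
items, 150 farms, 30 measured plots, σ_g = σ_e = 1 — reflect a typical
single-season trial; they were fixed once and are not tuned. Two caveats
the tests acknowledge: (i) at σ_e = 0 the subset estimates recover the
truth exactly, but the enhanced estimates cannot reach correlation 1
because log-worth is a monotone, not linear, transform of the trait; (ii)
under σ_g = 0 the measured plots are shared with the ranked plots, so the
regression slope carries a small shared-noise bias and its null
non-significance rate sits slightly above the nominal 5%.

## Simulation and power

`sample_ranking_from_worths` adds independent standard Gumbel noise to the
log-worths and sorts descending, which is exactly Plackett–Luce
distributed (no MCMC); a chi-square goodness-of-fit test against the
closed-form ranking probabilities is part of the acceptance suite.
Simulated trials use balanced designs, uniform(−1,1) coordinates and
standard-normal named covariates; a two-regime truth flips the worth
vector across a covariate threshold to emulate genotype-by-environment
crossover.

The power simulation places one entry `effect_d` latent-noise standard
deviations (Gumbel sd = π/√6) above the rest — an interpretation of
Cohen's d on the latent scale, since the trait scale of the published
sample-size heuristic is not printed. Detection means the bootstrap
reliability of that entry against the best other entry reaches 1 − α.
Only calibration (null rate near α), saturation (large d → 1) and
monotonicity in the number of farms are asserted; the published "95% at
d = 0.8 with 150 farms" figure is not asserted because its latent-scale
definition cannot be pinned down.

## Scaled-down test sizes

Stochastic suites run at sizes chosen to keep the full run well inside a
15-minute single-CPU budget: tree null calibration 50 replicates at n=200,
split recovery 20 replicates at n=400, θ recovery 20 replicates at n=800,
power monotonicity 25 simulations per farm count with 80 bootstrap draws,
fusion properties 100 replicates. Green tests establish calibration and
recovery at these sizes under the stated generative models; they do not
certify behaviour under real-data features the generator omits: farmer
response error beyond the Luce model, missing-not-at-random answers,
spatial correlation between farms, or unequal package sizes.

## Known limitations

- Ties and partial rankings are out of scope; Davidson-type tie parameters
  are not implemented.
- No genomic-relatedness covariance, no raster/spatial extrapolation of
  tree recommendations, no weather-data download.
- The closed-form efficiency ignores plot heterogeneity by assumption.
- Quasi-variances inherit the quality of the observed-information
  covariance; with severe separation they are not meaningful (the
  separation flag should be checked first).
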