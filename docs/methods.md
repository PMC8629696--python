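# Methods

`emanet` estimates dynamic networks from daily diary (EMA) panels: one
prompt per day, ordinal 1–5 item scores, persons observed for a fixed study
window (40 days by default). This note records the statistical model, the
numerical choices, and what the synthetic-data validation does and does not
establish.

## Model

For person *p* with item vector *x_t* on day *t*, the working model is a
multilevel VAR(1):

    x_t = B_p (x_{t-1} − μ_p) + μ_p + ε_t,      ε_t ~ N(0, Σ_w)
    μ_p ~ N(μ_0, Σ_b),   B_p = B + U_p,   U_p[j,k] ~ N(0, τ[j,k]²) independent

Three networks summarize it:

- **Temporal** (directed): the fixed matrix `B`; entry `(j, k)` is the
  average within-person effect of item *k* at day *t−1* on item *j* at day
  *t*, controlling for all other lagged items. The diagonal holds
  autoregressive carry-over. Interpreted as Granger-causal ordering.
- **Contemporaneous** (symmetric): partial correlations of the same-day
  innovations, i.e. the Gaussian graphical model of `Σ_w⁻¹` — dynamics
  faster than the daily sampling interval.
- **Between-subjects** (symmetric): partial correlations among person means,
  the Gaussian graphical model of `Σ_b⁻¹` — trait-like, risk-factor-level
  structure.

Within- and between-person structure can differ, even in sign (Simpson's
paradox); the estimator separates them by within-person centering on each
person's own sample mean.

## Estimation

Two-step node-wise multilevel regression:

1. **Step 1** (per node *j*): linear mixed model of the detrended score on
   all items' within-person-centered lag-1 values (fixed effects + person
   random slopes) and on the grand-mean-centered person means of the *other*
   items (person-level fixed effects), plus a random intercept. Random
   effects are mutually uncorrelated ("orthogonal" estimation, diagonal
   random-effects covariance) — the recommended choice above six nodes,
   keeping the variance-parameter count linear in the node count. The lagged
   fixed effects fill row *j* of the temporal matrix. The person-mean
   coefficients, combined pairwise via
   `ρ̂_jk = mean(β_jk √(s_k²/s_j²), β_kj √(s_j²/s_k²))` with `s_j²` the
   random-intercept variance (the person-level residual variance of node
   *j*), give the between network. The own mean is excluded from the
   predictors: including it makes the person-level regression
   self-predicting (its coefficient tends to 1 and all other between
   coefficients to 0 as T grows), collapsing the between network.
2. **Step 2** (per node *j*): mixed model of the step-1 conditional
   residual on the other nodes' same-day residuals, same orthogonal
   random-effect structure, no person-level predictors. Coefficients are
   combined with the step-2 residual variances into the contemporaneous
   partial correlations.

Missing rows are dropped listwise within each node regression; a missing
day breaks the lag chain (lag-1 means consecutive calendar days). Wald
p-values use the standard normal — with hundreds of persons,
degrees-of-freedom corrections are immaterial.

Optimization: REML via L-BFGS with a Powell backstop (gradient methods
stall on boundary fits where a variance component is estimated at zero,
routine when true random-slope variance is 0), then ML, then a
random-intercept-only model. Each node records which rung converged.

### Known bias

Centering on *sample* means induces Nickell bias in the autoregressive
diagonal, ≈ −(1+φ)/T (≈ −0.026 at T=40, φ=0; measured −0.032 in
simulation). Off-diagonal (cross-lagged) edges are unaffected in practice:
their null rejection rate at α=.05 is calibrated (measured 0.056 over 200+
edge tests), while the diagonal's null test rejects ~44% and should not be
used for inference on carry-over at this T. This is inherent to two-step
sample-mean centering, not specific to this implementation.

## Pre-processing

- **Completion filter**: persons with fewer than 30 completed diaries of 40
  are dropped (a completed diary = a submitted row with ≥1 item answered;
  partial diaries count as completed, a choice users should be aware of).
- **Detrending**: per item, pooled OLS of score on day index and a weekend
  dummy (Saturday/Sunday from the declared weekday of day 1); fitted slopes
  and weekend offsets are subtracted unconditionally, intercepts retained.
  A per-person or significance-gated variant is deliberately not the
  default: a single fixed trend keeps person means meaningful.
- **Centering**: per person/item sample means over observed days; the means
  feed the between level, the deviations feed the within level.

## Item screening

Before estimation, candidate item sets are screened for redundancy: the
correlation matrix must be positive definite with no item a near linear
combination of the others (multiple R² > 0.999), and pairs with r ≥ .5 are
tested against every third item with the Hittner–May–Silver z for dependent
overlapping correlations (Fisher transforms; covariance term evaluated at
the backtransformed mean correlation). A pair is flagged potentially
redundant when fewer than 25% of third-item comparisons differ at α=.05.
Correlations are pooled person-day correlations — the screen runs before
the multilevel decomposition, so within- and between-person correlation are
deliberately mixed at this stage (a documented limitation). Null
calibration of the test was verified by Monte Carlo (rejection rate 0.048
at nominal .05, n=150).

## Centrality and visualization

Raw (unstandardized) strength centralities: outstrength/instrength are
column/row sums of absolute off-diagonal temporal weights (self-loops
excluded); symmetric networks use plain strength. Node placement averages
the Fruchterman–Reingold layouts of the three networks after Procrustes
alignment (force-directed layouts are defined only up to rotation and
reflection, so unaligned averaging would be meaningless). Display
conventions: edges with |w| < .04 hidden (inclusive boundary: |w| = .04 is
drawn), extra emphasis above .05, widths scaled to a shared maximum of .4,
blue positive / red negative, arrowheads only on directed matrices. Hiding
is display-only and never mutates the matrices. Radar charts put one axis
per node in catalog order; overlaid series share one radial scale.

## Replicability protocol

Four subsamples: a random participant split (near-equal halves) and a time
split (first vs second half of days, re-based day indices, weekday of day 1
shifted accordingly; the completion cutoff is rescaled proportionally,
e.g. 15-of-20, since 30-of-20 would be unattainable). Per split pair:
Pearson correlations of vectorized edges (temporal: all directed entries
including the diagonal; symmetric: lower triangle) and of the four
centrality vectors, plus the fraction of full-sample top-k central nodes
re-identified per subsample and metric. Note that this fraction is *not*
monotone in k (replicas can agree on top-1 yet disagree within top-2); it
is 1 at k = n by construction.

## Period trend models

Named day-index intervals (defaults: baseline 1–5, holidays 6–12, 13–19
and 38–end, mitigation 20–37). Per item × period, a linear mixed model
`score ~ day` with a person random intercept (no random slope — these are
descriptive contrasts, and parsimony wins at 7–18 day windows), two-sided
α = .001. Constant outcomes short-circuit to slope 0, p = 1. Weekend
effects are not adjusted for inside periods (holidays and weekends are
confounded by design); the trend removal for the network pipeline is
separate and unaffected.

## Synthetic-data generator

`sample_generative_params` draws an estimable truth; `simulate_panel`
realizes a panel plus a `SimulationTruth` (implied contemporaneous and
between partial correlations from precision-matrix inversion, realized
person parameters). Defaults, chosen to emulate published diary-network
scales:

- grand means 3 (scale midpoint), between-person SD 0.6, innovation SD 0.6
  — person-day scores mostly inside the 1–5 band before discretization;
- autoregressions U(0.15, 0.35); cross-lagged effects ±(0.5–1)×0.15 at the
  requested density, rescaled so spectral radius(B) + 3·max(τ) < 0.9
  (essentially all realized person matrices stationary; per-person draws
  are additionally rejected-and-resampled until spectral radius < 1);
- random-coefficient SD τ = 0.1 per coefficient, independent across
  coefficients — matching the orthogonal estimator so recovery is
  well-posed;
- innovation and between-person covariances from sparse diagonally
  dominant precision matrices sized so the strongest implied contemporaneous
  partials are ≈ .25 and between partials ≈ .35–.45 (between-person
  networks carry the largest effects in published diary studies);
- hub-weighted edge placement (Dirichlet node propensities) in both the
  temporal matrix and the precision matrices: empirical symptom networks
  concentrate influence in a few driver/receiver nodes, and without this
  heterogeneity node centralities are near-tied and centrality-based
  replication statistics are ill-posed at small node counts;
- day-level MCAR missingness with per-person completion probability
  ~ Beta(8, 2) (mean 0.8, matching ~80% retention at the 30-of-40 cutoff)
  — whole diaries go missing, single items do not, mirroring diary
  submission;
- optional discretization (round, clip to [1, 5]); burn-in 50 steps from
  the person mean.

What the generator does **not** emulate: ordinal measurement error beyond
rounding, non-MCAR missingness (e.g. symptom-dependent skipping), regime
switches between study periods (period models are validated on injected
linear trends instead), time-varying or nonlinear dynamics, and item-level
skipping. Passing recovery tests therefore show the estimator is correct
*under its own assumptions*, not that those assumptions hold in any real
diary dataset.

## Validation sizes

Chosen as the package's standard validation settings: oracle equivalence
(mixed model vs pooled OLS in the τ=0 limit, agreement within 0.02) at 6
nodes × 50 persons × 60 days; parameter recovery at 6 nodes × 300 persons
× 40 days, τ=0.1 (temporal and contemporaneous recovery correlation ≥ .9,
between ≥ .8); null calibration over 200+ off-diagonal edge tests at 100
persons; split-half replication at 150 persons per half. The between
network rests on one observation per person, so at 150 persons/half its
replicability is assessed at the edge level; a strength-centrality
correlation across 6 nodes is too unstable at that scale to be a meaningful
criterion (the full-scale study's weakest centrality replication was
likewise at the person level).
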