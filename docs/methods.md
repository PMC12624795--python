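# Methods

This note documents the models, estimators and numerical choices in
`resilnet`, and what the synthetic-data experiments do and do not show.

## Data model and scoring

Input is a long-format panel: one row per participant-year with five
MHI-5 items (integers 0–5, favourable direction; positively-worded items
are assumed pre-harmonized), sociodemographic covariates, and binary
healthcare outcomes. The sum score is rescaled to 0–100 (sum × 4);
scores strictly below 60 classify a record as mentally unhealthy, so 60
itself is healthy. Missing items are never imputed: any record with an
incomplete item set is removed listwise before network estimation.
Eligibility further requires age ≥ 18 and, by default, gender in
{male, female} (the panel offered "other" only in its final wave, with
too few respondents to estimate separate effects; the filter is
configurable). Item-level binarization marks a symptom active iff the
favourable item score is ≤ 2 — the item-scale analogue of the 60% sum
cutoff. The threshold is a parameter; no claim is made that the original
analyses used exactly this rule, which is not publicly documented.

## Ising network estimation (eLasso)

For each survey year the binary symptom matrix X (n × 5) yields one
group-level Ising model with node thresholds τ and symmetric edge
weights W. Estimation is nodewise: each node j is regressed on the
remaining nodes by ℓ1-penalized logistic regression along a descending
λ path of 100 log-spaced values from λ_max (the smallest λ with an empty
model for that node) to 0.01·λ_max. Per path point the extended BIC

    EBIC_γ = −2·loglik + df·ln n + 2γ·df·ln(K−1),  γ = 0.25

is evaluated at the penalized estimates, with df = number of nonzero
coefficients; the minimizing λ is selected, ties going to the larger λ
(sparser model). τ_j is the selected intercept. Directed coefficients
are symmetrized by the AND rule (edge kept only if selected in both
regressions; weight = mean of the two coefficients) or optionally the OR
rule. Predictors are left on their natural 0/1 scale (no
standardization; all predictors are binary and comparable).

Numerics: the nodewise problems are solved on the 2⁵ = 32 aggregated
response patterns — sufficient statistics for every likelihood involved —
so one network fit costs O(2^K) independent of n. The solver is
IRLS with inner coordinate descent (working weights floored at 1e-5,
glmnet-style), path points converged to 1e-5 and the selected model
refit to the requested tolerance (default 1e-7); coefficients below
1e-8 in magnitude are flushed to exact zero so a model's df is never
inflated by floating-point residue. At λ = 0 the solver reproduces the
unpenalized logistic MLE (validated against statsmodels to 1e-6).
A constant symptom column is a hard error naming the node; implausibly
large coefficients trigger a separation warning (the finite λ path keeps
them bounded).

## Stability landscape and stability difference

The Boltzmann distribution P(x) ∝ exp(Στᵢxᵢ + ΣW_ij xᵢxⱼ) is computed by
exact enumeration (refused beyond K = 20 rather than silently
approximated) and projected onto n = Σxᵢ, the number of active symptoms.
The potential is U(n) = −ln P(n), in nats. Local minima of U are
attractors; plateaus collapse to a single minimum at their smallest n.
With the healthy region n ≤ 2 and unhealthy region n ≥ 3 (the item-count
analogue of the 60% cutoff, configurable), the stability difference is

    S = min_{n≥3} U(n) − min_{n≤2} U(n).

Positive S means the healthy regional minimum is the deeper one; any
shared barrier between the two regional minima cancels in the
difference, and S is invariant to additive shifts of U. Exact
enumeration makes S deterministic given the network. The cited
landscape literature does not pin down one canonical formula for
"stability of a state"; regional minima of U are used here because they
are fully specified, testable, and consistent with the depth-of-valley
reading.

## BCa bootstrap contrast

Change in S between two years is tested by resampling participants with
replacement independently within each year and refitting the entire
pipeline (eLasso → landscape → S) per replicate, θ* = S_b* − S_a*,
B = 1000 by default. Because the statistic depends on the data only
through the 32 pattern counts, resampling is implemented as a
multinomial draw over pattern counts — distributionally identical to row
resampling and orders of magnitude faster. Replicates producing a
constant symptom column are redrawn (counted; > 10% redraws aborts).

The interval is bias-corrected and accelerated: z₀ = Φ⁻¹(#{θ* < θ̂}/B)
with ties counted half (the fraction clamped to [0.5/B, 1−0.5/B]);
acceleration a from the jackknife skewness formula over grouped
(delete-d) jackknife values, G = 100 random participant groups per year
with the other year held at its full sample — O(100) refits per year
instead of O(n), with negligible effect on a for a smooth statistic.
Quantiles use linear interpolation (Hyndman–Fan type 7, numpy default),
so z₀ = 0, a = 0 reduces exactly to the percentile interval. The p-value
is the smallest α whose (1−α) interval excludes 0, found by bisection to
1e-4 and capped at 1.0. Replicate randomness derives from one master
seed; identical seeds give bit-identical results. The resampling unit is
the participant (household clustering is out of scope).

## Interrupted time series

Binary outcomes are modelled as logit P(y_it = 1) = x_it'β + u_i with a
participant random intercept u_i ~ N(0, σ²). Time is t = year −
campaign_start (2016), post = 1{year ≥ campaign_start}; the trend change
is the t×post coefficient. A post main effect (level change) is off by
default — the design is a single trend line with a slope break — and can
be switched on. The yearly business-cycle indicator joins by calendar
year and enters standardized over the window; a constant series is
dropped (it would duplicate the intercept). Subgroup analyses add
reference-coded main effects, subgroup×t, and subgroup×t×post
(the differential trend change). The missing 2014 wave needs no special
handling: calendar-time coding leaves t for all other years unchanged.
The primary window is 2012–2019 (pre-COVID); full-window runs are
exploratory.

The marginal likelihood integrates u_i by Gauss–Hermite quadrature
(15 nodes; one-dimensional, so effectively exact), maximized by L-BFGS-B
with the analytic gradient, σ bounded at [0, 25]. Standard errors come
from the observed information (central differences of the analytic
gradient); inference is Wald (z, two-sided p), matching the summary
convention of standard mixed-model software. When the true
random-intercept variance is zero the boundary estimate σ̂ = 0 obtains
with probability ≈ ½ in finite samples, and the fixed effects then equal
the ordinary logistic MLE (validated to 1e-3; also cross-validated
against lme4's `glmer` with adaptive quadrature on a small panel).
Non-convergence is flagged, never silently reported.

## Synthetic panel generator

The generator emulates the structure of a yearly internet panel so every
stage has known truth:

- **Symptoms.** One Ising model per survey year; the default yearly
  (mean τ, connectivity) trajectory follows the published study-period
  values (2012: −3.25, 12.94 … 2022: −3.78, 15.29; 2014 absent), with a
  fixed zero-sum node-heterogeneity pattern scaled to the observed 2012
  between-node SD (0.97) and uniform edge weights (connectivity / 10).
  Experienced social support shifts all thresholds (+0.5 low, −0.5 high
  by default), giving subgroup analyses real signal. States are drawn
  from the exact 32-state distribution (no burn-in); a single-site Gibbs
  sampler is provided as a cross-check.
- **Items.** Active symptoms draw uniformly from {0,1,2}, inactive from
  {3,4,5} — the simplest mechanism that makes binarization an exact
  round-trip. It is *not* a model of real MHI-5 item psychometrics; the
  implied unhealthy prevalence (≈ 18.6% in 2012, falling to ≈ 13%,
  computable exactly by `exact_unhealthy_probability`) tracks, but does
  not reproduce, the published prevalence path.
- **Panel dynamics.** Participants survive each calendar year with
  probability 0.90 (per elapsed year, also across 2014); refreshment
  restores the yearly target (default 5000; analyses in this repository
  use scaled-down targets of 400–3000, stated per script). Ages 16–17
  (2%) and a 2022-only "other" gender option (0.35%) exercise the
  eligibility filters; 5% of records miss the whole item block and 0.5%
  of items are missing singly, exercising listwise deletion.
- **Outcomes.** Healthcare use and medication use follow logistic models
  with participant random intercepts (σ = 1.2), a yearly AR(1)
  business-cycle covariate (φ = 0.7, stationary start), and trend-change
  coefficients defaulting to published effect sizes: −0.31 on medication
  use, and differential healthcare-use trend changes of −0.31 (middle vs
  low support) and +0.67 (non-Dutch LMIC vs Dutch). The
  mentally-unhealthy outcome is never injected directly — it emerges
  from the symptom model, so its trend change is a genuine end-to-end
  consequence of the τ trajectory.

Passing tests on these panels show the estimators recover known
generating structure under MCAR missingness, homogeneous-edge networks
and clean logistic outcome processes. They do not certify behaviour
under informative dropout, item-level measurement models, household
clustering, or real-world confounding.

## Problem sizes and determinism

Statistical acceptance checks run at deliberately scaled sizes chosen to
make Monte Carlo bands tight enough to be meaningful: landscape/sampler
agreement at 2×10⁵ draws; eLasso recovery at n = 10⁴ (20 seeds for the
null); BCa coverage at 500 Gaussian-mean replications and 200 null-panel
simulations (n = 2000, B = 300); ITS recovery over 50 seeds at n = 3000
participants and size over 200 null replications at n = 400. All
simulations, bootstraps and the CLI flow from explicit integer seeds;
rerunning any artifact-producing command with the same seed reproduces
the files byte for byte.

## Known limitations

- Resilience proxies are estimated per year from cross-sections; no
  within-person dynamics are modelled.
- The stability difference uses regional minima of U; basin-integrated
  alternatives would differ in degenerate landscapes.
- The grouped jackknife acceleration is an approximation to
  leave-one-out; with G = 100 the effect on the interval is well below
  Monte Carlo noise at B ≤ 1000.
- EBIC selection at γ = 0.25 is conservative by design: at n ≈ 2500 per
  year it prunes weak true edges before it admits false ones.
- Survey weighting, household clustering and imputation are explicitly
  out of scope.
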