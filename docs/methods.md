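# Methods

## Task design and covariates

The design crosses 2 outcome contexts (gain, loss) x 2 baselines (0,
100 days) x 2 delays (7, 30 days) x 3 magnitudes (100, 400, 1000
tokens) x 6 premium rates (5%..30%) = 144 cells. The literature the
task descends from states the factor levels but not how magnitude and
rate compose into the two options; we construct the sooner option as
the base magnitude delivered at the baseline and the later option as
the base magnitude times (1 + rate) delivered after the additional
delay, in both contexts (negative amounts in the loss context: a
smaller loss paid earlier vs a larger loss paid later). The money
difference `|later| - |sooner| = magnitude x rate` is therefore
unsigned in both contexts; directional context effects live in the
signed drift coefficients.

Drift covariates (money difference, delay difference, baseline coded
0/1) are z-scored across the 144 cells with the population SD. Raw
token/day units would make drift coefficients of order 1e-3;
standardization puts them on the ~0.1 scale on which such coefficients
are conventionally reported and makes them comparable across
covariates. The interaction term of the largest model is the product of
the standardized delay and baseline covariates.

## Diffusion process and likelihood

Within-trial noise is fixed at sigma = 1, so drift and boundary are
expressed in that scale; the accumulator starts at `z * a` between
absorbing boundaries 0 and `a`, the upper boundary is the later/delayed
option in both contexts, and the response time is the first-passage
time plus the non-decision time `t_nd`. The trial likelihood is the
Wiener first-passage-time density computed by the classic dual series
expansion with automatic small-time/large-time regime selection at
absolute truncation error 1e-7; the lower-boundary density is the
upper-boundary density under the reflection (v -> -v, z -> 1 - z). No
inter-trial variability parameters (sv, sz, st) are included.

Forward simulation uses Euler-Maruyama at dt = 1 ms (configurable)
inside a 10 s response window. Naive discrete-time first-exit tests are
biased at order sqrt(dt) because the path can cross and re-cross a
boundary within a step; we resolve within-step crossings with the
Brownian-bridge crossing probability exp(-2 d0 d1 / dt) for each
boundary (d0, d1 the endpoint distances). With this correction the
dt = 1 ms simulator matches the closed-form absorption
probability within Monte-Carlo error and the analytic RT distribution
at Kolmogorov-Smirnov distance < 0.01 at n = 50,000 (verified in the
acceptance suite, including a dt-halving refinement check).

## Hierarchical model and priors

Contexts are estimated independently (a config-free default; the
alternative of sharing z and t_nd across contexts is structurally
possible but not implemented, as nothing in the analysis requires it).
For each context, each parameter is sampled on an unconstrained scale —
log a, logit z, log t_nd, identity for the drift coefficients — where
participant values are exchangeable Normal(mu, sigma^2) draws.
Hyperpriors: mu_log_a ~ N(log 2, 1.5^2), mu_logit_z ~ N(0, 1),
mu_log_tnd ~ N(log 0.4, 1.5^2), drift-coefficient means ~ N(0, 3^2);
all group SDs ~ Half-Normal(1). These are weakly informative on the
scales behavioral DDM fits occupy. Placing the hierarchy uniformly on
the unconstrained scale (rather than mixing Gamma/truncated-Normal
families per parameter) buys exact conjugate Gibbs updates for every
group mean and a single sampler kernel; the implied log-normal
population law for a and t_nd is standard practice in hierarchical DDM
software.

## Sampler

Gradient-based samplers are awkward here because the series-truncated
likelihood is expensive to differentiate robustly, so estimation uses
adaptive Metropolis-within-Gibbs (numba-compiled):

* participant-level: single-site Gaussian random-walk updates (scales
  adapted toward 44% acceptance) plus full-vector proposals whose
  covariance is the chain's own burn-in sample covariance scaled by
  2.38^2/K (Haario adaptive Metropolis, ~25% target). The joint moves
  matter: starting point, baseline drift and non-decision time are
  strongly correlated for skewed choice splits and defeat purely
  coordinate-wise sampling.
* participant-level independence proposals drawn from the current
  group law, both full-vector and per-coordinate (MH ratio = likelihood
  ratio when the proposal is the prior). The full-vector form is the
  mode-jumping move — without it a chain occasionally traps one
  participant's block in a spurious non-decision-time basin and R-hat
  diverges; the per-coordinate form is near-rejection-free for weakly
  likelihood-identified coordinates such as the starting point, whose
  full conditionals are prior-dominated.
* group means: exact conjugate Gibbs.
* group SDs: random-walk Metropolis on the log scale in the centered
  conditional, plus interweaved non-centered moves (an
  ancillarity-sufficiency interweaving strategy): a scale move that
  redraws log sigma with every participant deviation rescaled
  accordingly, and a translation move that shifts mu together with all
  participant values. Both interweaved coordinates are updated by slice
  sampling (stepping-out/shrinkage), which is rejection-free and
  self-tuning where random-walk proposals leave too little effective
  sample size. Without the interweaving the weakly-identified
  coordinates (participant z, beta_0) couple to their group SDs in a
  funnel and split-chain R-hat stalls around 1.02-1.16; with it a
  4-chain, 2,000-iteration run reaches max R-hat <= 1.01.

All adaptation happens during burn-in and is frozen afterwards, so the
post-burn-in kernel is a valid fixed MCMC kernel. `n_draws` counts
total iterations per chain of which `n_burn` are discarded (the
samples/burn-in convention of the hierarchical-DDM literature).
Per-chain seeds are spawned deterministically from the estimator seed;
identical seeds give bit-identical traces.

Convergence is gated at max split-chain R-hat <= 1.01 over all sampled
parameters (group-level locations/scales on the sampling scale and
participant-level parameters on their natural scales). R-hat is the
classical split-chain Gelman-Rubin statistic; the implementation is
cross-checked against ArviZ's split method in the tests.

## DIC

DIC = mean posterior deviance + p_D with p_D = D_bar - D(theta_bar),
where theta_bar is the posterior mean of the natural-scale
participant-level parameters mapped back to the sampling scale for
evaluation. DIC is parameterization-dependent; the natural-scale mean
mirrors common reporting practice. The comparison table reports the
delta against the best model and against the predecessor in the nested
M1..M5 order, because published tables use both conventions
inconsistently and the two differ whenever the ranking is not the
nesting order.

## Synthetic data generator

The generator is the study-conditions oracle for everything downstream.
Group centers encode the qualitative structure the analysis targets,
anchored to reported group x context means where available: boundary
3.168 (gain, both groups), 3.450/3.100 (loss, control/SUD-like); start
bias 0.512 gain / 0.484 loss; reward sensitivity 0.191/0.130 (gain),
-0.086/-0.051 (loss); time sensitivity -0.170/-0.131 (gain), 0.083
(loss, both). Baseline drift is under-determined by published summaries
(only context means plus the observation that the SUD-like group shows
almost no context shift); we use control 0.33/-0.42 and SUD -0.10/-0.10,
which reproduce the context means at the study's 86/100 group weighting.
Non-decision time (unreported) defaults to 0.5 s. Per-participant
spreads default to 20% of the center magnitude with floors (0.03 for
drift coefficients, 0.04 for z, 0.08 s for t_nd) — the study reports
only CIs of means, so the spreads are the generator's assumption, and
parameter-recovery results should be read conditional on them.

An optional contamination fraction (default 1%) replaces trials with
fast random guesses (RT < 100 ms) to exercise the exclusion filter,
emulating the ~2.4% fast-guess rate such tasks produce in practice.
What the generator does **not** emulate: session/fatigue dynamics,
left/right position effects, demographic covariates, incentive-type
effects, and any deviation of real participants from the DDM itself —
passing recovery tests therefore demonstrates correctness of the
estimation machinery, not adequacy of the model for any particular real
dataset.

Hyperbolic-discounting agents (for testing the discounting module in
isolation) choose by a logistic function of the difference in
discounted subjective values, each option discounted over its own
delivery delay (baseline for the sooner option, baseline + delay for
the later one); their RTs are log-normal nuisance values because the
discounting analysis ignores RT.

## Discount-rate estimation

A deterministic value-comparison rule has zero gradient in k on binary
choices, so the "nonlinear least squares" fit is posed with a logistic
link: predicted P(later) = sigmoid((V_later - V_sooner)/tau) with the
temperature tau profiled per participant, minimizing the summed squared
residual against the 0/1 choices. k is bounded to [1e-5, 10] per day
and optimized by multi-start (50-point log-spaced grid with profiled
tau, top-3 starts refined jointly by L-BFGS-B). All-identical choice
patterns carry no discounting signal and are pinned to the bound that
predicts the pattern, flagged, and excluded from group tests.

Group tests compare ln(k) between groups with a pooled-variance t-test
(Welch optional) and pooled-SD Cohen's d, at participant level. Some
reports print lnk on a positive scale inconsistent with ln of a
per-day rate < 1 (plausibly a different time or money unit); since any
monotone affine transform leaves the test statistics unchanged, the
module emits native ln(k) plus a documented shifted variant and takes
no position on the original unit.

## Exclusion rules

Strict inequalities per the usual wording: RT *below* 100 ms excluded
as fast guesses, decisions *exceeding* 10,000 ms (or timeout-marked
rows) excluded; exactly 100 ms and exactly 10,000 ms are retained.
Counts always reconcile (retained + fast + timeout = total); report
percentages are rounded half-up to two decimals. Malformed input rows
are collected and counted, never silently dropped; duplicate
(participant, condition) pairs are a hard error.

## Posterior predictive checks

For each of n evenly-thinned posterior draws the full design is
re-simulated at the drawn participant-level parameters. Per group x
context cell the report pairs each observed statistic — later-choice
proportion and RT deciles {10, 30, 50, 70, 90}% per boundary — with its
predictive interval and a two-sided predictive p-value (doubled minimum
tail, capped at 1). These statistics are a quantitative reduction of
the usual distribution-overlay figures.

## Group statistics

Reported group analyses of this design are univariate 2 (group,
between) x 2 (context, within) tests per parameter, so the module runs
a per-parameter mixed-design ANOVA (pingouin backend, verified against
direct sums-of-squares arithmetic in the tests) with partial
eta-squared, plus two-sample simple-effect contrasts with pooled-SD
Cohen's d; Bonferroni families (number of parameters, or number of
contrasts) are recorded in the output. Inputs are posterior means of
participant-level parameters — the conventional two-stage practice; a
fully Bayesian contrast on the group-mean posterior is available via
`HierarchicalDDM.group_mean_draws`.

## Problem sizes used in the checked examples

The acceptance suite runs desk-scale versions of the study design,
chosen as the smallest sizes at which each property is cleanly
decidable: convergence at 20 participants x 144 trials with 4 chains x
2,000 iterations; group-parameter recovery at 20 participants per group
(one replicate, 2 chains x 1,200); DIC model recovery at 6 participants
x 72 gain trials over 10 replicates; discounting recovery over 20
seeded agents; oracle grids at 20,000-50,000 simulated trials per
setting. Full-study sizes (86/100 participants, 10,000 iterations) are
plain configuration changes.

## Known limitations

* Contexts are always estimated independently; no shared-parameter
  variant.
* DIC is the only model-comparison criterion (WAIC/LOO out of scope).
* No inter-trial variability parameters; collapsing bounds and race
  models out of scope.
* Recovery tolerances are conditional on the generator's assumed
  heterogeneity; relative tolerances are hard to satisfy for
  parameters whose generative magnitude is near zero (e.g. the
  SUD-like loss-context reward sensitivity of -0.051), which is why
  recovery is assessed by the median across group x context cells.
* The trial-level (rather than participant-level) degrees of freedom
  that some published lnk t-tests imply are not reproduced; the module
  tests at participant level, the statistically defensible unit.
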