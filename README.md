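# driftchoice

Hierarchical drift-diffusion and delay-discounting analysis of
intertemporal choice in gain and loss contexts.

## The scientific problem

Intertemporal choice — picking between a smaller-sooner and a
larger-later outcome — is a core behavioral probe of impulsivity, and a
signature deficit in substance use disorder (SUD). Classic analyses
summarize behavior with a single hyperbolic discount rate
`V = A / (1 + kD)`, which says *whether* someone is impulsive but not
*why*. Sequential-sampling models expose the mechanism: in the
drift-diffusion model (DDM), noisy evidence accumulates between two
absorbing boundaries (here, upper = the delayed option), and the first
boundary hit fixes both the choice and its response time. The boundary
separation `a` captures caution, the relative start `z` a prior bias,
the non-decision time `t` encoding/motor latency, and the drift rate
`v` the speed and direction of evidence integration.

This package implements, as a tested and reusable pipeline, the full
analysis for a two-group (control vs SUD-like) study in which each
participant completes a 144-cell factorial task — 2 outcome contexts
(gain/loss) x 2 time baselines (now / 100 days) x 2 delays (7 / 30
days) x 3 magnitudes (100/400/1000 tokens) x 6 premium rates (5–30%) —
with trial-level drift regression

    v = beta_0 + beta_reward * MoneyDiff + beta_time * DelayDiff
              + beta_time-base * DelayBaseline

on covariates standardized across the design cells. The pipeline
covers: factorial design construction; synthetic-data generation from
group-structured diffusion parameters (the raw study data are not
public, so simulated studies with known ground truth drive all
testing); exclusion-rule preprocessing (fast guesses < 100 ms, 10 s
timeouts); per-participant hyperbolic discount-rate estimation with
group lnk contrasts; hierarchical Bayesian estimation of five nested
drift models by adaptive Metropolis-within-Gibbs MCMC with split-chain
R-hat diagnostics; DIC model comparison; posterior predictive checks;
and the group x context statistics layer (mixed ANOVA, Bonferroni,
Cohen's d, partial eta-squared).

## Worked example

```python
from driftchoice import simulate
from driftchoice.preprocessing import apply_exclusions
from driftchoice.inference import HierarchicalDDM, dic, rhat

trials, truth = simulate.simulate_study(
    simulate.control_like_spec(8), simulate.sud_like_spec(8), rng_seed=1)
retained, report = apply_exclusions(trials)
print(report.pct_excluded)           # 3.39  (% fast guesses + timeouts)

fit = HierarchicalDDM(model="M3", n_draws=800, n_burn=400,
                      n_chains=2, seed=0).fit(
    retained[retained["group"] == "control"])
print(float(rhat(fit.trace_).max())) # 1.021 (short demo run; use the
                                     #        full settings for inference)
gm = fit.group_mean_summary()
print(gm[gm["parameter"] == "a"])
# context parameter     mean       sd    ci2.5   ci97.5
#    gain         a 2.965114 0.063285 2.849019 3.096862
#    loss         a 3.557180 0.088119 3.385418 3.737035
```

The group-mean boundary estimates track the generative centers (gain
3.168, loss 3.450 for the control-like group) up to the sampling noise
of an 8-participant draw from the population, the loss boundary sits
credibly above the gain boundary as generated, and the exclusion report
reproduces the preprocessing bookkeeping exactly. A full run — including DIC comparison of the five
drift models, posterior predictive checks and the group-contrast
tables — is one command:

```
driftchoice run-all --output-dir run1 --seed 1 --n-control 8 --n-sud 8
driftchoice report run1
```

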