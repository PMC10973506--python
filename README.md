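# trialborrow

Bayesian interim monitoring of randomized controlled trials with dynamic
borrowing from propensity-matched historical controls, alongside the
conventional group-sequential comparator.

## The problem

Phase III trials with a time-to-event endpoint take years to mature.
`trialborrow` implements an interim-analysis workflow for this setting,
motivated by induction trials in adult acute myeloid leukemia (AML): a
1:1 randomized trial (~390 patients per arm) is assessed at scheduled
enrollment milestones (150/300/450/600 patients), with the concurrent
control arm *reinforced* by controls from a preceding trial that used the
same control treatment.  At each interim the package reports a Bayesian
benefit-risk summary across five endpoints, and the same data can be held
against a classical error-spending boundary design.

## What it computes

**Event-free survival (EFS)** is modelled with a Weibull proportional-hazards
likelihood, hazard h(t) = ν t^(ν−1) exp(η), with

- η = μ_c + β·1[experimental] for randomized patients, η = μ_h for
  historical controls, HR = e^β;
- a *commensurate prior* μ_c ~ N(μ_h, σ_τ²) linking the two control
  strata: σ_τ → 0 pools them, σ_τ → ∞ ignores the historical data, and in
  adaptive mode σ_τ gets a half-normal hyperprior so the degree of
  borrowing is learned from the control/historical concordance;
- self-contained adaptive Metropolis-within-Gibbs MCMC (default 3 chains ×
  50,000 iterations, first half warmup), Gelman-Rubin R̂ convergence
  diagnostics, and posterior probabilities P(HR < 0.76), P(HR < 0.87),
  P(HR < 1) — assumed, moderate and any benefit.

**Binary endpoints** — complete remission (CR), MRD-negative CR, death
within 60 days, grade 4–5 adverse events — use beta-binomial models with
the same commensurate structure on the logit scale, summarising the
treatment difference Δ = p_exp − p_ctrl and P(Δ > 0).

**Historical controls** are selected by logistic-regression propensity
scores on age and ELN 2017 risk, matched 1:1 to concurrent controls by
greedy nearest neighbour.

**The group-sequential comparator** provides Schoenfeld event counts,
Lan-DeMets O'Brien-Fleming α- and β-spending, efficacy and non-binding
futility z/HR boundaries solved by recursive numerical integration, exact
crossing probabilities, and simulation-based log-rank operating
characteristics.

A synthetic-data module generates patient-level trial tables with the
full structure the analysis assumes (staggered accrual, Weibull EFS,
administrative censoring at interim locks, Table-style endpoint rates),
so every pipeline stage is testable end to end.

## Worked example

```python
from trialborrow import (TrialConfig, generate_trial, fit_propensity,
                         greedy_match, run_interim_schedule,
                         BorrowConfig, MCMCConfig, reports_to_frame)

data = generate_trial(TrialConfig(), seed=1)          # null synthetic trial
fit = fit_propensity([r for r in data.records if r.arm == "control"])
pairs = greedy_match(fit, n_pairs=300)
reports = run_interim_schedule(
    data, pairs, milestones=(150, 300, 450, 600),
    borrow=BorrowConfig(mode="adaptive"),
    mcmc=MCMCConfig(n_chains=2, n_iter=4000, seed=10))
print(reports_to_frame(reports).head())
```

Running `python examples/05_interim_schedule.py` (which executes exactly
this) prints:

```
interim 150: cutoff 7.7 mo, median follow-up 3.8 mo, 20 EFS events, futility signal: False
interim 300: cutoff 14.0 mo, median follow-up 6.3 mo, 51 EFS events, futility signal: False
interim 450: cutoff 21.1 mo, median follow-up 10.2 mo, 93 EFS events, futility signal: False
interim 600: cutoff 27.7 mo, median follow-up 13.7 mo, 145 EFS events, futility signal: True

 interim endpoint  median   lo95   hi95  prob_benefit
     150      efs   0.918  0.368  2.049         0.332
     150       cr  -0.030 -0.148  0.070         0.275
     ...
     600      efs   1.002  0.717  1.441         0.046
     600       cr  -0.059 -0.114 -0.003         0.021
```

Events accumulate across interims and the credible intervals narrow.  For
this null trial (true HR = 1) the EFS `prob_benefit` column — P(HR < 0.76)
— erodes as evidence accrues, the binary treatment differences sit near
zero, and at the final interim the advisory futility flag fires because
P(HR < 0.76) has fallen below 0.05: the assumed design benefit has become
implausible.

The other example scripts cover data generation and interim locks (01),
propensity matching and balance (02), CR with and without borrowing (03),
the EFS model at a single interim (04), and the group-sequential design,
its calibrated event inflation and simulated power (06).

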