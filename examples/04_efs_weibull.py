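"""Bayesian Weibull proportional-hazards analysis of event-free survival
at an interim lock, with and without commensurate borrowing.

Prints the posterior hazard ratio (HR, experimental vs control) and the
threshold probabilities P(HR < 0.76) (assumed design benefit),
P(HR < 0.87) (moderate benefit) and P(HR < 1) (any benefit).
"""

from trialborrow import (BorrowConfig, MCMCConfig, TrialConfig,
                         cut_at_milestone, fit_weibull_borrow,
                         generate_trial)

data = generate_trial(TrialConfig(), seed=1)
interim = cut_at_milestone(data, 450)
mcmc = MCMCConfig(n_chains=3, n_iter=10_000, seed=3)


def show(label, summary):
    lo, hi = summary.ci95["hr"]
    probs = summary.threshold_probs["hr"]
    print(f"{label}: HR {summary.median['hr']:.2f} "
          f"(95% CrI {lo:.2f}-{hi:.2f}); "
          f"P(HR<0.76) {100*probs[0.76]:.1f}%, "
          f"P(HR<0.87) {100*probs[0.87]:.1f}%, "
          f"P(HR<1) {100*probs[1.0]:.1f}%")


with_borrow = fit_weibull_borrow(interim, BorrowConfig(mode="adaptive"), mcmc)
show("adaptive borrowing   ", with_borrow)

no_borrow = fit_weibull_borrow(
    interim.subset(lambda r: r.source == "current"),
    BorrowConfig(mode="none"), mcmc)
show("concurrent data only ", no_borrow)

print("\nthis synthetic trial is null (true HR = 1): any apparent benefit "
      "is sampling noise at an immature interim, and borrowing tightens "
      "the credible interval")
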