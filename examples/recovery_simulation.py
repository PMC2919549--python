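"""Which estimator recovers the incidence density ratio from a survey?

Draws replicated cross-sections of a steady-state population with a true
IDR of 3 and equal outcome durations, then compares the mean PR and POR
estimates against the causal parameter.
"""

from epiconv import SimulationConfig, markov_microsim_prevalence, recovery_experiment

config = SimulationConfig(
    id1=1.0, id0=1 / 3, t1_bar=1.0, t0_bar=1.0,
    n_per_stratum=100_000, reps=200, seed=42,
)
report = recovery_experiment(config)
print(f"true IDR = {report.true_idr:.3f}, true PR = {report.true_pr:.3f}")
print(f"mean POR-hat = {report.mean_por_hat:.4f} (sd {report.sd_por_hat:.4f})")
print(f"mean PR-hat  = {report.mean_pr_hat:.4f} (sd {report.sd_pr_hat:.4f})")
# The cross-product (POR) estimate sits on the IDR; the PR estimate sits on
# the prevalence ratio 2.0 and is biased for the IDR by the odds/risk gap.

# Independent check of the equilibrium itself: a brute-force two-state
# continuous-time simulation reproduces P = ID*T/(ID*T+1).
p_sim = markov_microsim_prevalence(
    1 / 3, 1.0, horizon=20.0, burn_in=10.0, n_individuals=50_000, seed=42
)
print(f"microsimulated unexposed prevalence = {p_sim:.4f} (closed form 0.25)")
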