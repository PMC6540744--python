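"""Measure selection-conditional bias and MSE of the four estimators.

Simulates two-stage trials with k = 3 identical arms (true means all zero,
unit variance, n = m = 10), selects the arm with the largest stage-1 mean,
and compares estimators of the selected arm's mean.  Errors are measured
against the true mean of whichever arm won, so any systematic deviation is
pure selection bias.

10 000 replicates keep this quick; the reference studies use 100 000.
"""
from selectest import SimulationScenario, evaluate_estimators

scenario = SimulationScenario(
    true_means=(0.0, 0.0, 0.0),
    sigma2=1.0,
    stage1_sizes=(10, 10, 10),
    stage2_sizes={1: 10},
    select_ranks=(1,),
    n_reps=10_000,
    seed=7,
)
result = evaluate_estimators(
    scenario, ["mle", "stage2", "umvcue_unknown", "umvcue_known"],
    plug_in_sigma2="pooled")

print(f"{'estimator':>16} {'bias':>9} {'(3 MC SE)':>10} {'MSE':>9}")
for (tag, rank), cell in sorted(result.table.items()):
    print(f"{tag:>16} {cell['bias']:>+9.4f} {3 * cell['mc_se_bias']:>10.4f} "
          f"{cell['mse']:>9.4f}")

# Expected pattern: the MLE is biased upward by ~0.13 (it pools the winning
# stage-1 data) but has the smallest MSE (~0.057); stage-2 alone is unbiased
# with the largest MSE (sigma^2/m = 0.1); both UMVCUEs are unbiased with MSE
# ~0.074 — about 30% above the MLE but 26% below stage 2.
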