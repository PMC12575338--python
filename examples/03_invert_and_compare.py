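"""Full inference loop on one synthetic dataset.

Generates ground-truth data from the identical-observers reduced model
(all cross-scale difference in the dynamics), inverts the full model by
variational Laplace, reduces to both hypotheses by zero-variance
Bayesian model reduction and prints the resulting model probabilities.
"""

from sysobs import NoiseSpec
from sysobs.workflows import ExperimentConfig, analyze_pair, generate_dataset

config = ExperimentConfig()
scenario = "identical_observers"  # truth: delta_a = 0.5, delta_k = 0

driver, observed, truth = generate_dataset(config, scenario, "none", seed=1)
posterior, comparison, free_energies = analyze_pair(
    observed, driver, config.params, NoiseSpec(mode="none"), config.settings
)

print(f"ground truth: delta_a = {truth.delta_a}, delta_k = {truth.delta_k}")
print("posterior over the deviations:")
for label in ("delta_a", "delta_k"):
    i = posterior.index(label)
    print(f"  {label}: {posterior.mean[i]: .3f} +/- {posterior.marginal_sd(label):.3f}")
print(f"full-model free energy: {posterior.free_energy:.1f} nats")
print()
print("reduced-model comparison (free energies relative to the minimum):")
for lbl, f, p in zip(comparison.labels, comparison.free_energies,
                     comparison.probabilities):
    print(f"  {lbl:21s}  F_rel = {f:8.1f}   p = {p:.3g}")
print(f"winner: {comparison.winner}  "
      f"(losing-model probability {comparison.losing_probability:.3g})")
print()
print("A posterior concentrated on delta_a with delta_k ~ 0 means the data")
print("are explained by different dynamics seen through identical observers,")
print("and model reduction assigns essentially all probability to that view.")
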