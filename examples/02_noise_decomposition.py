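"""Decompose the observed cross-scale difference into its two sources.

The rate of change of (h_mu - h_M) splits into a degenerate term, which
mixes system and observer properties, and an observer-only term driven
by the state noise passing through the observer sensitivities.  The
printed RMS values show that with identical systems (delta_a = 0) the
remaining difference is carried almost entirely by the observer-only
term.
"""

import numpy as np

from sysobs import GenerativeParams, NoiseSpec, simulate_latent, stratonovich_difference
from sysobs.workflows import ExperimentConfig, make_driver

config = ExperimentConfig()
driver = make_driver(config, seed=2)
rms = lambda x: float(np.sqrt(np.mean(np.square(x))))

for label, delta_a, delta_k in [
    ("identical observers (delta_a=0.5)", 0.5, 0.0),
    ("identical systems   (delta_k=0.5)", 0.0, 0.5),
]:
    params = GenerativeParams(delta_a=delta_a, delta_k=delta_k,
                              sigma_mu=0.2, sigma_M=0.2)
    latent = simulate_latent(params, driver, NoiseSpec(mode="additive", seed=3),
                             dt=1.0 / config.fs)
    degenerate, observer_only = stratonovich_difference(params, latent)
    print(f"{label}:")
    print(f"  RMS degenerate term    {rms(degenerate):8.3f}")
    print(f"  RMS observer-only term {rms(observer_only):8.3f}")

print()
print("The observer-only term exists only because noise passes through the")
print("nonlinear observers; it depends on g' alone, not on the dynamics f,")
print("which is what breaks the system/observer degeneracy.")
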