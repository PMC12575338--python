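"""Simulate the two-scale generative model and observe it.

Builds an 8-scene driver, integrates the micro/macro latent dynamics
(deterministic and with additive Stratonovich noise), and maps them
through the tanh observers.  The printed SDs show how the macroscopic
deviations (delta_a here) and state noise shape the two channels.
"""

import numpy as np

from sysobs import (
    GenerativeParams,
    NoiseSpec,
    observe,
    simulate_latent,
)
from sysobs.workflows import ExperimentConfig, make_driver

config = ExperimentConfig()
driver = make_driver(config, seed=1)

params = GenerativeParams(
    a=-1.0, b=1.0, delta_a=0.5, c=1.0, k=1.0,
    sigma_mu=0.2, sigma_M=0.2, obs_noise_sd=0.05,
)

for mode in ("none", "additive"):
    latent = simulate_latent(params, driver, NoiseSpec(mode=mode, seed=7),
                             dt=1.0 / config.fs)
    pair = observe(latent, params, seed=8)
    print(f"mode={mode}:")
    print(f"  latent SD   micro {latent.x_mu.std():.3f}   macro {latent.x_M.std():.3f}")
    print(f"  channel SD  micro {pair.h_mu.std():.3f}   macro {pair.h_M.std():.3f}")
    r = np.corrcoef(pair.h_mu, pair.h_M)[0, 1]
    print(f"  micro/macro correlation {r:.3f}")

print()
print("The macro channel is larger and slower because delta_a = +0.5 slows")
print("its dynamics; additive state noise adds shared fluctuations on top,")
print("which is what later makes the observer mappings identifiable.")
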