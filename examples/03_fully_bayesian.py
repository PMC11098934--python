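"""Fully Bayesian fit by Metropolis-within-Gibbs with convergence checks.

Runs two chains of the sampler over 40 simulated trials (reduced schedule),
prints the Gelman-Rubin diagnostic for the monitored hyper-parameters and
the posterior-mean variance components of one trial.
"""

import warnings

import numpy as np

from interblock.fb import MCMCConfig, posterior_sigma_fb, run_mcmc
from interblock.simulate import SimulationScenario, _simulate_collection

scenario = SimulationScenario.scenario_a(n_trials=40, seed=7)
_, summaries, _ = _simulate_collection(scenario)

config = MCMCConfig(n_iter=4000, burn_in=1000, thin=5, n_chains=2, seed=1)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result = run_mcmc(summaries, family="lognormal", config=config)

print(f"retained draws per chain: {result.config.n_retained}")
print("Gelman-Rubin PSRF (≈1 indicates convergence):")
for name, v in result.psrf.items():
    print(f"  {name:<20}{v:6.3f}")
print(
    "\n(The replicate-level hyper-parameters mix slowly on 2-replicate"
    " designs — each trial contributes a single df for replicates.)"
)
sig = posterior_sigma_fb(result, 0)
print("\nposterior-mean sigma for trial 0:", np.round(sig.as_array(), 3))
print("strictly positive by construction, unlike boundary REML estimates")
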