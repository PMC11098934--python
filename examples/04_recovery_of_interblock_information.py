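"""REML versus plug-in GLS: what a zero block variance does to treatment means.

Fits one small trial by REML; when the block variance hits the zero
boundary the model silently degenerates to a no-block analysis.  Plugging
in a strictly positive (EB-style) block variance re-weights intra- and
inter-block information and changes the treatment differences.
"""

import numpy as np

from interblock import VarianceComponents, gls_blue, pairwise_differences, reml_fit
from interblock.design import generate_alpha_design
from interblock.simulate import DEFAULT_PRIOR, simulate_trial

layout = generate_alpha_design(t=6, r=2, k=3, seed=1)
rng = np.random.default_rng(230)
# find a trial where REML hits the block boundary
for _ in range(50):
    sim = simulate_trial(layout, DEFAULT_PRIOR(), 1.0, rng)
    fit = reml_fit(sim.data)
    if fit.boundary_flags[1]:
        break
print("REML sigma:", np.round(fit.sigma.as_array(), 4), "boundary flags:", fit.boundary_flags)

reml_est = gls_blue(sim.data, fit.sigma)
plug = VarianceComponents(max(fit.sigma.sigma_r2, 1e-8), 0.4, fit.sigma.sigma_e2)
eb_est = gls_blue(sim.data, plug)

print("\npair   REML diff   plug-in diff   true diff")
for (i, j, d_reml), (_, _, d_eb) in list(zip(pairwise_differences(reml_est), pairwise_differences(eb_est)))[:5]:
    truth = sim.true_tau[i - 1] - sim.true_tau[j - 1]
    print(f"{i}-{j}   {d_reml:9.3f}   {d_eb:12.3f}   {truth:9.3f}")
print(
    "\nWith sigma_b^2 = 0 the analysis ignores incomplete blocks entirely;"
    " a positive plug-in value recovers inter-block information and"
    " generally moves the estimated differences toward the truth."
)
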