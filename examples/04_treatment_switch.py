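"""Mid-assay inhibitor treatment: piecewise influx fit.

A protonophore applied 7 min (420 s) after the tracer collapses
proton-gradient-dependent uptake: the influx constant switches from I to a
much smaller I'.  The piecewise model fits both constants from one trace.
"""

import numpy as np

from ckflux import KineticParams, SimulationDesign, fit_treatment_assay, simulate_assay

truth = KineticParams(I=0.02, E=0.004, K=0.02, I_prime=0.002)
design = SimulationDesign(
    time_grid=tuple(np.linspace(0.0, 900.0, 16)),
    noise_sd=0.04,
    seed=3,
    t_prime=420.0,
)
assay, _ = simulate_assay(truth, design, "cccp_like")

fit = fit_treatment_assay(assay, f=0.05)
p = fit.single()
print(f"pre-treatment  I  = {1e3 * p.I:.3f}e-3 /s  (true {1e3 * truth.I})")
print(f"post-treatment I' = {1e3 * p.I_prime:.3f}e-3 /s  (true {1e3 * truth.I_prime})")
print(f"efflux         E  = {1e3 * p.E:.3f}e-3 /s  (true {1e3 * truth.E})")
print(f"converged: {fit.converged}, residual norm: {fit.residual_norm:.3e}")
print()
print("The ten-fold drop of the influx constant at t' = 420 s is recovered,")
print("mirroring the accumulation plateau seen after uncoupler treatment.")
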