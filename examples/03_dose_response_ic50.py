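"""Full dose-response campaign: competitor ladder -> joint fit -> IC50.

Unlabelled competitor at 0/2/20/200/2000/20000 nM progressively displaces
the tracer from its membrane carriers; the fitted influx constants fall with
competitor concentration and the saturation model recovers the IC50 used to
generate the data.
"""

from ckflux import (
    DoseResponseSeries,
    SaturationParams,
    SimulationDesign,
    fit_dataset_shared,
    fit_saturation,
    simulate_competition_experiment,
)

truth = SaturationParams(v_lim=1.78, ic50=112.21, D=2e-3)
design = SimulationDesign(noise_sd=0.04, seed=7)
dataset, _ = simulate_competition_experiment(truth, shared_E=4e-3, shared_K=0.02, design=design)

fit = fit_dataset_shared(dataset)
series = DoseResponseSeries(
    [a.condition["competitor_conc_nM"] for a in dataset.assays],
    [fit.params[a.assay_id].I for a in dataset.assays],
)
print("competitor (nM)   fitted I (1e-3/s)")
for cK, I in zip(series.competitor_conc, series.I_values):
    print(f"{cK:14.0f} {1e3 * I:16.3f}")

sat = fit_saturation(series)
print(f"\nfitted IC50 = {sat.params.ic50:.2f} nM (true {truth.ic50} nM)")
print(f"residual influx D = {1e3 * sat.params.D:.3f}e-3 /s (true {1e3 * truth.D}e-3 /s)")
print()
print("The influx constant drops by ~an order of magnitude along the ladder;")
print("the half-saturation concentration is recovered within a few percent.")
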