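# Methods

## Accumulation model

The package models radiotracer uptake in a suspension of cells as a single
well-mixed intracellular compartment exchanging tracer with the medium by
first-order kinetics. With influx and efflux rate constants *I* and *E*
(s⁻¹), initial extracellular concentration *c₀* (nM), and a dimensionless
volume-correction factor *f* accounting for the different sizes of the
intra- and extracellular spaces, the internal concentration obeys
`dc/dt = I(c₀ − f·c) − E·c` with `c(0) = 0`. A fraction *K* of the measured
signal is tracer adsorbed to cell surfaces rather than internalised, so the
observable is `(1 − fK)·c + K·c₀`, giving the closed form

    c_I(t) = I·c₀/(fI + E) · (1 − e^{−t(fI+E)}) · (1 − fK) + K·c₀.

Assumptions: the extracellular pool is depleted only through the `f·c`
back-term (c₀ is treated as constant otherwise), metabolic conversion of the
tracer is not modelled (the initial-rate character of *I* limits its
influence), and adsorption equilibrates instantly (the `K·c₀` offset is
present from *t* = 0).

A treatment added mid-assay (e.g. a protonophore) switches the influx
constant from *I* to *I′* at the treatment time *t′*. For `t > t′` the
dynamic part relaxes toward the *I′* steady state with rate `fI′ + E`,
starting from its value at *t′*; the curve is continuous at the junction and
converges to the *I′* steady state as `t → ∞`.

Degenerate cases are evaluated analytically: when `fI + E = 0` the dynamic
term becomes the linear-growth limit `I·c₀·t`, and the steady state is
reported as a divergence error when `I > 0` with no turnover. `f·K < 1` is
enforced at validation so the measured dynamic fraction `(1 − fK)` stays
positive. Units are seconds and nM throughout; rate constants are reported
in the `10⁻³ s⁻¹` range typical of these assays.

An independent fixed-step RK4 integrator of the mass-balance ODE (default
`dt = 0.01 s`, landing exactly on requested time points and on *t′*) is part
of the package and serves as the numerical oracle in the test suite; it
never calls the closed forms.

## Parameter fitting

All fits are bounded trust-region nonlinear least squares
(`scipy.optimize.least_squares`, method `trf`) with lower bounds of zero on
every parameter, initial guesses `I = E = 10⁻³ s⁻¹`, `K = 0`, and
`ftol = xtol = gtol = 10⁻¹⁵`, capped at 10⁵ function evaluations with the
convergence flag reported. Residuals are unweighted. Three modes:

* **single assay** — (I, E, K) against one curve (≥ 4 points);
* **joint dataset** — parameter vector `(I₁, …, I_n, E, K)` with all assay
  residuals stacked, so *E* and *K* are shared across the dataset while each
  assay keeps its own *I* (and its own c₀). Used when comparing conditions
  measured on the same culture;
* **treatment** — (I, I′, E, K) of the piecewise model; *I′* starts from the
  same guess as *I*. With no post-treatment points the fit falls back to the
  plain model with a warning.

Parameters within 10⁻¹² of a bound are listed in `bound_hits`. A fitted
curve whose dynamic range is below 10⁻⁶ of the data scale is reported as a
flat trace: *I* is effectively zero and *E* is unidentifiable — the note is
attached rather than silently returning an arbitrary *E*.

*f* is never fitted: it is a per-dataset configuration constant (synthetic
default 0.05). The field-typical magnitudes used by the generators (influx
constants of a few to a few tens of 10⁻³ s⁻¹) leave (I, E, K) well
identified by 10–16 regular samples over 900 s.

Group summaries report the median *I* across replicate assays within a
condition group (midpoint convention for even counts); grouping keys are
explicit caller input.

## Dose–response

Influx constants fitted at a ladder of competitor concentrations are fitted
to `I(c_K) = v_lim/(IC50 + c_K) + D` with lower bounds of zero, initial
guesses of 1 for all three parameters and the same tolerances as above.
Under this parameterisation `v_lim` carries units of nM·s⁻¹ (the saturable
component at `c_K = 0` is `v_lim/IC50`). The default ladder is
0/2/20/200/2000/20000 nM.

"No saturation observed" is flagged when the fitted IC50 exceeds 10⁶ times
the largest tested concentration, or when the best fit is essentially flat
(saturable drop < 10⁻⁹ of the data scale) although the data themselves vary
— the signature of a non-decreasing series that the model cannot follow.  A
genuinely constant series is fitted as `v_lim → 0, D = const` without a
flag.

Fold-change matrices divide the treated median influx constant by the
matching control median (values < 1 = inhibition); non-tested combinations
stay absent (NaN), and zero-control cells are flagged undefined rather than
reported as infinities.

## Shoot segmentation

Top-view scans are converted from sRGB (D65) to CIELAB (L* in [0, 100],
signed a*/b*). The mask keeps pixels with `a* ≤ −9.5`, `b* ≥ −9.5` and
`L* ≥ 18.5`; connected components smaller than 2048 px are removed, the mask
is closed with a disk footprint of radius 8 px, components smaller than
8192 px are removed, and the remaining objects are labelled and measured.
Size filters and labelling use faces-only (4-)connectivity, configurable.
"Smaller than N px" is strict — an object of exactly N px survives.
Multi-Otsu boundaries (3 classes per channel, falling back to 2 when the
histogram cannot support 3, with a degenerate flag for uniform channels) are
offered as advisory threshold estimates only; the fixed defaults above are
what the pipeline applies. Areas convert to mm² as `px·(25.4/dpi)²` when a
scan resolution is supplied.

## qPCR expression and statistics

Relative expression with two reference genes is
`REL = 2^{(CP_R1 + CP_R2)/2 − CP}` — the geometric mean of the reference
signals over the target, assuming amplification efficiency 2 (no
efficiency correction, no melting-curve QC). Group comparisons use the
Kruskal–Wallis rank test (scipy), with significance classes n.s. (P ≥ 0.05),
\* (< 0.05), ** (< 0.01), *** (< 0.001) and no multiple-testing correction;
fully tied data return H = 0 directly since the scipy routine rejects that
degenerate input.

## Synthetic data

Generators emulate the study conditions: 12 regular samples over 0–900 s
(10 for the sparser recovery checks), `c₀ = 2 nM`, `f = 0.05`, treatment at
`t′ = 420 s` for treatment designs, and the six-step competitor ladder.
Measurement noise is additive Gaussian truncated at zero with
sd = 2 % of c₀ (0.04 nM) — a placeholder for unknown scintillation-counting
noise, exposed in configuration. Scenes for segmentation paint solid
rosette blobs in sRGB (60, 170, 70) (L* 61.8, a* −51.7, b* 41.8 — passing
the thresholds) on a near-white textured background, with same-coloured
distractors constrained below 2048 px; qPCR plates place the target crossing
point `log2(REL)` cycles below the reference mean (default references 20 and
22 cycles) with optional cycle noise on the target.

Every generator is bit-reproducible given a seed and returns a truth record;
recovery tests compare against that record, never against hard-coded
numbers. What the generators do **not** emulate — tracer metabolism,
extracellular depletion beyond the model's own back-term, correlated or
heteroscedastic counting noise, leaf-shaped or partially occluded rosettes,
scanner vignetting, pipetting gradients across qPCR plates — bounds what
passing tests show about real data: they certify the estimation machinery,
not robustness to unmodelled biology.

## Problem sizes and runtime

The test-suite and acceptance-script problem sizes — 100 random parameter
sets for the oracle comparison, 8-assay campaigns for recovery, 6-rung
ladders, 3 rendered scenes of 600×800 px — were chosen as the smallest
designs at which the statistical guarantees (median influx error < 10 %,
shared efflux error < 15 %, IC50 within 20 % under 2 % noise) are
comfortably met; the full acceptance run completes in seconds.

## Known limitations

* The closed form treats c₀ as fixed; strong extracellular depletion beyond
  the `f·c` term would bias *I* downward.
* *E* is weakly identified in short assays with small `fI + E` (curves are
  nearly linear); the joint fit mitigates this by pooling assays.
* IC50 estimates inherit the ladder's log-spacing: values far outside
  2–20000 nM are extrapolations and will trip the divergence flag.
* The segmentation recipe assumes scans resembling the rendered scenes
  (saturated green tissue on a light background); dark soil, moss, or
  colour-shifted cameras require re-estimating thresholds.
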