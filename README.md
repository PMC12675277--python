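# ckflux

Analysis pipeline for cytokinin membrane-transport kinetics in plant cell
suspensions (BY-2), plus the surrounding phenotyping and expression assays:

* **Compartmental radiotracer model** — closed-form accumulation curves with
  influx/efflux rate constants and a surface-adsorption term, including a
  piecewise variant for mid-assay inhibitor treatment, validated against an
  independent RK4 integration of the mass-balance ODE.
* **Constrained fitting** — per-assay fits and joint dataset fits in which
  the efflux constant *E* and adsorption factor *K* are shared across assays
  while each assay keeps its own influx constant *I*.
* **Dose–response / IC50** — saturation fits of fitted influx constants
  against competitor concentration, with divergence ("no saturation
  observed") detection and fold-change matrices.
* **Shoot segmentation** — top-view rosette area measurement via CIELAB
  thresholds, size filters and morphological closing.
* **qPCR relative expression** — delta-Ct with two reference genes, and
  Kruskal–Wallis group comparisons.
* **Synthetic data** — generators for every input above with exact,
  machine-readable ground truth, so the whole pipeline is testable without
  any external data.

## The model

During a radio-accumulation assay the intracellular tracer concentration
follows

```
c_I(t) = I·c0/(f·I + E) · (1 − e^{−t(f·I+E)}) · (1 − f·K) + K·c0
```

where *I* and *E* (s⁻¹) are first-order influx and efflux rate constants,
*K* is the fraction of signal adsorbed to cell surfaces, *c₀* (nM) the
initial extracellular tracer concentration and *f* the correction for the
relative sizes of the intra- and extracellular spaces. This is the solution
of `dc/dt = I(c0 − f·c) − E·c` mapped to the measured signal
`(1 − fK)c + K·c0`. A treatment at time *t′* (e.g. the protonophore CCCP)
switches *I* to *I′*, giving a continuous piecewise curve.

Saturable carrier-mediated uptake is summarised by

```
I(c_K) = v_lim / (IC50 + c_K) + D
```

with competitor concentration *c_K*, half-saturation concentration IC50 and
residual (non-saturable) influx *D*.

qPCR relative expression against two reference genes is
`REL = 2^{(CP_R1 + CP_R2)/2 − CP}`.

## Worked example

`examples/03_dose_response_ic50.py` simulates a full competition campaign on
the 0/2/20/200/2000/20000 nM competitor ladder (2 % measurement noise),
jointly fits all six assays with shared (*E*, *K*), and fits the saturation
model to the recovered influx constants:

```
competitor (nM)   fitted I (1e-3/s)
             0           17.797
             2           17.517
            20           15.338
           200            7.766
          2000            2.808
         20000            2.151

fitted IC50 = 113.19 nM (true 112.21 nM)
residual influx D = 2.026e-3 /s (true 2.0e-3 /s)
```

The influx constant falls roughly ten-fold along the ladder and the
half-saturation concentration used to generate the data is recovered within
about one percent. The other scripts in `examples/` cover the accumulation
model itself, joint fitting, mid-assay treatment, shoot segmentation and
qPCR expression, one capability each.

A thin CLI mirrors the library:

```bash
ckflux simulate competition --seed 1 --out sim/
ckflux fit --assays sim/assays.csv --shared-ek --out params.csv
ckflux segment --image scan.png --dpi 300 --out areas.csv
ckflux rel --in cp.csv --out rel.csv --compare genotype
```

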