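# chromdoe

Chemometric method development for liquid chromatography, end to end and in
silico: central-composite-design screening of mobile-phase factors, PLS
response-surface modelling of retention and resolution, constraint-based
selection of operating conditions, and the full ICH-style validation battery.
The package ships a calibrated synthetic HILIC retention simulator for
moxonidine and its four pharmacopoeial impurities (A–D), so every step of a
real method-development study — from the 20-run screening plan to the tablet
assay — can be exercised, tested and reproduced without an instrument.

It is written for analytical chemists and chemometricians who want a tested,
scriptable implementation of this workflow, and for anyone who needs a
realistic, fully-controlled testbed for DoE/validation software.

## The method

**Screening design.** K = 3 mobile-phase factors — acetonitrile content
(70/75/80 % v/v), aqueous-phase pH (2.8/3.5/4.2) and ammonium formate
concentration (20/40/60 mM) — are varied in a rotatable central composite
design: 2³ factorial runs at coded ±1, 2·3 axial runs at ±α with
α = (2³)^¼ ≈ 1.682, and 6 centre replicates (20 runs).

**Response surfaces.** Each response y ∈ {k_M, k_A, k_B, k_C, k_D, Rs_A/B,
Rs_C/D} is regressed by PLS (NIPALS, autoscaled) on the 9-term block
(x₁, x₂, x₃, x₁², x₂², x₃², x₁x₂, x₁x₃, x₂x₃) of coded factors.  Model
quality is R² = 1 − RSS/TSS and leave-one-out Q² = 1 − PRESS/TSS; the
component count maximises Q².  Coefficient uncertainty comes from a jackknife
over the leave-one-out refits with Student-t 95 % intervals; a term is
significant when its interval excludes zero (the "error bar does not cross
the axis" rule of coefficient plots).  With all components on full-rank data
the PLS fit coincides with ordinary least squares, which the tests use as an
independent oracle.

**Optimisation.** Conditions are feasible when both critical resolutions
satisfy Rs ≥ 2 (baseline separation, Rs = 2|ΔtR|/(w₁+w₂) with 4σ widths) and
the last peak elutes within 12 min (tR = t₀(1+k)); among feasible points the
fastest run wins.

**Validation.** Linearity (r ≥ 0.997 and an intercept t-test against
Student's t at 5 %), LOD/LOQ from signal-to-noise 3:1 and 10:1 (S/N = 2H/h),
spiked-placebo recovery (98–102 % API; 70–130 % or 80–120 % for impurities by
level) and precision (RSD ≤ 2 / 10 / 15 % by compound class), one-factor-at-
a-time robustness (±0.5 % ACN, ±0.05 pH, ±2 °C, ±0.1 mL/min must move areas
< 5 %, retention times < 3 %, resolutions < 3 %), placebo selectivity, and a
tablet assay checked against the impurity specification.

## Worked example

```bash
python examples/03_select_optimum.py
```

prints (seed 1):

```
evaluated 9253 grid points, 7 feasible
best: 80.0 % ACN, pH 2.80, 34 mM
  predicted Rs(A/B) = 2.12, Rs(C/D) = 2.00, run time 11.74 min
```

A noisy 20-run screening study was simulated, seven PLS surfaces fitted, and
a 21³ coded grid (inside the design sphere) filtered by the resolution and
run-time constraints.  Only a small corner of the factor space is feasible —
high acetonitrile and low pH — because low ACN/low pH coelutes impurities
A and B while high pH coelutes C and D.  The selected condition matches the
method's declared optimum (80 % ACN, pH 2.8) with the buffer axis, to which
the separation is insensitive, settling near the centre.  The other examples
build the design table (01), fit and interpret the screening models (02) and
run the full validation battery (04).

The same workflow is scriptable from the shell:

```bash
chromdoe run-all --seed 1 --outdir study/
```

writes the design, response table, model JSONs, coefficient tables, ranked
feasible conditions, the validation report and a hash manifest.

## Layout

```
src/chromdoe/
  doe.py         central composite designs, coded/actual conversions
  pls.py         term expansion, PLS fits, Q², jackknife CIs
  simulator.py   calibrated synthetic HILIC system (the data generator)
  optimizer.py   constraint-based grid search over fitted surfaces
  validation.py  ICH validation statistics and pass/fail rules
  datasets.py    published benchmark tables used by the classifiers
  pipeline.py    design → simulate → fit → optimize → validate bundles
  cli.py         thin `chromdoe` command-line interface
examples/        narrative scripts, one per capability
docs/methods.md  the model, its assumptions and design choices
```
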