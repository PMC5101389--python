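# Methods

## Scope and model

The package reproduces, as tested software, the chemometric workflow used to
develop and validate an isocratic HILIC method for a drug substance
(moxonidine) and four related impurities: screen three mobile-phase factors
with a rotatable central composite design, model each chromatographic
response with PLS on the quadratic factor block, select operating conditions
under resolution and run-time constraints, and run the ICH-style validation
battery.  Because the underlying study published anchor observations but not
its raw per-run data, the package includes a synthetic retention simulator
calibrated to those anchors; it is the data source for everything the
pipeline computes.

## Design of experiments

A CCD in K factors has 2^K factorial runs (coded ±1), 2K axial runs at ±α and
n_center centre replicates.  We use α = (2^K)^(1/4) (rotatable; for K = 3,
α = 1.681793), n_center = 6, and the canonical run order centre → factorial
(first factor fastest) → axial.  Coded and actual units are related affinely
per factor (actual = center + coded·step); the HILIC factors are
ACN % (center 75, step 5), pH (center 3.5, step 0.7) and buffer mM
(center 40, step 20).  The pH step is inferred from the stated levels
2.8/3.5/4.2.  Actual levels are displayed at 2 decimals (66.59, 73.64, …)
while full precision is kept internally.  Whether the original experiments
were randomised is unknown; the canonical order is the default and a seeded
shuffle is available.

## PLS response surfaces

One PLS1 model per response (seven in total) on the fixed 9-term block
x1, x2, x3, x1², x2², x3², x1x2, x1x3, x2x3 of coded levels.  Choices:

* **Autoscaling** (centre + unit variance) by default, the norm in
  chemometrics software; configurable.
* **Engine**: scikit-learn's NIPALS `PLSRegression`, which is deterministic
  (initialised from the response; no randomness).  With all components on
  full-rank data it equals ordinary least squares; the tests assert this
  against `numpy.linalg.lstsq` at 1e-8.
* **Component count**: chosen to maximise leave-one-out Q², ties toward
  fewer components.  The original study does not state its component counts.
* **Q²** = 1 − PRESS/TSS with PRESS from strict leave-one-out refits.
* **Coefficient intervals**: jackknife over the LOO refits,
  SE² = (n−1)/n · Σ(θ₍ᵢ₎ − θ̄)², Student-t at 95 % with n−1 df; a term is
  significant iff its interval excludes zero.  The original software's CI
  algorithm is unstated; the jackknife is the declared convention here, and
  simulation shows its 95 % intervals cover true coefficients at close to
  nominal rate (the acceptance suite checks 88–99 % over 200 studies).
* Coefficients are reported on the original response scale (signs and
  zero-crossings are invariant to autoscaling, so the significance rule is
  unaffected).
* An extrapolation guard warns when predictions are requested beyond
  1.1·α in coded norm.

R² is computed as 1 − RSS/TSS; for a least-squares fit this equals the
squared correlation between fitted and observed values.

## The retention simulator (synthetic data)

**Ground truth.** Per compound, log10 k is a quadratic polynomial in the
coded factors — the same family the screening models use, which keeps k > 0
everywhere and makes log-scale refits exactly identifiable.  The shipped
coefficient set (version 1) was solved offline, by construction rather than
fitting, against the study's anchor observations:

* Rs(A/B) = 0 at 70 % ACN, pH 2.8, at 20 and 60 mM alike;
* Rs(C/D) = 0 and Rs(A/B) = 10.91 at 75 % ACN, pH 4.68, 40 mM;
* at 80 % ACN, pH 2.8, 40 mM: every adjacent pair baseline-resolved
  (Rs ≥ 2) and the last peak within 12 min;
* k of the API and impurities B, C, D strictly increasing in ACN (the HILIC
  signature) with ACN the dominant factor; impurity A governed by pH with a
  negative sign;
* the robustness perturbations (below) all stay inside their windows;
* the fitted-model optimiser reproduces the declared optimum region.

These constraints pin most of the surface; the remaining freedom (absolute
retention levels, elution order) was fixed once at values a practitioner
would call realistic: dead time t0 = 2.05 min (250 × 4.6 mm column, porosity
≈ 0.66, 1 mL/min), k between ≈ 1.4 and 6 over the design region, elution
order A < B < M < C < D at the optimum.  The published study names A/B and
C/D as the critical pairs but never prints an elution order; placing the
pairs adjacent with the API between them is one consistent choice.

**Peaks.** Gaussian, shared plate count N = 10 000, width w = 4·tR/√N;
resolution uses the baseline-width formula Rs = 2|ΔtR|/(w₁+w₂); k =
(tR − t0)/t0.  Peak area = response factor × concentration, with the response
factors taken from the method's published calibration slopes (the ~10³ unit
difference between the API and impurity slopes is the source's own
convention and is kept, configurable).  Heights follow from area and width.

**Noise.** Run-to-run variability adds Gaussian noise of total SD
σ_logk = 0.01 to each log10 k, decomposed into a shared system component
(95 % of the variance; mobile-phase preparation and drift move all
co-injected peaks together) and an independent per-compound remainder.  The
shared part largely cancels in resolutions, which is what keeps the
resolution responses cross-validatable (Q² > 0.7) at realistic noise, as the
published model statistics imply.  Detector traces add white baseline noise
(SD 0.17 area-units, set so a ~0.1 µg/mL impurity standard shows S/N of a
few tens, putting the LODs at the 0.01–0.05 µg/mL level the method reports);
calibration responses use σ = σ0 + σrel·response with σ0 = 0.3 % of the
mid-level response and σrel = 0.5 %; found concentrations in recovery
samples carry 0.6 % (API) / 1.2 % (impurity) relative SD.

**Temperature and flow.** Temperature enters log10 k linearly
(−0.005 per °C), small enough that ±2 °C moves retention times by ~2 %.
Retention times scale with flow as tR ∝ F^(−0.25) — an empirical damping:
physically the dead time scales as 1/F, but the emulated study reports that
±0.1 mL/min changes retention times by less than 3 %, which a strict 1/F
cannot satisfy.  The exponent is a ground-truth parameter; setting it to 1
restores strict physics at the cost of that robustness outcome.  Peak areas
are modelled as flow-independent.  This is the simulator's main known
departure from first-principles chromatography.

**What passing tests do and do not show.** The generator emulates smooth
quadratic log-retention, Gaussian peaks, linear calibration and
level-proportional recovery noise.  Real HILIC systems add peak tailing,
retention drift between equilibrations, detector nonlinearity at high load
and matrix effects — none of which are modelled.  Green tests therefore
certify the statistics and the workflow logic, not instrument behaviour.

## Optimiser

Grid search over coded conditions: default 21 points per factor spanning the
factorial cube [−1, 1], filtered to the rotatable sphere (‖x‖ ≤ α).  The cube
is the region where all three factors were jointly varied and the quadratic
surface interpolates; the axial extremes are one-dimensional excursions, and
quadratic extrapolation toward them can manufacture artefacts (e.g. a
re-opening A/B gap at very low pH).  Feasibility uses predicted means —
Rs(A/B) ≥ 2, Rs(C/D) ≥ 2, t0(1+max k̂) ≤ 12 min — and the objective is
minimum predicted run time (the published selection is justified by speed at
adequate separation; "maximise the worst resolution" is available as an
alternative).  Ties break toward the design centre, then lexicographically,
so results are deterministic.  An empty feasible set is a structured result,
not an error.

## Validation statistics

* **Linearity**: OLS on level means (replicate-wise optional), r from
  Pearson correlation; intercept t = |b₀|/SE(b₀) compared with two-sided
  t(0.05, df), df = n − 2 by default.  Published tables of this kind
  sometimes print critical values whose implied df does not match the stated
  level count (here: t 2.365/2.262 imply df 7/9 against 6/9 levels), so df
  is overridable.  The 5 % false-flag rate per line is inherent to the
  criterion: with five compounds, about one study in four flags a truly zero
  intercept somewhere.
* **LOD/LOQ**: S/N = 2H/h, H the peak height above the local baseline
  (median of a peak-free window), h the peak-to-peak noise in that window —
  the pharmacopoeial convention.  LOD = c·3/(S/N), LOQ = c·10/(S/N), reported
  at 2 significant figures; LOQ/LOD = 10/3 identically when scaled.
* **Accuracy windows**: 98–102 % (API), 80.0–120.0 % for impurity levels at
  or above 0.5 % of the API concentration, 70.0–130.0 % below that.  The
  LOQ-level spikes sit below every stated band; applying the widest band to
  them is a documented extrapolation.
* **Precision**: RSD ≤ 2 % API, ≤ 10 % impurities C/D, ≤ 15 % impurities A/B.
* **Robustness**: OFAT around the declared conditions; pass iff max |Δarea|
  < 5 %, max |ΔtR| < 3 %, max |ΔRs| < 3 % (strict inequalities, boundary
  behaviour unit-tested).
* **Selectivity**: placebo signal in each analyte's retention window must
  stay below 0.3 × the LOQ-level analyte height.
* **Assay**: inverse calibration, API as % of label claim, impurities as %
  of the nominal API concentration; below-LOQ values are flagged, not
  reported as numbers; the specification check passes when every impurity is
  below its limit (0.5 % for A/B, 1 % for C/D).

The pipeline validates at the declared method conditions (80 % ACN, pH 2.8,
40 mM): an analyst rounds the DoE suggestion to practical set points, and
robustness margins are certified at the declared method, not at an arbitrary
grid node.

## Problem sizes and determinism

The shipped study sizes are the emulated study's own: 20 screening runs,
9-term models, 21³ optimisation grid, 9- or 6-level calibrations in
triplicate, 3 recovery replicates per level, 8 robustness perturbations.
Simulation-based checks in the tests use 20–200 seeded replicates, enough to
pin the Monte-Carlo error well inside the asserted margins.  All randomness
flows through `numpy.random.default_rng` seeds; identical seeds give
bit-identical artifacts (the pipeline writes a SHA-256 manifest to prove it).

## Known limitations

* The ground truth is *constrained, not estimated*: the published study
  prints no per-run retention data, so any surface satisfying the anchors is
  admissible and published R²/Q² values are plausibility context, not
  reproduction targets.
* Quadratic log-k surfaces cannot represent retention mechanisms that change
  regime inside the design space.
* The flow exponent (above) trades physical strictness for the emulated
  robustness outcome.
* Gaussian peaks only: no tailing/fronting, no gradient elution, no MS
  detection.
* Intermediate precision, forced degradation and stability are out of scope.
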