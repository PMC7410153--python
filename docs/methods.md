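# Methods

## The problem

Benchtop coronary phantoms printed from patient CT angiography reproduce the
large and medium arteries, but the arterioles and capillary bed are below
both imaging and printing resolution.  Their hydraulic effect — most of the
circulation's resistance, and its compliance — must therefore be supplied by
hardware: each main coronary tree (LAD, LCX, RCA) drains into a sealed
outflow chamber (a compliance, plus a small unavoidable series resistance),
and a catheter of chosen radius and length downstream of each chamber
imposes the distal resistance of a chosen activity state.  This package does
the quantitative work around that hardware: sizing the catheters,
characterizing the chambers, and solving the resulting 0D circuit.

## Catheter sizing

For fully developed laminar flow in a cylinder, the Hagen–Poiseuille law
gives

```
R = 8 μ L / (π r⁴)       [dynes·s/cm⁵, CGS]
```

with μ the dynamic viscosity (poise), L the length (cm), r the inner lumen
radius (cm).  Sizing inverts this exactly: `L = R·πr⁴/(8μ)`.  Entrance/exit
losses and turbulence are ignored; at bench flows of 1–3 cm³/s in 0.6–0.9 mm
radius lumens the Reynolds number stays low and the fully developed term
dominates.  The forward/inverse pair round-trips to machine precision and is
property-tested for monotonicity and the viscosity-free ratio law
`L(r₂)/L(r₁) = (r₂/r₁)⁴`.

**Working fluid.** The default viscosity is 0.037 poise (3.7 cP), a
blood-analog value.  It is also the value a bounded 1-D search recovers
(`fit_viscosity`, scipy `minimize_scalar`) when the mean relative error
between Poiseuille lengths and the shipped 27-cell reference sizing table is
minimized over μ ∈ (0.005, 0.10) P — the table is Poiseuille-consistent to
within rounding.  Every public routine accepts a viscosity override; the
mmHg↔dyn/cm² constant (1333.22) is fixed.

**Reference table quirks.** Two cells of the reference table round more
coarsely than the rest: the moderate-exercise LAD 4 Fr cell prints 3.9 cm
where the formula gives ≈3.99 cm (2.3% off), and the matching LCX cell
prints 4.0 vs ≈4.03.  Table-reproduction tests therefore use a 2.5%
relative tolerance rather than exact equality; the three directly quoted
rest-state cells agree within 0.6%.

**Catalog and feasibility.** The default catalog maps 4/5/6 Fr to inner
radii 0.06/0.071/0.09 cm with a 112 cm maximum length — the longest stock
catheter vendors routinely supply.  A catheter can be trimmed arbitrarily
short, so the default minimum length is 0; a `min_length_cm` per entry is
honored for users whose stock has a floor.  With these defaults exactly
three reference cells are infeasible (≈177, 129 and 333 cm, all rest-state),
each flagged with the remedy ("use smaller Fr").  Options are sorted
feasible-first, then by |relative error| (rounded at 1e-9 so float noise
cannot scramble ties), then by French size — smaller sizes give shorter
catheters and less dead volume.

**Chamber correction and quantization.** Because chamber and catheter sit in
series, the chamber's measured resistance is subtracted from the coronary
target before inversion (`required_distal_resistance`); a chamber resistance
at or above the target is rejected as non-physical.  The bench set built by
`build_quantized_set` snaps targets to multiples of 10,000 dynes·s/cm⁵ over
50,000–300,000 by default (range and step configurable); the induced
relative error, `quantization_error`, is ≤ step/(2·target) — about 1.7% for
the rest-state LAD target, consistent with the ~2% figure usually quoted for
this rounding.

## Chamber characterization

A constant flow Q is driven through each chamber alone over an inclusive
ladder (default 80–160 mL/min in 20 mL/min steps, i.e. 1.33–2.67 cm³/s)
while the pressure drop ΔP is recorded with the outlet at atmospheric
reference (a downstream pressure column, if supplied, shifts the reference).
Per-point resistance is ΔP/Q.  Two estimators are reported:

* **mean of ratios** `mean(ΔPᵢ/Qᵢ)` — the headline number;
* **through-origin slope** `Σ(QᵢΔPᵢ)/Σ(Qᵢ²)` — a regression cross-check.

For noiseless linear data the two coincide exactly.  Under relative Gaussian
pressure noise the mean estimator is unbiased with SD `R·σ/√n`; the
Monte-Carlo harness (`recovery_suite`) verifies bias < 1% of truth and the
σ/√n scaling at the default 2% noise.  No model of flow-dependent chamber
resistance R(Q) is assumed: bench data show it can drift with flow
(minor-loss effects), so the per-flow report mode simply tabulates the
per-point values.

Percent-of-coronary reporting divides the chamber estimate by the per-vessel
distal resistance of each activity state, rendered rounded half-up to two
decimals (resistances to zero decimals); internally every table keeps full
precision and rounding happens only at render time.

## The lumped (0D) circuit

The phantom is an aortic inlet feeding parallel branches; each branch is a
series chain — artery resistance (usually negligible), chamber resistance,
catheter resistance — with the chamber's compliance C hanging at the node
between artery and chamber:

```
C · dP_c/dt = Q_in − (P_c − P_out)/R_down,    R_down = R_chamber + R_catheter
```

**Steady state.** Compliances carry no flow, so pressure-driven branches obey
the hydraulic Ohm analog Q = ΔP/R_series and the flow-driven case solves one
nodal equation for the aortic pressure.  Conservation at the aortic node is
verified to 1e-9 relative in both modes, and the solver is cross-checked in
the tests against an independent brute-force nodal solve.

**Transient.** Fixed-step classic RK4 on the chamber-pressure states.  The
step must satisfy `dt ≤ 2·min(R_eff·C)/safety` with safety factor 10, where
R_eff is the downstream resistance in parallel with the artery resistance
when one exists — the explicit-Euler stability limit with an order of
headroom, which also keeps RK4 in its accurate regime (the closed-form decay
test converges at better than 8× error reduction per dt halving).  The inlet
ball valve (aortic-valve surrogate) is an ideal check valve: negative pump
flow is clipped to zero.  With every artery resistance zero, the inflow
split between parallel chambers is undefined (their pressures would be
algebraically pinned together); the solver accepts that configuration only
for a single branch, where the inflow injects straight into the compartment.
Validated behaviors: convergence to the steady solution with time constant
τ = R_down·C, e-folding discharge, and the first-order low-pass amplitude
`1/√(1+(ωRC)²)` within 2% at ωRC of 0.5–2.

**Compliance values** are not standardized for printed chambers and depend
on trapped air volume; they are required inputs for transients, with
1e-4 cm⁵/dyne used as a representative value in tests and examples (an
ωRC ≈ 1 regime at bench frequencies).  Intramyocardial pressure coupling and
systolic resistance variation are deliberately excluded — the printed
phantom has no contracting myocardium.  Multi-element Windkessel variants,
stenosis pressure-loss terms and 3D CFD are out of scope.

## Synthetic data

`generate_chamber_experiment` emulates the constant-flow chamber experiment:
ΔP = R·Q at each sweep setpoint, perturbed by a chosen noise model.  Noise
is applied to pressure only — a calibrated programmable pump holds its flow
setpoint far more tightly than a bench pressure transducer reads ΔP — and
negative perturbed pressures are clipped at zero.  The default is 2%
relative Gaussian noise, a typical transducer class.  All randomness flows
from one explicit seed; the provenance triple (truth, sweep, noise+seed)
regenerates byte-identical measurement files, which the tests assert.

What the generator does **not** emulate: flow-dependent chamber resistance,
sensor drift/autocorrelation, pulsatile contamination of the constant-flow
plateau, or geometric print error.  Passing recovery tests therefore show
the estimators are correct for the stated noise model, not that a real
bench sweep is this clean.

## Problem sizes and determinism

The shipped validation uses the 27-cell reference table, 1000 Monte-Carlo
replicates of the 5-point sweep for estimator recovery, 50 random circuits
for the nodal cross-check, and RC integrations of 500–2300 steps — sizes at
which every check is comfortably converged while the whole suite runs in
seconds.  All stochastic tests and the acceptance script derive their
generators from explicit seeds.

## Known limitations

* Poiseuille sizing ignores minor losses and catheter-connector dead volume;
  for very short catheters (a few cm) entrance effects are a larger share of
  the total drop.
* Whether the reference radii are true inner lumen radii of stock 4/5/6 Fr
  catheters or nominal design values is not documented; treat the catalog as
  configuration, not ground truth.
* The transient solver is a design aid for choosing compliances and
  interpreting bench waveforms, not a reproduction of any measured pressure
  recording.
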