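# Methods

## Model structure and assumptions

The kinetic model is a linear, constant-coefficient compartment system.
Seven compartments — lungs, arterial blood, venous blood, kidney, liver,
brain and a lumped rest-of-body — are connected by blood flow in the usual
mammillary arrangement: venous blood → lungs → arterial blood → systemic
organs in parallel → venous blood.  Assumptions:

* **Well-stirred, perfusion-limited tissues.**  Each tissue is homogeneous
  and the venous blood leaving it is in instantaneous equilibrium with the
  tissue, at concentration `C_T / P_T`.  There is no membrane-permeability
  limitation, no saturable (receptor) binding and no tumour compartment.
* **Constant parameters.**  Flows, volumes, partition coefficients and
  clearances do not change over the simulated 0–120 h.
* **Intrinsic clearance.**  Kidney and liver remove tracer at rate
  `CL_T · C_T / P_T` [Bq/min], i.e. the clearance acts on the
  venous-equilibrium concentration (the intrinsic-clearance convention).
* **IV bolus.**  The administered activity starts entirely in the venous
  compartment.
* **Vascular-only brain.**  Large radiolabeled peptides do not cross the
  blood–brain barrier, so the brain compartment volume is the cerebral
  blood volume, 3.8 % of the anatomical brain.
* **Physical decay off by default.**  Measured scintigraphy count rates
  are not decay-corrected here; the fitted clearances therefore absorb
  Lu-177 decay.  A `decay_constant` switch restores explicit decay
  (λ = ln2/T½) when decay-corrected data are used.

The system matrix is Metzler (non-negative off-diagonal), so non-negative
initial states stay non-negative, and with decay off the total of body
activity plus cumulative cleared activity is conserved exactly — both
properties are asserted in the tests and after every simulation.

## Parameters and defaults

| parameter | meaning | unit | default |
|---|---|---|---|
| organ masses | lungs 1000, kidney 299, liver 1910, brain 1420, venous/arterial blood 2350 each, rest of body 64371 | g | reference adult |
| flow fractions | kidney 22, liver 17.5, brain 11.4, rest of body 49.1 (sum exactly 100) | % of Q_C | reference adult |
| tissue density | mass→volume conversion | g/ml | 1.0 (1.056 selectable) |
| cardiac output | coeff·BW^exp | L/h, BW kg | 15·BW^0.74 |
| body weight | patient weight (not recorded with the datasets) | kg | 70, overridable |
| brain CBV fraction | accessible brain volume | – | 0.038 |
| P_T | tissue-to-blood partition | – | fitted (init 1) |
| CL_K, CL_L | intrinsic clearances | ml/min | fitted (init 1) |
| detection_scale | count-rate ↔ activity bridge | – | 1, fixed |

Internal units are ml, min, Bq; dataset files carry hours and are converted
at the boundary.

## Calibration

The objective is a weighted least-squares discrepancy between simulated
organ activities and the time–activity table, with three weightings:
`uniform` (default; zero-valued brain observations are kept as genuine
zeros), `relative` (1/data², zero observations dropped) and `poisson`
(1/data).  Rows at t = 0 are consistency checks, not residuals — the model
is exactly zero there.

The minimizer is a trust-region method with positivity constraints:

* gradient by central finite differences (relative step 1e-5, one-sided at
  the positivity bound, flagged in the iteration log);
* quadratic model Hessian maintained by the BFGS rank-two secant update,
  skipped when the curvature `yᵀs` is non-positive;
* subproblem (minimize the model inside ‖ΔP‖ ≤ D with P + ΔP ≥ ε) solved
  by a dogleg step with box faces pinned recursively as they activate,
  compared against the constrained Cauchy point, then polished by
  projected gradient descent; the returned step is always feasible and
  never worse than the Cauchy point;
* standard acceptance/radius control: η₁ = 0.1, η₂ = 0.75, shrink 0.25,
  expand 2, D₀ = 1, at most 200 iterations by default.

Three robustness measures matter in practice and are part of the design:
the unit initial Hessian is rescaled to the observed curvature at the
first update; a collapsed subproblem step with a large gradient triggers a
one-shot Hessian reset; and the initial Hessian can be set to the
Gauss-Newton matrix `2 JᵀJ` (finite-difference residual Jacobian), which
is what makes it possible to follow the very flat valley described below.

Free parameters default to `{P_K, P_L, P_BR, P_RB, CL_K, CL_L}` with
`P_Lu = 1` and `detection_scale = 1` fixed: only liver, kidney and brain
are observed, and freeing everything makes the fit under-determined.  A
seeded log-uniform multistart (`fit_multistart`) is provided because the
residual surface has multiple basins — from the all-ones start the
optimizer reliably falls into a "predict ≈ 0 everywhere" basin.

### Identifiability

With organ blood flows of order 1000 ml/min and clearances of order
10 ml/min, each organ equilibrates with arterial blood in ~1 min, far
faster than the first imaging time (0.5 h).  In that quasi-equilibrium both
clearing organs remove tracer at `CL_T · C_A`, so the data determine the
*sum* `CL_K + CL_L` well but the split between the organs only through
second-order transients; likewise each organ curve constrains the
combination `P_T · Q_T / (Q_T + CL_T)` rather than `P_T` and `CL_T`
separately.  Noise-free synthetic data still pin all four parameters
(the recovery study reaches well under 1 % error), but at 5 % measurement
noise the clearance split is lost: the residual surface has a nearly flat
valley along the clearance-exchange direction, orders of magnitude softer
than its stiffest direction, and the resulting median clearance errors are
tens of percent no matter the optimizer.  Partition coefficients remain
recoverable to a few percent.  Users fitting real data should either fix one clearance, fit the
total, or accept that only the sum is meaningful.

## Synthetic data

The generator mimics the clinical study layout: 4 imaging times over
0–120 h (the four built-in grids are selectable), three observed organs,
one unobserved injected dose of 7400 MBq, and multiplicative log-normal
noise (default cv 5 %, mean-preserving) with additive-Gaussian and
Poisson-count alternatives.  Default ground-truth kinetics — P_K = 5,
P_L = 2, P_BR = 1, P_RB = 0.5, CL_K = 15 ml/min, CL_L = 8 ml/min — were
chosen to reproduce the qualitative shape of the clinical tables: rapid
early distribution, strong kidney/liver signal, and slow washout with an
effective whole-body half-life of roughly a day.

What the generator does **not** emulate: image formation (projection,
attenuation, scatter, ROI overlap), organ-mass variability between
patients, background activity, tumour uptake, and any detection-scale
mismatch between counts/s and Bq.  Passing recovery tests therefore show
that the calibration machinery is correct and consistent, not that real
scintigraphy uptakes are unbiased estimates of physical activity.

The recovery study frees `{P_K, P_L, CL_K, CL_L}` by default (fixing the
poorly informed `P_BR`, `P_RB` at truth) and fits each replicate by
multistart + Gauss-Newton-polished trust region; in the zero-noise arm the
polish runs with ODE tolerances of 1e-12 so the integration error stays
below the valley depth being resolved.

## Numerical choices

* ODE integration: stiffness-switching LSODA with analytic (constant)
  Jacobian, rtol 1e-8 / atol 1e-10 by default; the lung/blood exchange
  (~6 min⁻¹) against multi-day washout makes the system moderately stiff.
  A matrix-exponential evaluation of the same linear system serves as an
  independent oracle in the tests (agreement to 1e-8).
* Negative concentrations beyond `1e-6 ×` peak raise an error; smaller
  excursions (solver ripple) are clamped to zero.
* Positivity floor for fitted parameters: 1e-12 — small enough that
  clinical fits with `detection_scale = 1` (data in counts/s against a
  7.4e9 Bq dose) can reach their optimum near zero partition values.
* Cumulated activity: trapezoid on the sampled grid (O(Δt²)); optional
  mono-exponential tail from a log-linear fit to the last ≥3 positive
  samples, refused when the terminal slope is non-negative.
* Tie-breaks/degenerate inputs: a zero gradient returns a zero subproblem
  step; equilibrium computation requires zero clearance and decay and
  rejects anything else; readers reject malformed rows rather than coerce.

## Problem sizes used in validation

The shipped validation runs use the study sizes stated above: 100 random
parameter sets for mass balance, 20 for the matrix-exponential oracle,
20 noisy replicates (cv 5 %) for recovery, 6-start multistarts for each of
the four clinical datasets, and a 100-point random-search baseline per
dataset.

## Known limitations

* The clearance-site split is effectively unidentifiable from sparse WBS
  data (see Identifiability); reported CL_K/CL_L from real fits should be
  interpreted as a sum.
* No uncertainty quantification (bootstrap/profile likelihood) — the
  iteration log and Gauss-Newton Hessian are exposed as building blocks.
* The counts/s ↔ Bq equivalence of the clinical tables is taken at face
  value; `detection_scale` exists to absorb a calibration factor but is
  fixed to 1 by default.
* No tumour compartment: fits describe normal-organ kinetics only.
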