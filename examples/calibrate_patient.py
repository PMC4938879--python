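"""Calibrate the model against a packaged clinical scintigraphy dataset.

Fits partition coefficients and intrinsic clearances to the dataset-1
liver/kidney/brain time-activity table (uniform least squares) with the
positivity-constrained trust-region/BFGS optimizer, using a seeded
log-spaced multistart followed by a Gauss-Newton-warm-started polish.
Prints the fitted parameters, the objective, and per-observation
residuals; smaller objective = closer model-data agreement in Bq^2.
"""

from dataclasses import replace

from radiopbpk import ObjectiveSpec, TrustRegionConfig, builtin_dataset, fit
from radiopbpk.calibration import fit_multistart
from radiopbpk.physiology import build_compartments, default_physiology

comp = build_compartments(default_physiology())
ds = builtin_dataset(1)
spec = ObjectiveSpec(dataset=ds)  # defaults: uniform weights, 6 free params

best = fit_multistart(
    spec, TrustRegionConfig(max_iterations=200), comp,
    n_starts=6, low=1e-10, high=10.0, seed=0,
)
polish = fit(
    spec, best.params,
    replace(TrustRegionConfig(max_iterations=150), gauss_newton_start=True),
    comp,
)
res = polish if polish.objective <= best.objective else best

print(f"patient: {ds.patient_id}   final objective: {res.objective:.4g}")
print(f"convergence: {res.convergence} after {len(res.iterations)} iterations")
print("fitted partition coefficients:")
for organ, value in res.params.partition.items():
    print(f"  P_{organ:3s} = {value:.4g}")
print("fitted intrinsic clearances [ml/min]:")
for organ, value in res.params.clearance.items():
    print(f"  CL_{organ} = {value:.4g}")
print("\nresiduals (model - data) [Bq]:")
for (t, organ, data), model in zip(res.observations, res.model_values):
    print(f"  t={t:6.1f} h  {organ:7s} data={data:6.2f}  model={model:8.3f}")
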