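"""Parameter-recovery study on synthetic scintigraphy data.

Generates noisy datasets on the patient-1 imaging grid from known ground
truth, refits the kidney/liver partitions and clearances, and reports the
per-parameter recovery errors.  Relative errors near zero at zero noise
show the calibration is consistent; the growth with noise shows how much
of each parameter the sparse 4-time-point design actually determines.
"""

from radiopbpk import recovery_study

report = recovery_study(
    noise_levels=(0.0, 0.05),
    n_reps=5,
    seed=42,
)

print("noise_cv  parameter  median|rel err|  rel RMSE   rel bias")
for row in report.rows:
    print(
        f"{row['noise_cv']:8.2f}  {row['parameter']:9s}"
        f"  {row['median_abs_rel_error']:14.4f}"
        f"  {row['rel_rmse']:8.4f}  {row['rel_bias']:+9.4f}"
    )
if report.failures:
    print("failures:", report.failures)
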