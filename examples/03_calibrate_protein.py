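"""Calibrate crude protein from ground-sample spectra, with screening.

Runs the full workflow: GH spectral-outlier screening (cutoff 3.0),
an initial PLS calibration, t-statistic lab-outlier screening (cutoff 2.5),
and a refit with cross-validated factor selection under the 16-factor cap.
"""

from haycal import CVSpec, GeneratorConfig, MathTreatment, acceptance_check, calibrate, generate

ds = generate(GeneratorConfig(species="alfalfa", n_samples=200, seed=7))
res = calibrate(ds, "CP", MathTreatment.from_string("1,4,4"), cv=CVSpec(k=10, seed=7))

row = res.summary_row()
print(f"selected samples : {row['n_selected']} of {res.provenance['n_initial']}")
print(f"PLS terms        : {row['pls_terms']}")
print(f"calibration      : R2 = {row['r2_cal']}, SEC = {row['sec']} %CP")
print(f"cross-validation : R2 = {row['r2_cv']}, SECV = {row['secv']} %CP")
print(f"RPD              : {row['rpd']}")
print(f"accepted (R2cv > 0.80 and RPD > 2): {acceptance_check(res)}")
# RPD is the reference SD over SECV: values above ~2 mean the calibration
# resolves real compositional differences, not just the population mean.
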