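# haycal

NIRS calibration workflow for forage nutritive analysis.

Commercial hay trading needs fast, reliable estimates of nutritive value —
dry matter (DM), crude protein (CP = N × 6.25), neutral and acid detergent
fiber (NDF, ADF), and in vitro dry matter digestibility (IVDMD) — without
waiting days for wet chemistry. Near-infrared reflectance spectroscopy
(NIRS) delivers that, but only through a carefully built calibration:
spectra must be pretreated, outliers screened, a partial least squares
model fitted and cross-validated, and the resulting statistics judged
against acceptance rules. `haycal` implements that workflow end to end for
spectra on the conventional 680–2,500 nm grid (2 nm steps, 911 channels),
and ships a synthetic hay-spectra generator so the whole pipeline — in
particular the effect of scanning ground (1-mm milled) versus unground
(<10 cm pieces) samples — can be studied without instrument data.

## The method

Reflectance is transformed to absorbance, A = log(1/R). Each "math
treatment" code *d, g, s* denotes a gap-segment derivative recipe: a boxcar
smooth of width *s* channels followed by *d* applications of the gap
difference Δ_g A(i) = A(i+g) − A(i), applied after standard normal variate
(SNV) scatter correction and a quadratic detrend. The conventional grid of
12 treatments is {1,2,3,4} × {(4,4), (8,8), (16,16)}.

Calibration is PLS1 by NIPALS with at most 16 latent factors; the factor
count minimises the cross-validated standard error. Outliers are screened
twice: spectrally by the GH (global H) statistic — the squared Mahalanobis
distance of a sample's factor scores divided by the factor count — with
cutoff 3.0, and against the laboratory values by the t-statistic
|ŷ − y| / SEC with cutoff 2.5. Reported statistics per analyte × treatment:

* **SEC / SECV** — standard error of calibration (denominator n − k − 1) /
  of cross-validation (root mean squared pooled out-of-fold residual);
* **R², R²cv** — coefficients of determination of calibration and
  cross-validation;
* **RPD** = SD(reference values) / SECV.

A calibration is *accepted* when R²cv > 0.80 and RPD > 2; an SECV/SEC ratio
above 1.3 is warned as an overfitting symptom. All statistics are computed
in percent (g/kg ÷ 10).

## Worked example

```bash
python examples/03_calibrate_protein.py
```

```
selected samples : 198 of 200
PLS terms        : 13
calibration      : R2 = 1.0, SEC = 0.07 %CP
cross-validation : R2 = 0.99, SECV = 0.26 %CP
RPD              : 8.27
accepted (R2cv > 0.80 and RPD > 2): True
```

Two synthetic alfalfa samples were dropped by screening; the remaining 198
calibrate crude protein with a cross-validated error of 0.26 percentage
points of CP, and the reference SD is 8.27 times that error — a strongly
usable calibration. Running `examples/05_ground_vs_unground.py` scans the
same samples under both preparations and prints, per analyte, the mean
cross-validated R²; ground preparation wins for every analyte:

```
 analyte  R2cv ground  R2cv unground
      DM        0.984          0.801
      CP        0.988          0.880
     NDF        0.943          0.674
     ADF        0.950          0.627
   IVDMD        0.888          0.586
```

The other examples cover simulation (`01`), preprocessing (`02`) and
treatment grid search (`04`). A thin CLI wraps the same library calls:

```bash
haycal simulate --species alfalfa --prep both --n 200 --seed 7 --out scratch/sim
haycal calibrate --spectra scratch/sim/alfalfa_ground_spectra.csv \
    --reference scratch/sim/alfalfa_ground_reference.csv \
    --analyte CP --treatments default12 --cv kfold:10 --seed 7 --out scratch/cal
haycal predict --model scratch/cal/CP_model.json --spectra scratch/sim/alfalfa_ground_spectra.csv
```

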