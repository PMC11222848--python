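"""End-to-end NIRS calibration: cross-validation statistics, outlier-screened
PLS fits, and model selection over the math-treatment grid.

For each analyte the workflow preprocesses the spectra with a math treatment,
screens spectral outliers (GH > 3.0) and laboratory outliers (t > 2.5),
selects the PLS factor count by cross-validation under the 16-factor cap,
and reports calibration and cross-validation statistics: R², SEC, R²cv,
SECV, and RPD (reference SD / SECV).  A calibration is accepted when
R²cv > 0.80 and RPD > 2.

All statistics are computed and reported in percent (g/kg ÷ 10).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pls as _pls
from .preprocess import MathTreatment, apply_treatment, default_treatments
from .screening import (
    DEFAULT_GH_CUTOFF,
    DEFAULT_T_CUTOFF,
    screen_lab,
    screen_spectral,
)
from .spectra_io import AlignedDataset

logger = logging.getLogger(__name__)

#: Acceptance rules for a usable calibration.
R2_CV_THRESHOLD = 0.80
RPD_THRESHOLD = 2.0
#: SECV/SEC ratio beyond which the model is warned as overfitting-prone.
SECV_SEC_RATIO_WARN = 1.3


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class CVSpec:
    """Cross-validation layout: k-fold (default 10) or leave-one-out."""

    scheme: str = "k_fold"
    k: int = 10
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self) -> None:
        if self.scheme not in ("k_fold", "leave_one_out"):
            raise CalibrationError(f"unknown CV scheme {self.scheme!r}")
        if self.scheme == "k_fold" and self.k < 2:
            raise CalibrationError("k must be >= 2")

    def folds(self, n: int, seed_offset: int = 0) -> list[np.ndarray]:
        """Partition range(n) into test-fold index arrays."""
        k = n if self.scheme == "leave_one_out" else self.k
        if k > n:
            raise CalibrationError(f"cannot make {k} folds from {n} samples")
        idx = np.arange(n)
        if self.shuffle and self.scheme == "k_fold":
            rng = np.random.default_rng(self.seed + seed_offset)
            rng.shuffle(idx)
        return [np.sort(f) for f in np.array_split(idx, k)]


@dataclass
class CalibrationResult:
    """Per analyte x treatment calibration and cross-validation statistics."""

    analyte: str
    treatment: MathTreatment
    n_selected: int
    n_factors: int
    r2_cal: float
    sec: float
    r2_cv: float
    secv: float
    rpd: float
    accepted: bool
    model: _pls.PLSModel | None = None
    provenance: dict = field(default_factory=dict)

    def summary_row(self) -> dict:
        """Tables-shaped row, rounded the way NIRS reports print."""
        return {
            "analyte": self.analyte,
            "math_treatment": str(self.treatment),
            "n_selected": self.n_selected,
            "pls_terms": self.n_factors,
            "r2_cal": round(self.r2_cal, 2),
            "sec": round(self.sec, 2),
            "r2_cv": round(self.r2_cv, 2),
            "secv": round(self.secv, 2),
            "rpd": round(self.rpd, 2),
            "accepted": self.accepted,
        }


def r_squared(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination, 1 - SSE/SST about the observed mean.

    Can be negative for predictions worse than the mean; a warning is logged
    but the value is not clamped.
    """
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_obs.size != y_pred.size:
        raise CalibrationError("observed and predicted vectors differ in length")
    sst = float(np.sum((y_obs - y_obs.mean()) ** 2))
    if sst == 0:
        raise CalibrationError("zero-variance observations; R² undefined")
    r2 = 1.0 - float(np.sum((y_obs - y_pred) ** 2)) / sst
    if r2 < 0:
        logger.warning("negative R² (%.3f): predictions worse than the mean", r2)
    return r2


def rpd(sd_reference: float, secv: float) -> float:
    """Ratio of performance to deviation: reference SD / SECV.

    Both arguments must be strictly positive and in the same units.
    """
    if not sd_reference > 0 or not secv > 0:
        raise CalibrationError("sd_reference and secv must be strictly positive")
    return sd_reference / secv


def sec_from_residuals(residuals: np.ndarray, n_factors: int) -> float:
    """Standard error of calibration with denominator n - k - 1."""
    residuals = np.asarray(residuals, dtype=float).ravel()
    dof = residuals.size - n_factors - 1
    if dof < 1:
        dof = 1
    return float(np.sqrt(np.sum(residuals**2) / dof))


def cv_prediction_matrix(
    X: np.ndarray, y: np.ndarray, cv: CVSpec, cap: int
) -> np.ndarray:
    """Pooled out-of-fold predictions for every nested factor count.

    Returns an (n, k_max) matrix whose column a holds each sample's
    out-of-fold prediction from a model with a+1 factors, where k_max is the
    largest factor count every training fold supports.  A fold whose
    training response is constant triggers one reshuffle; if it recurs the
    fold layout is rejected.
    """
    n = y.size
    for attempt in (0, 1):
        folds = cv.folds(n, seed_offset=attempt)
        if all(np.std(np.delete(y, f)) > 0 for f in folds):
            break
        if attempt == 1:
            raise CalibrationError("a fold has zero response variance even after reshuffle")
    preds: list[np.ndarray] = []
    k_max = cap
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rank truncation handled via k_max
        for f in folds:
            train = np.delete(np.arange(n), f)
            model = _pls.nipals_fit(X[train], y[train], cap)
            preds.append(_pls.predict_factorwise(model, X[f]))
            k_max = min(k_max, model.n_factors)
    out = np.zeros((n, k_max))
    for f, p in zip(folds, preds):
        out[f] = p[:, :k_max]
    return out


def cross_validate(
    dataset: AlignedDataset,
    analyte: str,
    treatment: MathTreatment,
    cv: CVSpec | None = None,
    cap: int = _pls.MAX_FACTORS,
    unit: str = "percent",
) -> CalibrationResult:
    """Cross-validated calibration of one analyte under one math treatment.

    Preprocessing is per-spectrum (SNV, detrend, derivatives), hence
    fold-safe; PLS centring and fitting use training folds only.  The factor
    count minimising SECV (ties toward fewer factors) is selected, then a
    final model is fitted on the full set for SEC / R² of calibration.
    SECV uses denominator n; SEC uses n - k - 1.  RPD is the selected set's
    reference SD (ddof=1) over SECV.
    """
    cv = cv or CVSpec()
    ds, y = dataset.analyte_view(analyte, unit=unit)
    X = apply_treatment(ds.spectra, treatment).absorbance
    n = y.size
    preds = cv_prediction_matrix(X, y, cv, cap)
    secv_curve = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    k_sel = int(np.argmin(secv_curve)) + 1
    y_cv = preds[:, k_sel - 1]
    secv = float(secv_curve[k_sel - 1])
    r2_cv = r_squared(y, y_cv)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = _pls.nipals_fit(
            X, y, k_sel, analyte=analyte, treatment=str(treatment),
            training_ids=list(ds.sample_ids),
        )
    fitted = _pls.predict(model, X)
    sec = sec_from_residuals(y - fitted, model.n_factors)
    r2_cal = r_squared(y, fitted)
    sd_ref = float(np.std(y, ddof=1))
    rpd_val = rpd(sd_ref, secv)
    result = CalibrationResult(
        analyte=analyte,
        treatment=treatment,
        n_selected=n,
        n_factors=model.n_factors,
        r2_cal=r2_cal,
        sec=sec,
        r2_cv=r2_cv,
        secv=secv,
        rpd=rpd_val,
        accepted=(r2_cv > R2_CV_THRESHOLD and rpd_val > RPD_THRESHOLD),
        model=model,
        provenance={
            "cv": cv,
            "unit": unit,
            "secv_by_factor": secv_curve.tolist(),
            "sd_reference": sd_ref,
            "training_ids": list(ds.sample_ids),
        },
    )
    return result


def calibrate(
    dataset: AlignedDataset,
    analyte: str,
    treatment: MathTreatment,
    cv: CVSpec | None = None,
    cap: int = _pls.MAX_FACTORS,
    unit: str = "percent",
    gh_cutoff: float = DEFAULT_GH_CUTOFF,
    t_cutoff: float = DEFAULT_T_CUTOFF,
    screening_factors: int = 10,
    max_spectral_rounds: int = 2,
) -> CalibrationResult:
    """Full workflow: spectral screening, initial fit, lab screening, refit.

    Spectral outliers (GH > ``gh_cutoff`` on PCA scores of the treated
    spectra) are removed first, for at most ``max_spectral_rounds`` rounds.
    An initial cross-validated calibration then supplies fitted values and
    SEC for the t-statistic rule; lab outliers (t > ``t_cutoff``) are
    removed and the model refitted once.  ``n_selected`` in the result is
    the post-screening sample count.
    """
    cv = cv or CVSpec()
    ds, y = dataset.analyte_view(analyte, unit=unit)
    n0 = ds.n_samples

    spec_report = screen_spectral(
        ds, treatment, k=min(screening_factors, n0 - 1),
        cutoff=gh_cutoff, max_rounds=max_spectral_rounds,
    )
    keep = spec_report.kept_indices()
    ds1 = ds.subset(keep)

    first = cross_validate(ds1, analyte, treatment, cv=cv, cap=cap, unit=unit)
    fitted = _pls.predict(first.model, apply_treatment(ds1.spectra, treatment).absorbance)
    lab_report = screen_lab(y[keep], fitted, first.sec, cutoff=t_cutoff,
                            sample_ids=ds1.sample_ids)
    lab_keep = lab_report.kept_indices()
    if lab_keep.size == len(keep):
        final = first
        ds2 = ds1
    else:
        ds2 = ds1.subset(lab_keep)
        final = cross_validate(ds2, analyte, treatment, cv=cv, cap=cap, unit=unit)

    removed_spectral = [ds.sample_ids[i] for i in np.flatnonzero(spec_report.flagged)]
    removed_lab = [ds1.sample_ids[i] for i in np.flatnonzero(lab_report.flagged)]
    final.provenance.update(
        {
            "n_initial": n0,
            "removed_spectral": removed_spectral,
            "removed_lab": removed_lab,
            "gh_cutoff": gh_cutoff,
            "t_cutoff": t_cutoff,
            "sec_before_lab_screen": first.sec,
            "secv_sec_ratio": final.secv / final.sec if final.sec > 0 else float("inf"),
        }
    )
    logger.info(
        "%s / %s: kept %d of %d (%d spectral, %d lab outliers)",
        analyte, treatment, final.n_selected, n0,
        len(removed_spectral), len(removed_lab),
    )
    return final


def grid_search(
    dataset: AlignedDataset,
    analyte: str,
    treatments: list[MathTreatment] | None = None,
    cv: CVSpec | None = None,
    cap: int = _pls.MAX_FACTORS,
    unit: str = "percent",
    screen: bool = True,
    **screen_kwargs,
) -> CalibrationResult:
    """Evaluate a treatment grid and return the best calibration.

    Default grid is the conventional 12 treatments.  The winner minimises
    SECV; ties break toward higher R²cv, then lower derivative order.  The
    full per-treatment table is kept in ``provenance["grid"]``.
    """
    treatments = treatments if treatments is not None else default_treatments()
    if not treatments:
        raise CalibrationError("empty treatment list")
    results: list[CalibrationResult] = []
    for t in treatments:
        if screen:
            res = calibrate(dataset, analyte, t, cv=cv, cap=cap, unit=unit, **screen_kwargs)
        else:
            res = cross_validate(dataset, analyte, t, cv=cv, cap=cap, unit=unit)
        results.append(res)
    best = min(
        results,
        key=lambda r: (r.secv, -r.r2_cv, r.treatment.derivative_order),
    )
    best.provenance["grid"] = pd.DataFrame([r.summary_row() for r in results])
    return best


def acceptance_check(result: CalibrationResult) -> bool:
    """Apply the acceptance rules: R²cv > 0.80 and RPD > 2.

    Also logs the SECV/SEC ratio; a ratio above ``SECV_SEC_RATIO_WARN``
    (default 1.3) warns that cross-validation error is far from calibration
    error, the usual overfitting symptom.
    """
    ratio = result.secv / result.sec if result.sec > 0 else float("inf")
    if ratio > SECV_SEC_RATIO_WARN:
        logger.warning(
            "%s / %s: SECV/SEC = %.2f exceeds %.2f; SECV not close to SEC",
            result.analyte, result.treatment, ratio, SECV_SEC_RATIO_WARN,
        )
    return result.r2_cv > R2_CV_THRESHOLD and result.rpd > RPD_THRESHOLD


def summary_table(results: list[CalibrationResult]) -> pd.DataFrame:
    """Render results as the conventional calibration-report table."""
    return pd.DataFrame([r.summary_row() for r in results])
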