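"""Outlier screening: spectral GH (global H) distance and the lab t-statistic.

Spectral outliers are flagged by the GH statistic — the squared Mahalanobis
distance of a sample's factor scores from the score centroid, divided by the
number of factors — with the conventional cutoff of 3.0.  Under this
normalisation the calibration-set mean of GH is (n-1)/n, just below 1, so the
cutoff reads as "three times the average spectral leverage".

Laboratory outliers are flagged where |predicted - observed| exceeds 2.5
standard errors of calibration (the t-statistic rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import MathTreatment, apply_treatment
from .spectra_io import AlignedDataset

DEFAULT_GH_CUTOFF = 3.0
DEFAULT_T_CUTOFF = 2.5


class ScreeningError(ValueError):
    pass


class RankError(ScreeningError):
    """Score covariance singular; advise using fewer factors."""


@dataclass
class OutlierReport:
    sample_ids: list[str]
    gh: np.ndarray | None = None
    t_stat: np.ndarray | None = None
    spectral_flag: np.ndarray | None = None
    lab_flag: np.ndarray | None = None
    gh_cutoff: float | None = None
    t_cutoff: float | None = None
    round_removed: np.ndarray | None = None   # 0 = kept; >=1 = screening round

    @property
    def flagged(self) -> np.ndarray:
        n = len(self.sample_ids)
        out = np.zeros(n, dtype=bool)
        if self.spectral_flag is not None:
            out |= self.spectral_flag
        if self.lab_flag is not None:
            out |= self.lab_flag
        return out

    def kept_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.flagged)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"sample_id": self.sample_ids})
        if self.gh is not None:
            df["gh"] = self.gh
            df["spectral_flag"] = self.spectral_flag
        if self.t_stat is not None:
            df["t_stat"] = self.t_stat
            df["lab_flag"] = self.lab_flag
        if self.round_removed is not None:
            df["round_removed"] = self.round_removed
        return df


def gh_distance(scores: np.ndarray) -> np.ndarray:
    """GH(i) = D²(i) / k for score vectors in a (n, k) matrix.

    D² is the squared Mahalanobis distance from the score centroid under the
    sample (ddof=1) score covariance.  The set mean of GH is identically
    (n-1)/n.
    """
    T = np.atleast_2d(np.asarray(scores, dtype=float))
    if T.ndim != 2 or T.shape[1] < 1:
        raise ScreeningError("scores must be a (n, k) matrix with k >= 1")
    n, k = T.shape
    if n < 2:
        raise ScreeningError("need at least 2 samples for a GH distance")
    Tc = T - T.mean(axis=0)
    cov = (Tc.T @ Tc) / (n - 1)
    try:
        sol = np.linalg.solve(cov, Tc.T)
    except np.linalg.LinAlgError:
        raise RankError(
            "singular score covariance; use fewer factors for screening"
        ) from None
    d2 = np.einsum("ij,ji->i", Tc, sol)
    return d2 / k


def _pca_scores(X: np.ndarray, k: int) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    k = min(k, int(np.sum(s > s[0] * 1e-12)))
    if k < 1:
        raise RankError("spectra have no variance; cannot derive scores")
    return U[:, :k] * s[:k]


def screen_spectral(
    dataset: AlignedDataset,
    treatment: MathTreatment,
    k: int,
    cutoff: float = DEFAULT_GH_CUTOFF,
    response: np.ndarray | None = None,
    max_rounds: int = 2,
) -> OutlierReport:
    """Iterative GH screening of a dataset's preprocessed spectra.

    Scores come from a PLS decomposition when ``response`` is given, else
    from PCA of the treated spectra.  Flagged samples are removed and scores
    re-derived for up to ``max_rounds`` rounds; GH values reported for
    removed samples are those from the round that flagged them.
    """
    if k < 1:
        raise ScreeningError("k must be >= 1")
    X = apply_treatment(dataset.spectra, treatment).absorbance
    n = X.shape[0]
    gh_out = np.zeros(n)
    removed_round = np.zeros(n, dtype=int)
    active = np.arange(n)
    for rnd in range(1, max_rounds + 1):
        if active.size < 3:
            raise ScreeningError("screening removed almost all samples; pathological input")
        if response is not None:
            from .pls import nipals_fit

            kk = min(k, active.size - 1)
            model = nipals_fit(X[active], np.asarray(response)[active], kk)
            T = model.scores
        else:
            T = _pca_scores(X[active], min(k, active.size - 1))
        gh = gh_distance(T)
        gh_out[active] = gh
        newly = gh > cutoff
        if not np.any(newly):
            break
        removed_round[active[newly]] = rnd
        active = active[~newly]
    if active.size == 0:
        raise ScreeningError("all samples flagged as spectral outliers")
    return OutlierReport(
        sample_ids=list(dataset.sample_ids),
        gh=gh_out,
        spectral_flag=removed_round > 0,
        gh_cutoff=cutoff,
        round_removed=removed_round,
    )


def screen_lab(
    y_obs: np.ndarray,
    y_pred: np.ndarray,
    sec: float,
    cutoff: float = DEFAULT_T_CUTOFF,
    sample_ids: list[str] | None = None,
) -> OutlierReport:
    """Flag samples whose |predicted - observed| exceeds ``cutoff`` x SEC.

    The comparison is strict, so a residual of exactly 2.5 standard errors
    is kept.
    """
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_obs.size != y_pred.size:
        raise ScreeningError("observed and predicted vectors differ in length")
    if not sec > 0:
        raise ScreeningError(f"sec must be > 0, got {sec}")
    t = np.abs(y_pred - y_obs) / sec
    ids = sample_ids if sample_ids is not None else [str(i) for i in range(y_obs.size)]
    return OutlierReport(
        sample_ids=list(ids),
        t_stat=t,
        lab_flag=t > cutoff,
        t_cutoff=cutoff,
    )
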