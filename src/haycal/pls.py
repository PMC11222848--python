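"""NIPALS partial least squares (PLS1) regression.

One response per model, matching the per-analyte calibrations NIRS software
produces.  Factors are extracted by successive deflation in order of
covariance with the response; predictors are mean-centred (autoscaling is
optional and off by default, the usual NIRS choice).  The factor count is
capped at 16.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

#: Conventional ceiling on the number of latent factors.
MAX_FACTORS = 16

#: Numerical floor below which a weight/score is treated as rank exhaustion.
_TOL = 1e-10


class PLSError(ValueError):
    pass


class DegenerateResponseError(PLSError):
    """Response has zero variance; no regression is possible."""


@dataclass
class PLSModel:
    """A fitted NIPALS PLS1 decomposition.

    ``weights`` (W), ``loadings`` (P) and ``q`` hold one row/entry per
    factor; ``b`` is the equivalent regression vector so that
    ``yhat = (X - x_mean) @ b + y_mean``.
    """

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray          # (k, p)
    loadings: np.ndarray         # (k, p)
    q: np.ndarray                # (k,)
    b: np.ndarray                # (p,)
    n_factors: int
    x_scale: np.ndarray | None = None
    scores: np.ndarray | None = None   # training scores T, (n, k)
    treatment: str | None = None
    analyte: str | None = None
    training_ids: list[str] | None = None

    @property
    def n_channels(self) -> int:
        return int(self.b.size)

    def to_json(self, path) -> None:
        """Serialise to a self-describing JSON file (predict can run standalone)."""
        payload = {
            "format": "haycal-pls-model",
            "version": 1,
            "analyte": self.analyte,
            "treatment": self.treatment,
            "n_factors": self.n_factors,
            "x_mean": self.x_mean.tolist(),
            "y_mean": float(self.y_mean),
            "x_scale": None if self.x_scale is None else self.x_scale.tolist(),
            "weights": self.weights.tolist(),
            "loadings": self.loadings.tolist(),
            "q": self.q.tolist(),
            "b": self.b.tolist(),
            "training_ids": self.training_ids,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PLSModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if payload.get("format") != "haycal-pls-model":
            raise PLSError(f"{path} is not a haycal PLS model file")
        return cls(
            x_mean=np.asarray(payload["x_mean"], dtype=float),
            y_mean=float(payload["y_mean"]),
            weights=np.asarray(payload["weights"], dtype=float),
            loadings=np.asarray(payload["loadings"], dtype=float),
            q=np.asarray(payload["q"], dtype=float),
            b=np.asarray(payload["b"], dtype=float),
            n_factors=int(payload["n_factors"]),
            x_scale=None if payload["x_scale"] is None else np.asarray(payload["x_scale"]),
            treatment=payload.get("treatment"),
            analyte=payload.get("analyte"),
            training_ids=payload.get("training_ids"),
        )


def nipals_fit(
    X: np.ndarray,
    y: np.ndarray,
    n_factors: int,
    scale: bool = False,
    analyte: str | None = None,
    treatment: str | None = None,
    training_ids: list[str] | None = None,
) -> PLSModel:
    """Fit a PLS1 model with up to ``n_factors`` latent factors.

    If the requested factor count exceeds the effective rank of the deflated
    predictor matrix, extraction stops early with a warning and the model
    carries the factors actually found.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise PLSError(f"X has {n} rows but y has {y.size} values")
    if n_factors < 1:
        raise PLSError("n_factors must be >= 1")
    if np.std(y) == 0:
        raise DegenerateResponseError("response has zero variance")
    cap = min(n_factors, MAX_FACTORS, n - 1, p)

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    x_scale = None
    if scale:
        x_scale = Xc.std(axis=0, ddof=1)
        x_scale[x_scale == 0] = 1.0
        Xc = Xc / x_scale
    yc = y - y_mean

    ref = float(np.linalg.norm(X - x_mean)) or 1.0
    W = np.zeros((cap, p))
    P = np.zeros((cap, p))
    Q = np.zeros(cap)
    T = np.zeros((n, cap))
    k = 0
    for a in range(cap):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw <= _TOL * ref:
            warnings.warn(
                f"rank exhausted after {k} factors (requested {cap}); truncating",
                stacklevel=2,
            )
            break
        # With a single response u = y, so the NIPALS inner loop converges in
        # one pass; no iteration is needed beyond the covariance weight.
        w = w / nw
        t = Xc @ w
        tt = float(t @ t)
        if tt <= (_TOL * ref) ** 2:
            warnings.warn(f"degenerate score at factor {a + 1}; truncating", stacklevel=2)
            break
        P[a] = Xc.T @ t / tt
        Q[a] = float(yc @ t) / tt
        W[a] = w
        T[:, a] = t
        Xc = Xc - np.outer(t, P[a])
        yc = yc - Q[a] * t
        k += 1
    if k == 0:
        raise DegenerateResponseError("no usable covariance between X and y")
    W, P, Q, T = W[:k], P[:k], Q[:k], T[:, :k]
    b = W.T @ np.linalg.solve(P @ W.T, Q)
    if x_scale is not None:
        b = b / x_scale
    return PLSModel(
        x_mean=x_mean, y_mean=y_mean, weights=W, loadings=P, q=Q, b=b,
        n_factors=k, x_scale=x_scale, scores=T,
        treatment=treatment, analyte=analyte, training_ids=training_ids,
    )


def predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predicted response: ``(X_new - x_mean) @ b + y_mean``."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.n_channels:
        raise PLSError(
            f"channel mismatch: model expects {model.n_channels}, got {X_new.shape[1]}"
        )
    return (X_new - model.x_mean) @ model.b + model.y_mean


def predict_factorwise(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Cumulative predictions for every nested factor count.

    Returns an ``(n, k)`` matrix whose column ``a`` is the prediction of the
    sub-model using factors ``1..a+1``; the last column equals
    :func:`predict`.  Used for cross-validated factor selection.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.n_channels:
        raise PLSError(
            f"channel mismatch: model expects {model.n_channels}, got {X_new.shape[1]}"
        )
    Xc = X_new - model.x_mean
    if model.x_scale is not None:
        Xc = Xc / model.x_scale
    out = np.zeros((X_new.shape[0], model.n_factors))
    acc = np.full(X_new.shape[0], model.y_mean)
    for a in range(model.n_factors):
        t = Xc @ model.weights[a]
        acc = acc + model.q[a] * t
        out[:, a] = acc
        Xc = Xc - np.outer(t, model.loadings[a])
    return out


def scores(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Factor scores of new (preprocessed) spectra under the model."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    Xc = X_new - model.x_mean
    if model.x_scale is not None:
        Xc = Xc / model.x_scale
    T = np.zeros((X_new.shape[0], model.n_factors))
    for a in range(model.n_factors):
        t = Xc @ model.weights[a]
        T[:, a] = t
        Xc = Xc - np.outer(t, model.loadings[a])
    return T


def select_factors(X: np.ndarray, y: np.ndarray, cap: int = MAX_FACTORS, cv=None) -> int:
    """Cross-validated factor count: minimise SECV, ties toward fewer factors.

    ``cv`` is a :class:`haycal.calibration.CVSpec`; 10-fold with seed 0 when
    omitted.
    """
    from .calibration import CVSpec, cv_prediction_matrix

    if cap < 1:
        raise PLSError("cap must be >= 1")
    cv = cv or CVSpec()
    preds = cv_prediction_matrix(np.asarray(X, float), np.asarray(y, float).ravel(), cv, cap)
    secv = np.sqrt(np.mean((preds - np.asarray(y, float).ravel()[:, None]) ** 2, axis=0))
    return int(np.argmin(secv)) + 1
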