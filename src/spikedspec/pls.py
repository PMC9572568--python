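"""Single-response partial least squares regression (NIPALS).

The model extracts orthogonal X-scores T = XR with sequentially maximal
covariance with the response, regresses y on the scores (y-hat = Tq) and
folds the two together into a regression vector b = Rq so that
y-hat = Xb on centered data. Deterministic: the single-response NIPALS
weight for each component is the exact covariance direction, so no random
initialisation or iteration-to-convergence is involved; X alone is deflated.

X and y are mean-centered internally; the stored offsets are restored at
prediction time, so callers pass data on the original (already pipeline
pre-treated) scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    DegenerateInputError,
    DimensionMismatchError,
    RankError,
    ZeroVarianceError,
)

__all__ = ["PLSModel", "fit_pls", "predict_pls", "regression_fom"]

_TINY = 1e-12


@dataclass
class PLSModel:
    """A fitted single-response PLS model.

    Attributes
    ----------
    F : number of latent variables.
    W, P : X-weights and X-loadings, ``(p, F)``.
    R : transformed weights with ``T = Xc R``, ``(p, F)``.
    q : y-loadings, ``(F,)``.
    b : regression vector ``R q``, ``(p,)``.
    T : training scores ``(n, F)`` (kept for VIP and leverage computations).
    x_mean, y_mean : centering offsets learned from the training set.
    wavenumbers : optional axis the model was trained on (post pre-treatment).
    """

    F: int
    W: np.ndarray
    P: np.ndarray
    R: np.ndarray
    q: np.ndarray
    b: np.ndarray
    T: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    wavenumbers: np.ndarray | None = None

    @property
    def n_train(self) -> int:
        return self.T.shape[0]

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        return predict_pls(self, X_new)

    def predict_via_scores(self, X_new: np.ndarray) -> np.ndarray:
        """Prediction through the score route T_new q (identity check path)."""
        Xc = _check_dims(self, X_new)
        return (Xc @ self.R) @ self.q + self.y_mean

    def predict_all_components(self, X_new: np.ndarray) -> np.ndarray:
        """``(n, F)`` matrix of predictions using 1..F components.

        Column ``f-1`` equals the prediction of the truncated model with the
        first ``f`` latent variables; used to evaluate a whole complexity
        grid from a single fit.
        """
        Xc = _check_dims(self, X_new)
        return np.cumsum((Xc @ self.R) * self.q, axis=1) + self.y_mean

    def truncated(self, F: int) -> "PLSModel":
        """The sub-model using only the first ``F`` components."""
        if not (1 <= F <= self.F):
            raise RankError(f"F must be in 1..{self.F}, got {F}")
        R = self.R[:, :F]
        q = self.q[:F]
        return PLSModel(F=F, W=self.W[:, :F], P=self.P[:, :F], R=R, q=q,
                        b=R @ q, T=self.T[:, :F], x_mean=self.x_mean,
                        y_mean=self.y_mean, wavenumbers=self.wavenumbers)

    # -- plain-text serialization -------------------------------------------

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "F": self.F,
            "W": self.W.tolist(), "P": self.P.tolist(), "R": self.R.tolist(),
            "q": self.q.tolist(), "b": self.b.tolist(), "T": self.T.tolist(),
            "x_mean": self.x_mean.tolist(), "y_mean": self.y_mean,
            "wavenumbers": None if self.wavenumbers is None else self.wavenumbers.tolist(),
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PLSModel":
        d = json.loads(Path(path).read_text())
        wn = d.get("wavenumbers")
        return cls(F=d["F"], W=np.array(d["W"]), P=np.array(d["P"]),
                   R=np.array(d["R"]), q=np.array(d["q"]), b=np.array(d["b"]),
                   T=np.array(d["T"]), x_mean=np.array(d["x_mean"]),
                   y_mean=float(d["y_mean"]),
                   wavenumbers=None if wn is None else np.array(wn))


def _check_dims(m: PLSModel, X_new: np.ndarray) -> np.ndarray:
    X_new = np.atleast_2d(np.asarray(X_new, float))
    if X_new.shape[1] != len(m.x_mean):
        raise DimensionMismatchError(
            f"model expects {len(m.x_mean)} wavenumbers, got {X_new.shape[1]}"
        )
    return X_new - m.x_mean


def fit_pls(X: np.ndarray, y: np.ndarray, F: int,
            wavenumbers: np.ndarray | None = None,
            strict_rank: bool = True) -> PLSModel:
    """Fit a single-response PLS model with ``F`` latent variables.

    Parameters
    ----------
    X : ``(n, p)`` predictor matrix (pre-treated spectra).
    y : length-``n`` response (mg/L, or a 0/1 dummy vector for PLS-DA).
    F : number of latent variables, ``1 <= F <= min(n-1, p)``.
    strict_rank : when True (default), exhausting the X/y covariance before
        ``F`` components raises :class:`RankError`; when False the model is
        returned with however many components could be extracted (used when
        scanning a complexity grid).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if X.ndim != 2:
        raise DimensionMismatchError("X must be 2-D")
    n, p = X.shape
    if len(y) != n:
        raise DimensionMismatchError(f"y has length {len(y)}, X has {n} rows")
    if F < 1 or F > min(n - 1, p):
        raise RankError(f"F must be in 1..min(n-1, p) = {min(n - 1, p)}, got {F}")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    if np.allclose(yc, 0.0):
        raise ZeroVarianceError("response has zero variance")

    W = np.empty((p, F))
    P = np.empty((p, F))
    T = np.empty((n, F))
    q = np.empty(F)
    Xd = Xc.copy()
    norm0 = tt0 = None
    n_extracted = F
    for f in range(F):
        w = Xd.T @ yc
        norm = np.linalg.norm(w)
        if norm0 is None:
            norm0 = norm
        exhausted = norm < _TINY or norm < 1e-10 * norm0
        if not exhausted:
            w /= norm
            t = Xd @ w
            tt = float(t @ t)
            if tt0 is None:
                tt0 = tt
            exhausted = tt < _TINY * max(tt0, 1.0)
        if exhausted:
            if strict_rank:
                raise RankError(
                    f"X is rank-deficient: no covariance left at component {f + 1}"
                )
            n_extracted = f
            break
        q_f = float(t @ yc) / tt
        pload = (Xd.T @ t) / tt
        Xd -= np.outer(t, pload)
        W[:, f], P[:, f], T[:, f], q[f] = w, pload, t, q_f
    if n_extracted == 0:
        raise RankError("no covariance between X and y at the first component")
    if n_extracted < F:
        F = n_extracted
        W, P, T, q = W[:, :F], P[:, :F], T[:, :F], q[:F]

    # T = Xc R with R = W (P^T W)^(-1)
    R = np.linalg.solve((P.T @ W).T, W.T).T
    b = R @ q
    return PLSModel(F=F, W=W, P=P, R=R, q=q, b=b, T=T,
                    x_mean=x_mean, y_mean=y_mean, wavenumbers=wavenumbers)


def predict_pls(m: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predicted responses ``(X_new - x_mean) b + y_mean``."""
    return _check_dims(m, X_new) @ m.b + m.y_mean


def regression_fom(y_pred: np.ndarray, y_true: np.ndarray) -> dict[str, float]:
    """Regression figures of merit: root mean square error, bias and R^2.

    ``rmse = sqrt(mean((y_pred - y_true)^2))``; ``bias = mean(y_pred - y_true)``;
    ``r2 = 1 - SS_res / SS_tot`` about the evaluated set's own mean, which can
    go negative when predictions are worse than that mean.
    """
    y_pred = np.asarray(y_pred, float).ravel()
    y_true = np.asarray(y_true, float).ravel()
    if len(y_pred) != len(y_true):
        raise DimensionMismatchError("prediction and truth differ in length")
    if len(y_true) < 2:
        raise DegenerateInputError("need at least 2 observations")
    err = y_pred - y_true
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ZeroVarianceError("R^2 undefined: evaluated responses have zero variance")
    return {
        "rmse": float(np.sqrt(np.mean(err ** 2))),
        "bias": float(np.mean(err)),
        "r2": 1.0 - float(np.sum(err ** 2)) / ss_tot,
    }
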