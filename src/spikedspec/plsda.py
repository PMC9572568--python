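"""PLS discriminant analysis for the pure-vs-spiked decision.

Class membership is dummy coded (spiked -> 1, pure -> 0), a single-response
PLS model is fitted to the dummy vector, and a scalar decision threshold is
derived by one-dimensional linear discriminant analysis on the training
predictions: with pooled within-class variance and equal priors the LDA
boundary is the midpoint of the two class means of the predicted response.
A sample is called spiked when its predicted response exceeds the threshold;
a prediction exactly on the threshold is called pure (the rule favours the
"not spiked" null claim).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, DimensionMismatchError
from .pls import PLSModel, fit_pls, predict_pls
from .spectra import CLASS_PURE, CLASS_SPIKED

__all__ = [
    "encode_classes",
    "decode_classes",
    "lda_threshold",
    "LDAThreshold",
    "PLSDAModel",
    "fit_plsda",
    "classify",
    "classification_fom",
    "round_half_away",
]


def encode_classes(labels: np.ndarray) -> np.ndarray:
    """Dummy-code class labels: spiked -> 1, pure -> 0."""
    labels = np.asarray(labels, dtype=object)
    bad = set(labels) - {CLASS_PURE, CLASS_SPIKED}
    if bad:
        raise ValueError(f"unknown class labels: {sorted(bad)}")
    return (labels == CLASS_SPIKED).astype(float)


def decode_classes(dummy: np.ndarray) -> np.ndarray:
    """Inverse of :func:`encode_classes` on exact 0/1 vectors."""
    dummy = np.asarray(dummy, float)
    if not np.all(np.isin(dummy, (0.0, 1.0))):
        raise ValueError("dummy vector must contain only 0 and 1")
    return np.where(dummy == 1.0, CLASS_SPIKED, CLASS_PURE).astype(object)


@dataclass(frozen=True)
class LDAThreshold:
    """Decision threshold plus the training class means it came from."""

    threshold: float
    mean_pure: float
    mean_spiked: float

    def __float__(self) -> float:
        return self.threshold


def lda_threshold(
    y_hat_train: np.ndarray,
    y_dummy_train: np.ndarray,
    priors: str = "equal",
) -> LDAThreshold:
    """LDA boundary on the 1-D predicted responses.

    With pooled within-class variance, equal priors put the boundary at the
    midpoint of the class means of ``y_hat_train``. ``priors="proportional"``
    shifts it by ``s2 * ln(n_pure / n_spiked) / (m_spiked - m_pure)`` with
    ``s2`` the pooled within-class variance.
    """
    y_hat = np.asarray(y_hat_train, float).ravel()
    dummy = np.asarray(y_dummy_train, float).ravel()
    if len(y_hat) != len(dummy):
        raise DimensionMismatchError("predictions and dummy vector differ in length")
    spiked = y_hat[dummy == 1.0]
    pure = y_hat[dummy == 0.0]
    if len(spiked) == 0 or len(pure) == 0:
        raise DegenerateInputError("both classes must be present to set a threshold")
    m1, m0 = float(spiked.mean()), float(pure.mean())
    thr = 0.5 * (m0 + m1)
    if priors == "proportional":
        n0, n1 = len(pure), len(spiked)
        ss = float(np.sum((pure - m0) ** 2) + np.sum((spiked - m1) ** 2))
        s2 = ss / max(n0 + n1 - 2, 1)
        if m1 != m0 and s2 > 0:
            thr += s2 * math.log(n0 / n1) / (m1 - m0)
    elif priors != "equal":
        raise ValueError(f"priors must be 'equal' or 'proportional', got {priors!r}")
    return LDAThreshold(threshold=thr, mean_pure=m0, mean_spiked=m1)


@dataclass
class PLSDAModel:
    """A PLS model on the dummy response plus its LDA decision threshold."""

    pls: PLSModel
    threshold: LDAThreshold
    priors: str = "equal"

    def decision_values(self, X_new: np.ndarray) -> np.ndarray:
        return predict_pls(self.pls, X_new)

    def classify(self, X_new: np.ndarray) -> np.ndarray:
        return classify(self, X_new)


def fit_plsda(
    X: np.ndarray,
    labels: np.ndarray,
    F: int,
    priors: str = "equal",
    wavenumbers: np.ndarray | None = None,
) -> PLSDAModel:
    """Fit PLS on the dummy-coded labels and derive the LDA threshold."""
    dummy = encode_classes(labels)
    pls = fit_pls(X, dummy, F, wavenumbers=wavenumbers)
    thr = lda_threshold(predict_pls(pls, X), dummy, priors=priors)
    return PLSDAModel(pls=pls, threshold=thr, priors=priors)


def classify(m: PLSDAModel, X_new: np.ndarray) -> np.ndarray:
    """Assign spiked when the predicted response exceeds the threshold."""
    y_hat = m.decision_values(X_new)
    return np.where(y_hat > m.threshold.threshold, CLASS_SPIKED, CLASS_PURE).astype(object)


def classification_fom(
    pred_labels: np.ndarray, true_labels: np.ndarray
) -> dict[str, float]:
    """Classification figures of merit, all in percent.

    ``accuracy`` is the overall fraction correct; the two sensitivities are
    per-class correct classification rates; ``average_ccr`` is their
    unweighted mean (so accuracy equals the class-size-weighted mean of the
    sensitivities).
    """
    pred = np.asarray(pred_labels, dtype=object)
    true = np.asarray(true_labels, dtype=object)
    if len(pred) != len(true):
        raise DimensionMismatchError("label vectors differ in length")
    if len(true) == 0:
        raise ValueError("empty label vectors")
    sens = {}
    for cls in (CLASS_SPIKED, CLASS_PURE):
        mask = true == cls
        if not mask.any():
            raise DegenerateInputError(f"no samples of class {cls!r} to evaluate")
        sens[cls] = 100.0 * float(np.mean(pred[mask] == cls))
    return {
        "accuracy": 100.0 * float(np.mean(pred == true)),
        "sensitivity_spiked": sens[CLASS_SPIKED],
        "sensitivity_pure": sens[CLASS_PURE],
        "average_ccr": 0.5 * (sens[CLASS_SPIKED] + sens[CLASS_PURE]),
    }


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (report convention, e.g. 0.125 -> 0.13)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)
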