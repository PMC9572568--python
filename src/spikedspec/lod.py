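"""Multivariate limit of detection for a PLS calibration.

Follows the Allegrini-Olivieri error-propagation approach: the detection
limit depends on the spectral noise level, the model's sensitivity (the
inverse norm of the regression vector) and the leverage a blank sample has
in the calibration score space,

    LOD = 3.3 * sqrt( ||b||^2 sigma_x^2 (1 + h0) + h0 * sigma_ycal^2 )

where ``h0`` is the minimum blank-level leverage ``t0' (T'T)^-1 t0``
computed from the calibration scores, ``sigma_x`` the per-channel spectral
noise SD (absorbance) and ``sigma_ycal`` the SD of the calibration
concentration errors (mg/L). The 3.3 factor folds the conventional 0.05
false-positive and false-negative rates into one multiplier. This is the
"minimum LOD" single-number variant; interval variants are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NotFittedError, ParameterError
from .pls import PLSModel

__all__ = ["LODEstimate", "estimate_lod", "estimate_sigma_x"]


@dataclass(frozen=True)
class LODEstimate:
    """Limit of detection and the quantities that produced it."""

    lod: float  # mg/L
    sigma_x: float  # absorbance
    sigma_ycal: float  # mg/L
    h0: float  # blank leverage, dimensionless
    sen: float  # sensitivity = 1 / ||b||, absorbance per mg/L


def estimate_sigma_x(m: PLSModel, X_cal: np.ndarray) -> float:
    """Pooled spectral noise SD from the F-component reconstruction residuals.

    With no replicate scans available, the per-channel noise is estimated as
    the RMS of ``Xc - T P'`` over all calibration cells, with ``n - F - 1``
    residual degrees of freedom per channel.
    """
    X_cal = np.asarray(X_cal, float)
    Xc = X_cal - m.x_mean
    resid = Xc - m.T @ m.P.T
    n, p = resid.shape
    dof = max(n - m.F - 1, 1)
    return float(np.sqrt(np.sum(resid ** 2) / (dof * p)))


def _blank_leverage(m: PLSModel, y_cal: np.ndarray) -> float:
    """Minimum leverage of a blank-level sample in the calibration score space.

    If the calibration contains true blanks (y == 0) their score leverages
    are computed directly and the minimum taken; otherwise the
    pseudounivariate expression ``ybar^2 / sum((y - ybar)^2)`` — the leverage
    of a hypothetical sample predicted at zero concentration — is used.
    """
    y_cal = np.asarray(y_cal, float).ravel()
    TtT_inv = np.linalg.inv(m.T.T @ m.T)
    blanks = np.flatnonzero(y_cal == 0.0)
    if blanks.size:
        t0 = m.T[blanks]
        lev = np.einsum("ij,jk,ik->i", t0, TtT_inv, t0)
        return float(lev.min())
    ybar = y_cal.mean()
    return float(ybar ** 2 / np.sum((y_cal - ybar) ** 2))


def estimate_lod(
    m: PLSModel,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    sigma_x: float | None = None,
    sigma_ycal: float = 0.0,
) -> LODEstimate:
    """Limit of detection of a fitted PLS calibration, mg/L.

    Parameters
    ----------
    m : fitted calibration model.
    X_cal, y_cal : the calibration spectra (pre-treated, model scale) and
        concentrations used to fit ``m``.
    sigma_x : per-channel spectral noise SD; estimated from the model's
        reconstruction residuals when omitted.
    sigma_ycal : SD of the reference concentration errors (default 0:
        gravimetric spiking treated as exact).
    """
    if m.b is None:
        raise NotFittedError("model has no regression vector")
    if sigma_x is None:
        sigma_x = estimate_sigma_x(m, X_cal)
    if sigma_x < 0 or sigma_ycal < 0:
        raise ParameterError("noise standard deviations must be >= 0")
    h0 = _blank_leverage(m, y_cal)
    bnorm2 = float(m.b @ m.b)
    lod = 3.3 * np.sqrt(bnorm2 * sigma_x ** 2 * (1.0 + h0) + h0 * sigma_ycal ** 2)
    return LODEstimate(lod=float(lod), sigma_x=float(sigma_x),
                       sigma_ycal=float(sigma_ycal), h0=h0,
                       sen=1.0 / np.sqrt(bnorm2))
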