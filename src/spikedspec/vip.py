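"""Variable importance in projection (VIP) and greater-than-one band selection.

The VIP score of wavenumber j aggregates, over the F latent variables, the
squared normalized weight of that variable in each component, weighted by
the share of response variance the component explains:

    VIP_j = sqrt( p * sum_f SS_f (w_jf / ||w_f||)^2 / sum_f SS_f ),
    SS_f  = q_f^2 * t_f' t_f

(the y-variance captured by component f). The normalization makes the mean
squared score equal 1, so wavenumbers with VIP > 1 contribute more than an
average variable — the usual selection rule, applied here to flag the
spectral bands driving both the discrimination and the calibration models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionMismatchError, NotFittedError
from .pls import PLSModel

__all__ = ["VIPResult", "vip_scores", "vip_regions", "vip_analysis"]


@dataclass
class VIPResult:
    scores: np.ndarray
    wavenumbers: np.ndarray
    selected_regions: list[tuple[float, float]]


def vip_scores(m: PLSModel) -> np.ndarray:
    """Per-wavenumber VIP scores of a fitted PLS model."""
    if m.W is None or m.T is None:
        raise NotFittedError("model has no weights/scores")
    W = m.W
    p = W.shape[0]
    ss = m.q ** 2 * np.einsum("ij,ij->j", m.T, m.T)  # q_f^2 * t_f't_f
    wnorm2 = np.sum(W ** 2, axis=0)
    frac = (W ** 2 / wnorm2) @ ss
    return np.sqrt(p * frac / ss.sum())


def vip_regions(
    scores: np.ndarray,
    wavenumbers: np.ndarray,
    threshold: float = 1.0,
) -> list[tuple[float, float]]:
    """Maximal runs of consecutive grid points with VIP above the threshold.

    Returns ``(low, high)`` cm^-1 intervals (inclusive grid-point endpoints),
    sorted ascending by the lower edge, non-overlapping by construction.
    """
    scores = np.asarray(scores, float)
    wavenumbers = np.asarray(wavenumbers, float)
    if len(scores) != len(wavenumbers):
        raise DimensionMismatchError("scores and wavenumber axis differ in length")
    above = scores > threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1))
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above) - 1)
    regions = [
        (float(min(wavenumbers[s], wavenumbers[e])),
         float(max(wavenumbers[s], wavenumbers[e])))
        for s, e in zip(starts, ends)
    ]
    return sorted(regions)


def vip_analysis(m: PLSModel, threshold: float = 1.0) -> VIPResult:
    """Scores plus selected regions on the model's (post pre-treatment) axis."""
    if m.wavenumbers is None:
        raise NotFittedError("model carries no wavenumber axis")
    scores = vip_scores(m)
    return VIPResult(scores=scores, wavenumbers=m.wavenumbers,
                     selected_regions=vip_regions(scores, m.wavenumbers, threshold))
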