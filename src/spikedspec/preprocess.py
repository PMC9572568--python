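"""Spectral pre-treatments: mean centering, SNV, Savitzky-Golay derivatives.

The candidate set used throughout model selection is the four pipelines
``MC``, ``SNV+MC``, ``D1+MC`` and ``D2+MC``. Mean centering is the only
transform with fitted state (training column means); SNV is a stateless
rowwise standardization; D1/D2 are Savitzky-Golay smoothed derivatives with
respect to the wavenumber axis. Derivative edges are shrunk: the half-window
at each end of the axis is dropped rather than extrapolated, and the reduced
axis propagates through the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .errors import (
    DegenerateInputError,
    NotFittedError,
    ParameterError,
    ZeroVarianceError,
)

__all__ = [
    "mean_center_fit_apply",
    "apply_mean_center",
    "snv",
    "sg_derivative",
    "PreprocessingPipeline",
    "CANDIDATE_PIPELINES",
]

#: the pipeline labels considered during model selection, in tie-break order
CANDIDATE_PIPELINES = ("MC", "SNV+MC", "D1+MC", "D2+MC")

# Savitzky-Golay defaults (points / polynomial order) for D1 and D2
SG_DEFAULTS = {1: (15, 2), 2: (15, 3)}


def mean_center_fit_apply(X_train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-center a training matrix; return centered data and the means.

    The returned means are the fitted state reused on new data via
    :func:`apply_mean_center`.
    """
    X_train = np.asarray(X_train, float)
    if X_train.ndim != 2 or X_train.shape[0] < 2:
        raise DegenerateInputError("mean centering needs at least 2 samples")
    means = X_train.mean(axis=0)
    return X_train - means, means


def apply_mean_center(X: np.ndarray, means: np.ndarray) -> np.ndarray:
    X = np.asarray(X, float)
    if X.shape[1] != len(means):
        raise ParameterError(
            f"stored means have length {len(means)}, data has {X.shape[1]} columns"
        )
    return X - means


def snv(X: np.ndarray, sample_ids: np.ndarray | None = None) -> np.ndarray:
    """Standard normal variate: each row to mean 0, sample SD (n-1) 1.

    Removes multiplicative scatter and additive offset per spectrum; has no
    fitted state. A constant row has no scale to normalize and raises.
    """
    X = np.atleast_2d(np.asarray(X, float))
    means = X.mean(axis=1, keepdims=True)
    sds = X.std(axis=1, ddof=1, keepdims=True)
    zero = np.flatnonzero(sds.ravel() == 0)
    if zero.size:
        which = sample_ids[zero[0]] if sample_ids is not None else f"row {zero[0]}"
        raise ZeroVarianceError(f"constant spectrum ({which}) cannot be SNV-scaled")
    return (X - means) / sds


def sg_derivative(
    X: np.ndarray,
    wavenumbers: np.ndarray,
    order: int,
    window: int | None = None,
    polyorder: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Savitzky-Golay derivative of each spectrum w.r.t. wavenumber.

    The derivative is taken with respect to *increasing* wavenumber even
    though the axis is stored descending (the signed grid step handles the
    orientation). Edge points within half a window of either end are dropped,
    so the returned matrix comes with its shrunken axis.

    Returns
    -------
    (X_deriv, wavenumbers_out):
        derivative matrix in absorbance per (cm^-1)^order, and the trimmed axis.
    """
    if order not in (1, 2):
        raise ParameterError(f"derivative order must be 1 or 2, got {order}")
    if window is None or polyorder is None:
        w_def, p_def = SG_DEFAULTS[order]
        window = w_def if window is None else window
        polyorder = p_def if polyorder is None else polyorder
    if window % 2 == 0:
        raise ParameterError(f"window must be odd, got {window}")
    if not (window > polyorder >= order):
        raise ParameterError(
            f"need window > polyorder >= order, got window={window}, "
            f"polyorder={polyorder}, order={order}"
        )
    X = np.atleast_2d(np.asarray(X, float))
    wavenumbers = np.asarray(wavenumbers, float)
    if X.shape[1] != len(wavenumbers):
        raise ParameterError("matrix columns and wavenumber axis differ in length")
    if X.shape[1] < window:
        raise ParameterError(f"need at least {window} wavenumbers, got {X.shape[1]}")
    steps = np.diff(wavenumbers)
    if not np.allclose(steps, steps[0]):
        raise ParameterError("Savitzky-Golay derivative requires a uniform grid")

    delta = abs(steps[0])
    d = savgol_filter(X, window_length=window, polyorder=polyorder,
                      deriv=order, delta=delta, axis=1)
    # stored axis runs descending: d/d(index) = -d/d(wavenumber) per derivative order
    if steps[0] < 0:
        d = d * (-1.0) ** order
    half = (window - 1) // 2
    return d[:, half:-half], wavenumbers[half:-half]


# ---------------------------------------------------------------------------
# composable pipeline
# ---------------------------------------------------------------------------

@dataclass
class _Step:
    kind: str  # "snv" | "sg" | "mc"
    order: int = 0
    window: int | None = None
    polyorder: int | None = None


@dataclass
class PreprocessingPipeline:
    """Ordered fit-then-apply chain of spectral transforms.

    Built from one of the candidate labels (``"MC"``, ``"SNV+MC"``,
    ``"D1+MC"``, ``"D2+MC"``). Mean centering, if present, must be the last
    step and appears at most once; its column means are the only fitted
    state. ``fit`` learns those means (after the stateless steps) from the
    training spectra; ``transform`` replays the chain on new data.
    """

    label: str
    sg_window: int | None = None
    sg_polyorder: int | None = None
    steps: list[_Step] = field(init=False)
    means_: np.ndarray | None = field(default=None, init=False)
    wavenumbers_out_: np.ndarray | None = field(default=None, init=False)

    def __post_init__(self) -> None:
        self.steps = self._parse(self.label)

    def _parse(self, label: str) -> list[_Step]:
        steps: list[_Step] = []
        parts = [p.strip().upper() for p in label.split("+") if p.strip()]
        if not parts:
            raise ParameterError(f"empty pipeline label {label!r}")
        for i, part in enumerate(parts):
            if part == "MC":
                if i != len(parts) - 1:
                    raise ParameterError("mean centering must be the last step")
                steps.append(_Step("mc"))
            elif part == "SNV":
                steps.append(_Step("snv"))
            elif part in ("D1", "D2"):
                steps.append(_Step("sg", order=int(part[1]),
                                   window=self.sg_window, polyorder=self.sg_polyorder))
            else:
                raise ParameterError(f"unknown pre-treatment {part!r} in {label!r}")
        if sum(s.kind == "mc" for s in steps) > 1:
            raise ParameterError("mean centering may appear at most once")
        return steps

    def _stateless(self, X: np.ndarray, wavenumbers: np.ndarray,
                   sample_ids: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
        for step in self.steps:
            if step.kind == "snv":
                X = snv(X, sample_ids)
            elif step.kind == "sg":
                X, wavenumbers = sg_derivative(X, wavenumbers, step.order,
                                               step.window, step.polyorder)
        return X, wavenumbers

    def fit(self, X: np.ndarray, wavenumbers: np.ndarray,
            sample_ids: np.ndarray | None = None) -> "PreprocessingPipeline":
        X = np.asarray(X, float)
        Xp, wn = self._stateless(X, np.asarray(wavenumbers, float), sample_ids)
        if any(s.kind == "mc" for s in self.steps):
            _, self.means_ = mean_center_fit_apply(Xp)
        else:
            self.means_ = np.zeros(Xp.shape[1])
        self.wavenumbers_out_ = wn
        return self

    def transform(self, X: np.ndarray, wavenumbers: np.ndarray,
                  sample_ids: np.ndarray | None = None) -> np.ndarray:
        if self.means_ is None:
            raise NotFittedError("pipeline must be fitted before transform")
        Xp, wn = self._stateless(np.asarray(X, float),
                                 np.asarray(wavenumbers, float), sample_ids)
        if len(wn) != len(self.wavenumbers_out_) or not np.array_equal(
                wn, self.wavenumbers_out_):
            raise ParameterError("new data is not on the pipeline's training grid")
        return Xp - self.means_

    def fit_transform(self, X: np.ndarray, wavenumbers: np.ndarray,
                      sample_ids: np.ndarray | None = None) -> np.ndarray:
        return self.fit(X, wavenumbers, sample_ids).transform(X, wavenumbers, sample_ids)

    @property
    def wavenumbers_out(self) -> np.ndarray:
        if self.wavenumbers_out_ is None:
            raise NotFittedError("pipeline must be fitted first")
        return self.wavenumbers_out_
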