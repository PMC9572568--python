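"""The spectra data model.

A :class:`SpectraSet` bundles an absorbance matrix (samples x wavenumbers),
its wavenumber axis in cm^-1 (stored strictly descending, instrument
convention 10,000 -> 4,000) and per-sample metadata: gin brand, tonic brand,
alprazolam concentration in mg/L and the class label (``pure``/``spiked``).
It is the exchange object every other module consumes and produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import SpectraValidationError

#: canonical acquisition grid: 10,000 to 4,000 cm^-1 inclusive at 4 cm^-1 step
GRID_MAX_CM1 = 10_000.0
GRID_MIN_CM1 = 4_000.0
GRID_STEP_CM1 = 4.0

CLASS_PURE = "pure"
CLASS_SPIKED = "spiked"

#: metadata columns of the wide-CSV on-disk format, in order
METADATA_COLUMNS = ("sample_id", "gin_brand", "tonic_brand", "alprazolam_mg_per_L", "class")


def default_grid() -> np.ndarray:
    """The descending 1501-point acquisition grid (10,000..4,000 cm^-1, 4 cm^-1)."""
    return np.arange(GRID_MAX_CM1, GRID_MIN_CM1 - GRID_STEP_CM1 / 2, -GRID_STEP_CM1)


@dataclass
class SpectraSet:
    """Absorbance spectra plus aligned per-sample metadata.

    Parameters
    ----------
    absorbance:
        ``(n_samples, n_wavenumbers)`` matrix of unitless absorbance.
    wavenumbers:
        Strictly monotone descending axis in cm^-1; one entry per column.
    sample_ids, gin_brand, tonic_brand, concentration, class_label:
        Per-sample metadata vectors of length ``n_samples``. ``class_label``
        must be ``pure`` exactly when ``concentration`` is 0.
    """

    absorbance: np.ndarray
    wavenumbers: np.ndarray
    sample_ids: np.ndarray
    gin_brand: np.ndarray
    tonic_brand: np.ndarray
    concentration: np.ndarray
    class_label: np.ndarray

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        for name in ("sample_ids", "gin_brand", "tonic_brand", "class_label"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=object))
        self.concentration = np.asarray(self.concentration, dtype=float)
        self._validate()

    # -- invariants ---------------------------------------------------------

    def _validate(self) -> None:
        if self.absorbance.ndim != 2:
            raise SpectraValidationError("absorbance must be a 2-D matrix")
        n, p = self.absorbance.shape
        if self.wavenumbers.ndim != 1 or len(self.wavenumbers) != p:
            raise SpectraValidationError(
                f"wavenumber axis length {len(self.wavenumbers)} does not match "
                f"{p} absorbance columns"
            )
        if p > 1 and not np.all(np.diff(self.wavenumbers) < 0):
            raise SpectraValidationError(
                "wavenumbers must be strictly monotone descending with no duplicates"
            )
        for name in ("sample_ids", "gin_brand", "tonic_brand", "concentration", "class_label"):
            v = getattr(self, name)
            if len(v) != n:
                raise SpectraValidationError(f"metadata vector {name!r} has length "
                                             f"{len(v)}, expected {n}")
        if len(set(self.sample_ids)) != n:
            raise SpectraValidationError("sample_ids must be unique")
        bad = set(self.class_label) - {CLASS_PURE, CLASS_SPIKED}
        if bad:
            raise SpectraValidationError(f"unknown class labels: {sorted(bad)}")
        if np.any(self.concentration < 0):
            raise SpectraValidationError("concentrations must be >= 0 mg/L")
        inconsistent = (self.class_label == CLASS_PURE) != (self.concentration == 0.0)
        if np.any(inconsistent):
            ids = list(self.sample_ids[inconsistent])
            raise SpectraValidationError(
                "class/concentration contradiction (pure <=> 0 mg/L) for samples: "
                f"{ids}"
            )

    # -- basic accessors ----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavenumbers(self) -> int:
        return self.absorbance.shape[1]

    @property
    def combination(self) -> np.ndarray:
        """Per-sample (gin, tonic) pair as e.g. ``'G1T2'`` strings."""
        return np.array([g + t for g, t in zip(self.gin_brand, self.tonic_brand)],
                        dtype=object)

    def metadata_frame(self) -> pd.DataFrame:
        """Metadata as a DataFrame with the canonical wide-CSV column names."""
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "gin_brand": self.gin_brand,
                "tonic_brand": self.tonic_brand,
                "alprazolam_mg_per_L": self.concentration,
                "class": self.class_label,
            }
        )

    # -- subsetting ---------------------------------------------------------

    def take(self, index: np.ndarray) -> "SpectraSet":
        """Row-subset by integer index or boolean mask, preserving order."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return SpectraSet(
            absorbance=self.absorbance[index],
            wavenumbers=self.wavenumbers,
            sample_ids=self.sample_ids[index],
            gin_brand=self.gin_brand[index],
            tonic_brand=self.tonic_brand[index],
            concentration=self.concentration[index],
            class_label=self.class_label[index],
        )

    def subset_by_combination(
        self, combos: Iterable[tuple[str, str]]
    ) -> "SpectraSet":
        """Samples whose (gin, tonic) brand pair is in ``combos``, order preserved.

        Raises
        ------
        KeyError
            If a combination names a brand code absent from this dataset.
        """
        combos = list(combos)
        if not combos:
            raise SpectraValidationError("combos must be nonempty")
        gins = set(self.gin_brand)
        tonics = set(self.tonic_brand)
        for g, t in combos:
            if g not in gins:
                raise KeyError(f"unknown gin brand code {g!r}")
            if t not in tonics:
                raise KeyError(f"unknown tonic brand code {t!r}")
        wanted = {g + t for g, t in combos}
        mask = np.array([c in wanted for c in self.combination])
        return self.take(mask)

    # -- comparison (test convenience) --------------------------------------

    def equals(self, other: "SpectraSet", atol: float = 0.0) -> bool:
        """Exact metadata equality and absorbance equality within ``atol``."""
        return (
            np.allclose(self.absorbance, other.absorbance, rtol=0.0, atol=atol)
            and np.array_equal(self.wavenumbers, other.wavenumbers)
            and np.array_equal(self.sample_ids, other.sample_ids)
            and np.array_equal(self.gin_brand, other.gin_brand)
            and np.array_equal(self.tonic_brand, other.tonic_brand)
            and np.allclose(self.concentration, other.concentration, rtol=0.0, atol=atol)
            and np.array_equal(self.class_label, other.class_label)
        )
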