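"""Synthetic FT-NIR gin-and-tonic spectra.

Emulates the study design the analysis assumes: a 3x3 grid of gin and tonic
brands, 20 pure + 37 spiked drinks per combination, alprazolam spiking
levels spanning 1.6-34.6 mg/L, an analyte absorption band inside
6380-6520 cm^-1 and water/ethanol matrix bands near 5300-5400 and
7040-7175 cm^-1.

The generative model is Beer-Lambert additive: each spectrum is a shared
matrix base, perturbed multiplicatively and additively by smooth per-brand
effects (brands act as systematic blocks, drawn once per brand and reused),
plus concentration times a unit-concentration analyte signature, plus iid
Gaussian noise. Bands are Gaussians; brand effects are random cubic splines,
so they are spectrally smooth the way real brand-to-brand matrix differences
are.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import DimensionMismatchError, ParameterError
from .spectra import CLASS_PURE, CLASS_SPIKED, SpectraSet, default_grid

__all__ = [
    "BandModel",
    "BrandEffect",
    "DesignSpec",
    "ANALYTE_BAND_WINDOW_CM1",
    "DEFAULT_ANALYTE_BANDS",
    "DEFAULT_MATRIX_BANDS",
    "analyte_signature",
    "matrix_base_spectrum",
    "sample_brand_effect",
    "simulate_spectrum",
    "generate_dataset",
]

#: wavenumber window characteristic of the analyte (alprazolam)
ANALYTE_BAND_WINDOW_CM1 = (6380.0, 6520.0)


@dataclass(frozen=True)
class BandModel:
    """One Gaussian absorption band.

    ``amplitude`` is in absorbance units per unit of driver: per mg/L for
    analyte bands, absolute absorbance for matrix bands.
    """

    center: float  # cm^-1
    width: float  # Gaussian sigma, cm^-1
    amplitude: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ParameterError(f"band width must be > 0, got {self.width}")
        if not (4_000.0 <= self.center <= 10_000.0):
            raise ParameterError(
                f"band center {self.center} cm^-1 outside [4000, 10000]"
            )

    def evaluate(self, wavenumbers: np.ndarray) -> np.ndarray:
        z = (np.asarray(wavenumbers, float) - self.center) / self.width
        return self.amplitude * np.exp(-0.5 * z * z)


#: default analyte signature: single band centred in the 6380-6520 cm^-1 window
DEFAULT_ANALYTE_BANDS: tuple[BandModel, ...] = (BandModel(6450.0, 35.0, 1.0e-3),)

#: default drink-matrix bands: dominant O-H combination band near 5350 cm^-1,
#: first O-H stretch overtone near 7100 cm^-1, plus broad flanking structure
DEFAULT_MATRIX_BANDS: tuple[BandModel, ...] = (
    BandModel(5350.0, 60.0, 0.85),
    BandModel(7100.0, 90.0, 0.45),
    BandModel(4700.0, 160.0, 0.55),
    BandModel(8600.0, 240.0, 0.12),
)


def analyte_signature(
    bands: "list[BandModel] | tuple[BandModel, ...]" = DEFAULT_ANALYTE_BANDS,
    wavenumbers: np.ndarray | None = None,
) -> np.ndarray:
    """Unit-concentration analyte spectrum: the sum of Gaussian bands.

    Returns the absorbance contributed by 1 mg/L of analyte at every grid
    point, so a spiked spectrum adds ``concentration * signature``.
    """
    if len(bands) == 0:
        raise ParameterError("analyte band list must be nonempty")
    if wavenumbers is None:
        wavenumbers = default_grid()
    out = np.zeros(len(wavenumbers))
    for band in bands:
        out += band.evaluate(wavenumbers)
    return out


def matrix_base_spectrum(
    wavenumbers: np.ndarray | None = None,
    bands: "tuple[BandModel, ...]" = DEFAULT_MATRIX_BANDS,
) -> np.ndarray:
    """Brand-neutral drink spectrum: matrix bands over a gently sloping baseline."""
    if wavenumbers is None:
        wavenumbers = default_grid()
    wavenumbers = np.asarray(wavenumbers, float)
    baseline = 0.15 + 0.05 * (wavenumbers - 4_000.0) / 6_000.0
    out = baseline.copy()
    for band in bands:
        out += band.evaluate(wavenumbers)
    return out


# ---------------------------------------------------------------------------
# brand effects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BrandEffect:
    """Smooth per-brand spectral perturbation: multiplicative gain and offset."""

    gain: np.ndarray  # dimensionless, ~1
    offset: np.ndarray  # absorbance

    @staticmethod
    def neutral(n_points: int) -> "BrandEffect":
        return BrandEffect(gain=np.ones(n_points), offset=np.zeros(n_points))

    def combine(self, other: "BrandEffect") -> "BrandEffect":
        """Composition of two independent effects (gin x tonic)."""
        return BrandEffect(gain=self.gain * other.gain, offset=self.offset + other.offset)

    def apply(self, spectrum: np.ndarray) -> np.ndarray:
        return spectrum * self.gain + self.offset


# relative gain and absolute offset scales at brand_effect_scale = 1; knot
# spacing sets the spectral scale of brand-to-brand differences (~110 cm^-1,
# comparable to real band widths, so derivatives attenuate but do not erase
# them)
_GAIN_SD = 4.5e-3
_OFFSET_SD_AU = 6.0e-3
_N_KNOTS = 55


def _smooth_random_curve(rng: np.random.Generator, wavenumbers: np.ndarray) -> np.ndarray:
    knots_x = np.linspace(wavenumbers.min(), wavenumbers.max(), _N_KNOTS)
    knots_y = rng.standard_normal(_N_KNOTS)
    return CubicSpline(knots_x, knots_y)(wavenumbers)


def sample_brand_effect(
    rng: np.random.Generator, wavenumbers: np.ndarray, scale: float
) -> BrandEffect:
    """Draw one brand's systematic perturbation from the seeded generator."""
    gain = 1.0 + scale * _GAIN_SD * _smooth_random_curve(rng, wavenumbers)
    offset = scale * _OFFSET_SD_AU * _smooth_random_curve(rng, wavenumbers)
    return BrandEffect(gain=gain, offset=offset)


# ---------------------------------------------------------------------------
# single-spectrum simulator
# ---------------------------------------------------------------------------

def simulate_spectrum(
    matrix_base: np.ndarray,
    brand_effects: BrandEffect,
    conc: float,
    signature: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One spectrum: ``base o brand_effects + conc * signature + noise``."""
    matrix_base = np.asarray(matrix_base, float)
    signature = np.asarray(signature, float)
    p = len(matrix_base)
    if len(signature) != p or len(brand_effects.gain) != p or len(brand_effects.offset) != p:
        raise DimensionMismatchError(
            "matrix base, signature and brand effects must share one grid"
        )
    if conc < 0:
        raise ParameterError(f"concentration must be >= 0, got {conc}")
    out = brand_effects.apply(matrix_base) + conc * signature
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, size=p)
    return out


# ---------------------------------------------------------------------------
# full-design generator
# ---------------------------------------------------------------------------

@dataclass
class DesignSpec:
    """The sample-preparation design driving :func:`generate_dataset`.

    Defaults replicate the study conditions: 3 gin x 3 tonic brands, 20 pure
    and 37 spiked drinks per combination, spiking levels evenly spaced over
    1.6-34.6 mg/L. ``noise_sd`` is the iid spectral noise SD in absorbance
    units; ``brand_effect_scale`` multiplies the per-brand systematic
    perturbations (0 disables them).
    """

    gin_brands: tuple[str, ...] = ("G1", "G2", "G3")
    tonic_brands: tuple[str, ...] = ("T1", "T2", "T3")
    n_pure_per_combo: int = 20
    n_spiked_per_combo: int = 37
    conc_min: float = 1.6
    conc_max: float = 34.6
    noise_sd: float = 5.0e-4
    brand_effect_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.conc_min <= 0:
            raise ParameterError("conc_min must be > 0 (0 mg/L means pure)")
        if self.conc_max < self.conc_min:
            raise ParameterError("conc_max must be >= conc_min")
        if self.n_pure_per_combo < 0 or self.n_spiked_per_combo < 0:
            raise ParameterError("per-combination counts must be >= 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")

    def spiked_levels(self) -> np.ndarray:
        """The evenly spaced spiking concentrations, mg/L."""
        if self.n_spiked_per_combo == 0:
            return np.empty(0)
        if self.n_spiked_per_combo == 1:
            return np.array([self.conc_min])
        return np.linspace(self.conc_min, self.conc_max, self.n_spiked_per_combo)


def generate_dataset(
    spec: DesignSpec,
    analyte_bands: "tuple[BandModel, ...]" = DEFAULT_ANALYTE_BANDS,
    matrix_bands: "tuple[BandModel, ...]" = DEFAULT_MATRIX_BANDS,
    wavenumbers: np.ndarray | None = None,
) -> SpectraSet:
    """Generate the full design as a :class:`SpectraSet`.

    Brand effects are drawn once per gin brand and once per tonic brand from
    the seeded generator and reused for every sample of that brand, so brands
    are systematic blocks rather than per-sample noise. Deterministic under a
    fixed ``spec.seed`` (bitwise).
    """
    if wavenumbers is None:
        wavenumbers = default_grid()
    wavenumbers = np.asarray(wavenumbers, float)
    base = matrix_base_spectrum(wavenumbers, matrix_bands)
    signature = analyte_signature(analyte_bands, wavenumbers)

    ss = np.random.SeedSequence(spec.seed)
    brand_rng, noise_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    if spec.brand_effect_scale == 0:
        neutral = BrandEffect.neutral(len(wavenumbers))
        gin_eff = {g: neutral for g in spec.gin_brands}
        tonic_eff = {t: neutral for t in spec.tonic_brands}
    else:
        gin_eff = {
            g: sample_brand_effect(brand_rng, wavenumbers, spec.brand_effect_scale)
            for g in spec.gin_brands
        }
        tonic_eff = {
            t: sample_brand_effect(brand_rng, wavenumbers, spec.brand_effect_scale)
            for t in spec.tonic_brands
        }

    levels = spec.spiked_levels()
    rows, ids, gins, tonics, concs, labels = [], [], [], [], [], []
    for g in spec.gin_brands:
        for t in spec.tonic_brands:
            eff = gin_eff[g].combine(tonic_eff[t])
            for k in range(spec.n_pure_per_combo):
                rows.append(simulate_spectrum(base, eff, 0.0, signature,
                                              spec.noise_sd, noise_rng))
                ids.append(f"{g}{t}_pure_{k:02d}")
                gins.append(g)
                tonics.append(t)
                concs.append(0.0)
                labels.append(CLASS_PURE)
            for k, c in enumerate(levels):
                rows.append(simulate_spectrum(base, eff, float(c), signature,
                                              spec.noise_sd, noise_rng))
                ids.append(f"{g}{t}_spk_{k:02d}")
                gins.append(g)
                tonics.append(t)
                concs.append(float(c))
                labels.append(CLASS_SPIKED)

    return SpectraSet(
        absorbance=np.vstack(rows) if rows else np.empty((0, len(wavenumbers))),
        wavenumbers=wavenumbers,
        sample_ids=np.array(ids, dtype=object),
        gin_brand=np.array(gins, dtype=object),
        tonic_brand=np.array(tonics, dtype=object),
        concentration=np.array(concs, dtype=float),
        class_label=np.array(labels, dtype=object),
    )
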