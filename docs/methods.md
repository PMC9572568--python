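# Methods

## Data model and acquisition grid

Spectra live on a fixed descending wavenumber axis, 10,000 → 4,000 cm⁻¹ at
4 cm⁻¹ steps (1501 points), matching the nominal resolution of the FT-NIR
instrument class this workflow targets; the true export spacing of such
instruments varies, so the grid is a convention, not a physical claim. All
column indices in the package refer to this descending order. The wide-CSV
format is canonical and lossless (metadata columns, then one column per
wavenumber); JCAMP-DX reading is a convenience for single-spectrum
instrument exports and fills in neutral metadata.

A `SpectraSet` enforces three invariants at construction: a strictly
descending duplicate-free axis, unique sample identifiers, and the
class/concentration consistency rule (label `pure` ⇔ 0 mg/L).

## Synthetic data generator

The generator emulates the study design so the full pipeline can be run
and tested with no external data: 3 gin brands × 3 tonic brands, 20 pure +
37 spiked samples per combination (513 spectra), spiking levels evenly
spaced over 1.6–34.6 mg/L. Evenly spaced levels are an assumption — only
the range and count of the original preparation scheme are known.

Each spectrum is built additively (Beer–Lambert):

    x = base ∘ gain(brand) + offset(brand) + c · s + ε,
    ε ~ N(0, noise_sd² I)

- **Matrix base**: Gaussian bands for the dominant water/ethanol features
  (O–H combination near 5350 cm⁻¹, first O–H stretch overtone near
  7100 cm⁻¹, broad flanking structure) over a gently sloping baseline.
- **Analyte signature `s`**: a Gaussian band centered at 6450 cm⁻¹
  (σ = 35 cm⁻¹), amplitude 10⁻³ AU per mg/L, inside the 6380–6520 cm⁻¹
  window characteristic of alprazolam.
- **Brand effects**: one multiplicative gain curve (1 + spline) and one
  additive offset curve per gin brand and per tonic brand, drawn once per
  brand from the seeded generator and reused for all of that brand's
  samples — brands are systematic blocks, not per-sample noise. The curves
  are cubic splines through ~55 random knots (≈110 cm⁻¹ spacing, the scale
  of real band-to-band brand differences), gain SD 4.5 × 10⁻³ (relative)
  and offset SD 6 × 10⁻³ AU at `brand_effect_scale = 1`.
- **Noise**: iid Gaussian, default SD 5 × 10⁻⁴ AU per channel.

The brand-effect and noise scales were calibrated, once, so that the full
study reproduces the qualitative regime of real brand-held-out NIR
calibrations: held-out-brand RMSEP for the more favourable schemes at or
below the few-mg/L level with clearly degraded schemes above it,
detection limits between a few tenths and a few mg/L, and VIP analysis
always recovering the planted analyte band. They are defaults of the
`DesignSpec`, not tuned per run.

**What the generator does not emulate:** real ethanol/water NIR physics
(temperature- and concentration-dependent band shifts), pathlength and
scatter variability between vials, drift, replicate scans, and — most
importantly — any concentration-nonlinear signature of the spiking
formulation. The response is exactly linear in concentration by
construction. Consequences for what passing tests show are discussed under
*Known limitations*.

## Pre-treatments

The candidate set is fixed to the four pipelines used in the model
selection grid: `MC`, `SNV+MC`, `D1+MC`, `D2+MC`. Mean centering is always
last and is the only fitted state (training column means). SNV standardizes
each spectrum to mean 0 / SD 1 (n−1 denominator) and fails loudly on a
constant spectrum. Savitzky–Golay derivatives use window 15, polynomial
order 2 (D1) or 3 (D2) — common NIR practice; the original instrument
settings are unknown, and all derivative checks are property-based
(exactness on polynomials) rather than value replication. Derivatives are
taken with respect to *increasing* wavenumber (the signed grid step
corrects for the descending storage order), and edges are shrunk: half a
window (7 points) is dropped at each end instead of extrapolating the
polynomial fit, and the reduced axis propagates to every downstream
consumer (models store their own axis).

## PLS core

Single-response NIPALS with deflation of X only: for each component the
weight is the exact covariance direction w ∝ Xᵀy, so the algorithm is
deterministic with no iteration or random initialisation. X and y are
mean-centered internally; R = W(PᵀW)⁻¹ gives T = XR on training data and
b = Rq the regression vector. Because PᵀW is upper triangular, the leading
columns of R coincide with the truncated model's R, which lets one fit at
F_max serve an entire complexity grid (`predict_all_components`).

Numerical choices: covariance exhaustion is detected relative to the first
component's covariance norm (relative tolerance 10⁻¹⁰), so the criterion is
scale-free; during grid scans exhaustion truncates the grid instead of
failing (`strict_rank=False`), while direct fits raise.

## PLS-DA

Dummy coding spiked → 1 / pure → 0. The decision threshold is 1-D LDA on
the training predictions: with pooled within-class variance and equal
priors this is the midpoint of the two class means. Equal priors are the
default (the common chemometric choice when the sampling design, not the
population, fixes the class ratio); class-proportional priors are available
via `priors="proportional"`, which shifts the threshold by
s²·ln(n₀/n₁)/(m₁−m₀). A prediction exactly on the threshold is called
`pure`: the tie rule favours the "not spiked" null claim, the conservative
direction for a screening method. Reported rates are rounded half away
from zero to 2 decimals.

## Model selection

Each of the six schemes holds out one brand's three combinations as the
test set (3 gin-wise schemes ordered G3, G2, G1, then 3 tonic-wise ordered
T3, T2, T1, matching the report-table row order). Split-half CV uses the two
remaining brands of the held-out type as cancelation groups: fit on one
brand's block (pipeline statistics fitted on that block alone — the leak
test injects a fold-B-only artifact and verifies fold-A outputs are
bit-identical), evaluate on the other, pool both directions. The DA
criterion is the pooled plain misclassification rate with the LDA
threshold re-derived inside each fold; the regression criterion is pooled
RMSECV. F_max defaults to 25 and is clipped (with a warning) to the fold
rank. Ties in the grid break to fewer latent variables, then to candidate
order (MC, SNV+MC, D1+MC, D2+MC) — the simpler model wins.

## VIP

Wold's formulation from the NIPALS weights:
VIP_j = √(p · Σ_f SS_f (w_jf/‖w_f‖)² / Σ_f SS_f) with SS_f = q_f²·t_fᵀt_f,
so mean(VIP²) = 1 exactly. Regions are maximal runs of consecutive grid
points with VIP > 1, reported as inclusive [low, high] cm⁻¹ intervals on
the model's own (possibly edge-shrunk) axis.

## Limit of detection

LOD = 3.3·√(‖b‖²σₓ²(1+h₀) + h₀σ²_ycal), the single-number "minimum LOD"
variant of the Allegrini–Olivieri error-propagation approach, with
sensitivity SEN = 1/‖b‖. h₀ is the minimum leverage t₀ᵀ(TᵀT)⁻¹t₀ among
calibration blanks (y = 0) in score space; if the calibration contains no
blanks the pseudounivariate expression ȳ²/Σ(y−ȳ)² is used. σₓ defaults to
the pooled RMS of the F-component reconstruction residuals X_c − TPᵀ with
n−F−1 degrees of freedom per channel (no replicate scans exist in the
synthetic design); σ_ycal defaults to 0 (spiking treated as gravimetrically
exact). The estimate is scale-equivariant: rescaling spectra and σₓ
together leaves the LOD unchanged.

Note that σₓ estimated from residuals absorbs whatever systematic structure
the F components did not capture, so in schemes where the chosen model is
very small the LOD drifts above the pure-noise value — a real property of
residual-based noise estimates, not an artifact.

## Full study and reproducibility

`run_full_study` chains generate → split → select → fit → evaluate → VIP →
LOD and emits a report whose every table row is recomputable from the
stored per-sample predictions (tested). One global seed drives a
`SeedSequence` fan-out (brand effects, noise), so runs are bitwise
reproducible. The default study size is the full 513-sample design; a
complete run takes a few seconds on one core, and the test suite uses a
reduced design (4 pure + 6 spiked per combination) wherever the full size
adds nothing.

## Known limitations

- **Linear class signature.** Because spectra are exactly linear in
  concentration and the equal-priors threshold is the midpoint of the class
  means, a spiked sample is detected iff its concentration exceeds about
  half the spiked-class mean (≈9 mg/L under the default design). Spiked
  sensitivity on synthetic data is therefore structurally capped near 77%
  (accuracy ≈85%), regardless of noise level. Real spiked drinks can carry
  concentration-nonlinear signatures (formulation excipients, matrix
  interactions) that allow higher detection rates; passing synthetic tests
  therefore validate the pipeline's mechanics and its brand-robustness
  behaviour, not the detection rates attainable on real spectra.
- Brand effects are smooth random curves; real brand differences include
  discrete compositional bands (sweeteners, botanicals) that can be either
  easier or harder to orthogonalize away.
- The LOD's σₓ estimator conflates instrumental noise with model
  lack-of-fit when F is small (see above).
- JCAMP-DX support covers fixed-format `(X++(Y..Y))` tables only.
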