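# Methods

## The measurement model

The analysis treats plant growth as the product of two factors: the photon
dose incident on the canopy (set by canopy size and the local light field)
and the efficiency with which that dose becomes biomass. Projected canopy
size (PCS, cm²) — the top-view area of the rosette — is the
light-collecting surface. No absorptance or angular correction is applied:
the budget is *incident*, not absorbed, light, which is exactly what the
imaging measurement supports.

### Segmentation

A chlorophyll-fluorescence frame contains only the canopy (bright), a dim
noisy background and a reserved scale-marker strip. A pixel is canopy when
its intensity strictly exceeds a fixed per-experiment threshold and lies
outside the marker strip; each canopy pixel contributes its full
(cm/px)² — no sub-pixel weighting, no morphological cleanup by default. A
fixed threshold keeps the measurement reproducible; Otsu's method is
available (`threshold=None`) for convenience, and `min_object_px` removes
speckle where needed. Near the canopy edge the measurement is inherently
threshold-sensitive; with the default synthetic intensity separation
(foreground ≈ 40000 ± 3000, background ≈ 1500 ± 400 on a 16-bit scale,
threshold 10000) the sensitivity is nil.

The scale is either a known cm-per-pixel or is calibrated from the marker:
a high-intensity bar of known physical length whose pixel extent is the
longest above-threshold run in the strip. Calibration error is at most one
pixel of bar length.

### Growth curves

Rosette expansion over a 25-day cycle is near-exponential with a slowly
declining relative growth rate, captured by a quadratic in time on the
natural-log scale, fitted per plant by OLS to the imaged days. The log base
is internal — any base yields identical back-transformed predictions.
Predictions run over integer days from germination (day 0) to harvest;
since imaging starts after germination, the curve is extrapolated backwards
to day 0 and floored at 0.01 cm², which bounds extrapolation pathology
while staying far below any real seedling size. A log-scale R² below 0.99
raises a warning rather than an error (healthy series fit far better than
that; the warning flags data problems). A zero-variance response is given
R² = 1 when residuals vanish, else 0.

### Light budget

Daily incident dose: `mol = PCS·10⁻⁴ · flux·10⁻⁶ · hours_on·3600`, with
`hours_on = 18` by default (an 18 h on / 6 h off schedule). Each day's
predicted PCS is treated as constant over that day's photoperiod (no
sub-day integration). The cumulative sum runs from day 0 through the day
*before* harvest — plants are removed at the start of the harvest day; the
`include_harvest_day` flag flips this convention. LUE_PPFD and LUE_TOTAL
divide shoot dry weight by the 400–700 nm and 400–800 nm cumulative doses
respectively, so `LUE_TOTAL < LUE_PPFD` whenever any far-red is present.

### Efficacy statistics

"How much more effective is a far-red photon than a PPFD photon?" is
answered by the ratio of fitted linear slopes. Each response is modeled by
OLS with Gaussian errors, starting from
{intercept, FR, PPFD, FR×PPFD} and applying backwards elimination: while
any removable term has p > α (default 0.05), remove the one with the
largest p and refit; the interaction must leave before either main effect,
and the intercept always stays. Exact p ties are broken by removing the
interaction first, then alphabetically. Two numerical details:

- **Centered interaction.** The interaction column is the product of the
  mean-centered predictors. With a raw product, whenever a truly null
  interaction survives by chance the main-effect coefficients become slopes
  at FR = 0 or PPFD = 0 — far outside the design — which ruins confidence
  interval coverage of the marginal slopes. Centering keeps the mains
  interpretable at the gradient center, and any interaction-free final
  model is identical to the plain uncentered two-slope fit.
- **Exact-fit handling.** On numerically exact data the residual variance
  underflows and t-statistics are meaningless; a term is then retained only
  if removing it actually breaks the (numerically) perfect fit. This makes
  elimination on noise-free data return exactly the generating sub-model.

The efficacy percentage, `100·(slope_FR/slope_PPFD − 1)`, is defined only
when both main slopes are retained and is rounded only at reporting time.
No multiple-testing correction is applied. P-values are two-sided and
t-based.

## The synthetic experiment generator

The generator emulates two 60-plant studies in a 0.8 m × 1.8 m chamber,
laid out as a 6 × 10 grid with linear-in-grid-coordinate gradients (the
emulated studies report only range endpoints):

- **Far-red gradient study**: PPFD = 207 µmol m⁻² s⁻¹ plus Gaussian
  position noise (sd 13), far-red 4.9–28.0 along the long axis.
- **Perpendicular-gradient study**: PPFD 111–245 across the columns,
  far-red 4.7–32.8 across the rows; sample correlation between the two is
  exactly zero by construction.

Each plant grows as `ln PCS_i(t) = a + b_i t + c t²` with
`b_i = b₀ + β_FR·FR_i + β_PPFD·PPFD_i + η_i`. Defaults
(a, b₀, c) = (−1.05, 0.425, −0.0081), β_FR = 7·10⁻⁴, β_PPFD = 2·10⁻⁴ were
solved once so that a gradient-center plant has a ≈ 0.35 cm² seedling,
≈ 85 cm² at day 16 and ≈ 300 cm² at day 25 (plants near pot-footprint
coverage at each harvest), and so the linearized cumulative-light response
slopes have the published order of magnitude (≈ 0.005–0.008 mol per
µmol m⁻² s⁻¹ at the early harvest). The vigor deviation η (sd 0.003)
gives a realistic ±7.5% canopy spread at day 25.

Harvests at 16 and 25 days after germination split the cohort in half,
stratified by (FR, PPFD) rank so both harvests span the full gradient;
imaging days default to {2, 5, 9, 12, 16, 19, 23, 25} (eight sessions,
with early-harvest plants contributing the first five). Morphology (length
and width of the longest leaf, cm) is linear in FR and PPFD with the
published coefficient sets as generating defaults; leaf area is
`overlap_true × PCS(harvest)` (1.05 early, 1.40 late); and dry weight is
`true_lue_total × cumulative 400–800 nm dose + noise` with
`true_lue_total = 0.60 g/mol`, inside the observed 0.26–0.91 g/mol span.
The dry-weight identity uses the same day-before-harvest convention as the
budget module, so the zero-noise pipeline round trip is exact up to pixel
quantization. Negative simulated measurements are truncated at 10⁻⁶ with a
warning (keeping sample counts fixed) rather than resampled.

Noise defaults: PCS measurement log-sd 0.02, leaf length sd 0.8 cm, width
sd 0.4 cm, dry weight sd 0.03 g. These represent *measurement
repeatability*; the generator deliberately omits plant-level biological
variation in morphology and in light use efficiency (every plant shares
one true LUE, whereas real plants show declining LUE with age and
plant-to-plant spread). Consequently synthetic regression R² values are
higher than field data would give, and passing tests demonstrate that the
*estimators* recover the generating truth under realistic measurement
error — not that real lettuce behaves this simply.

### Image rendering

Canopies are rendered as cosine-lobed rosettes (6–12 lobes, 15% lobe
depth; a plain disk mode exists for analytic tests) on a 896 × 896 px,
16-bit frame at 0.06 cm/px with a 3 cm scale bar. The outline is scaled so
that exactly `round(PCS/(cm/px)²)` pixel centers fall inside — the scale
factor is the k-th smallest normalized radius — so rendered area error is
below one pixel and segmentation of a rendered frame returns the requested
area to well under 1% for any canopy larger than a few hundred pixels.
Frames are bit-identical for identical inputs and seed.

## Problem sizes and determinism

All stochastic operations are reproducible from explicit integer seeds;
per-frame seeds derive from (experiment seed, plant, day) seed sequences.
The test suite and acceptance script use 60-plant experiments (the study
size), 100–125 random rendered canopies for segmentation sweeps, and 200
replicate experiments for the coefficient-recovery check — sizes chosen so
every Monte-Carlo margin is wide relative to its tolerance.

## Known limitations

- The linear-in-grid light field ignores lamp falloff curvature; real
  chamber maps are measured per plant anyway.
- No inter-plant shading or leaf-level 3D geometry: the emulated studies
  harvested before canopies overlapped, and PCS is by definition top-view.
- Constant generating LUE and linear FR/PPFD responses mean the generator
  cannot probe saturating or supra-optimal light effects.
- The efficacy ratio is meaningful only where both slopes are positive;
  for responses with antagonistic signs (e.g. leaf length vs PPFD) the
  ratio is reported but has no "more effective" interpretation.
- With only ~5 imaging points before the early harvest, the quadratic
  back-extrapolation to germination is weakly constrained; the 0.01 cm²
  floor and the small early-day doses keep the effect on cumulative light
  negligible.
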