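# Methods

This note records the models implemented in `rseisim`, the defaults and why
they were chosen, what the synthetic-scene generator does and does not
emulate, and the numerical conventions that matter for reproducing results.

## Raster model and harmonization

All layers live on one square-cell, north-up grid in a projected CRS
(metres); cell centres carry the geometry. Nodata propagation is strict —
any operation consuming an invalid cell emits an invalid cell — so the
sample entering the PCA is identical across all four indicators. Inputs at
other resolutions are harmonized to the reflectance grid (the 30 m analogue):
continuous fields (population density, building height, thermal radiance)
bilinearly, categorical layers by nearest neighbour, and fine binary rooftop
masks by exact block aggregation into percent cover (the fine cell size must
divide the target cell size). GeoTIFF I/O is float32 with an explicit nodata
tag and the standard georeferencing tags (pixel scale, tiepoint, CRS text).

Min–max normalization `(v − min)/(max − min)` takes its range over valid
cells inside an optional domain mask; in the index pipeline that domain is
the non-water valid set, so masked water can never set a normalization
range. All-constant input is an error rather than a silent zero: a
degenerate range would otherwise poison the PCA.

## Indicators

- **Greenness** NDVI = (NIR − Red)/(NIR + Red).
- **Wetness** — tasseled-cap wetness with the Landsat-8 OLI coefficients
  (0.1511, 0.1973, 0.3283, 0.3407, −0.7117, −0.4559) on the six
  reflectance bands.
- **Dryness** NDISSI = (NDISI_nor + NDSI_nor)/2, with
  NDSI = (SWIR1 − NIR)/(SWIR1 + NIR) and
  NDISI = (TIR − m)/(TIR + m), m = (WI + NIR + SWIR1)/3, WI = MNDWI.
  Components are min–max normalized over non-water valid cells before
  averaging, so NDISSI lies in [0, 1].
- **Heat** — single-channel LST (below), normalized to [0, 1] only inside
  the RSEI construction.
- **Water mask** — MNDWI = (Green − SWIR1)/(Green + SWIR1) strictly above a
  threshold (default 0.1, configurable). MNDWI is used because large water
  bodies would otherwise dominate the PCA loadings.

Numerical conventions: zero denominators become nodata (not ±inf) so the PCA
sample stays finite. The thermal band enters NDISI after min–max scaling to
[0, 1] (`ndisi_scale: tir_only`, default) so it is commensurate with
reflectance; `all_bands` and `none` variants are kept behind a flag because
the appropriate common scale for mixed thermal/reflectance inputs is a
genuine design choice. Because WI can be negative over land, the raw NDISI
ratio can fall marginally outside [−1, 1]; outputs are clipped to the ratio
range.

## Single-channel LST

`LST = γ[ε⁻¹(ψ₁L + ψ₂) + ψ₃] + δ` with `T = K₂/ln(K₁/L + 1)`
(K₁ = 774.89 W/m²/sr/µm, K₂ = 1321.08 K for TIRS band 10),
`γ = T²/(b_γ L)`, `δ ≈ T − T²/b_γ`, b_γ = 1324 K, ψ₁ = 1/τ,
ψ₂ = −L↓ − L↑/τ. Two ψ₃ conventions circulate in the literature — the
upwelling radiance L↑ and the downwelling L↓; both are implemented
(`psi3_convention: paper | standard`, default the former) rather than
guessing which was intended; they coincide in the clear-sky limit. The
identity `γL + δ = T` holds to machine precision by construction, and with
ε = 1, τ = 1, L↑ = L↓ = 0 the retrieval equals the brightness temperature —
the closed-form check the acceptance suite enforces at 1e−9 K.

Atmospheric parameters are scene-level scalars (no atmosphere model is
computed); emissivity defaults to an NDVI-threshold scheme (soil 0.966 below
NDVI 0.2, vegetation 0.986 above 0.5, linear blend between, water 0.991),
with a constant-ε override. These defaults are the conventional Landsat
values; none of the acceptance quantities depends on them.

## RSEI construction

The indicator matrix holds the cells valid in all four indicators and not
water, each column min–max normalized over exactly those rows. PCA is of the
**covariance** matrix of the mean-centered columns — no variance scaling,
because normalization has already made the columns commensurate and
covariance weighting is the point of the construction. Eigenvector sign is
arbitrary, so PC1 is oriented by forcing the greenness loading non-positive
(wetness as tie-breaker); combined with RSEI₀ = 1 − score this makes
greener/wetter cells score higher regardless of the solver's sign choice,
and the final RSEI is bit-identical under eigenvector negation (tested).
RSEI₀ is min–max rescaled over the matrix rows, so RSEI attains exactly 0
and 1 on every scene. PCA is per scene/year, which means RSEI values are
comparable across years only ordinally — a documented caveat of the method,
not of this implementation.

Levels: [0, 0.2), [0.2, 0.4), [0.4, 0.6), [0.6, 0.8), [0.8, 1.0] → codes
1–5, lower-closed with the top interval closed — printed ranges like
"0.2–0.4" are boundary-ambiguous, so the rule is fixed here once. Water
cells are nodata throughout (never level 1) and excluded from level areas,
change detection and zonal means.

## Regression of RSEI on construction features

Five features: NDVI_nor, NDISI_nor (each min–max over non-water cells),
rooftop percent PB [0, 100], population density PopD ≥ 0, building height
BH ≥ 0 m. Training rows are a seeded uniform sample without replacement of
usable cells. The learner is XGBoost (squared error, single-threaded for
determinism); hyperparameters are tuned by seeded uniform random search over
the fixed space eta [0,1], gamma [0,20], max_depth [1,20], min_child_weight
[1,10], subsample [0.5,1], colsample_bytree [0.5,1], nrounds [50,300]
(integers rounded), scored by mean held-out RMSE over 5 seeded folds.
Random search (default budget 60 candidates) was chosen over a grid because
the space is seven-dimensional and a seeded random design covers it more
evenly at equal cost. When tuning is skipped, the fallback configuration is
eta 0.1, depth 6, 200 rounds.

Predictions are clamped to [0, 1] (the index range). Shapley attributions
are exact TreeSHAP values from the booster itself; the efficiency identity
(base value + Σ attributions = prediction) is checked against the *raw*
margin, since the clamp would break additivity on out-of-range rows, and
holds to 1e−6 (float32 attribution arithmetic). Marginal effects are emitted
two ways — partial dependence (set the feature to each grid value in every
row, average clamped predictions) and the Shapley-dependence scatter —
because published marginal-effect curves do not always say which they are;
deterministic partial dependence is what the tests pin down.

## Scenario engine

A1 is the built/bare core: normalized NDISSI ≥ threshold, Otsu-derived by
default (no published threshold value exists to adopt), user-overridable.
Rings A2–A4 come from a Euclidean distance transform of cell centres:
ring k = cells with distance to the nearest A1 cell in (d_{k−1}, d_k],
d = (200, 400, 600) m. This raster approximation of a vector GIS buffer is
exact up to ±½ cell discretization; the test suite pins it to a brute-force
all-pairs distance oracle on 20×20 grids.

The "5 % progressive change" is interpreted as **relative** (×0.95 for
NDVI_nor, ×1.05 for the rest) by default; an additive-of-range mode is kept
behind a flag because percentage-point stepping is the other defensible
reading — multiplicative stepping keeps nonnegative features nonnegative
(making the NDVI ≥ 0 clamp vacuous), while the additive mode actually
exercises that clamp. Clamps (NDVI_nor ≥ 0, NDISI_nor ≤ 1, PB ≤ 100) are
idempotent and commute with repeated perturbation at the bound.

Scenario S_k activates region k (A1 first, then rings outward) and applies
one step to the union of active regions, so after S_k a region activated at
step j has accumulated k−j+1 steps (e.g. A1 features carry a factor
0.95⁴/1.05⁴ after S4, pre-clamp). Zero-substitution applies when a buffer
ring is newly activated: cells with PopD and BH *both* zero receive the
minimum nonzero value of each layer within that ring ("minimum non-zero" is
the working reading of the ambiguous published wording; "within that
region" is read as the new ring, with a scene-wide fallback when the ring
has no nonzero values). A1 gets no substitution — it is the already-built
core. Scenario means are taken over all valid cells of the feature state;
cells outside every region are provably scenario-invariant.

## Synthetic scenes: what they do and do not show

`generate_scene` draws one smoothed Gaussian noise field, thresholds it at
the quantiles of the configured class fractions (water 0.10, vegetation
0.45, bare soil 0.15, impervious 0.12, settlement 0.18 by default), and
fills per-class mean spectra plus Gaussian noise (reflectance sd 0.015,
radiance sd 0.15, correlation length 4 cells). The default spectra encode
the qualitative orderings the index relies on — vegetation greener and
wetter, built/bare surfaces hotter and drier (radiance 8.6 → 10.4
W/m²/sr/µm from vegetation to impervious) — so the class-mean RSEI ordering
vegetation > bare soil > impervious holds by construction and is asserted
end-to-end. Construction layers put clustered rooftop percents, lognormal
population (median e^3.3 ≈ 27 per cell) and low-rise lognormal heights
(mean ≈ 6.4 m) on settlement cells and zeros (PB exactly) elsewhere,
mimicking the small-scale-concentration / large-scale-dispersion pattern of
rural building clusters.

`generate_feature_fields` is a separate generator for response-surface
recovery: rank-uniform smoothed fields covering [0, 1] without the coverage
gaps a class-clustered scene leaves between class modes.
`generate_regression_target` composes a known response (linear, U with
vertex 0.4, inverted-U with turning point 0.6) with seeded noise, enabling
the turning-point recovery checks (argmax/argmin of the fitted
partial-dependence curve at n = 10⁴, noise sd 0.02).

What passing these tests shows: the machinery — masking, normalization,
PCA orientation, bookkeeping, attribution, curve construction — is correct,
and the qualitative claims (monotone scenario decline under a monotone
response; U / inverted-U turning points recoverable) are reproduced under
known ground truth. What it does not show: agreement with any real scene's
RSEI values. Real Landsat scenes have mixed pixels, phenology, atmospheric
residuals and sensor noise the generator does not emulate, and published
study-area numbers (mean RSEI trajectories, fitted hyperparameters, model
RMSE, scenario means) depend on those real rasters. Relatedly, on a
class-clustered synthetic scene the fitted scenario response need not be
monotone — the model is unconstrained between class modes — which is why the
monotone-decline property is stated and tested for monotone fitted
responses.

## Problem sizes and determinism

Default problem sizes are chosen as the smallest at which the statistical
checks are stable: 120×120 scenes (≈ 13 km at 30 m) for index/PCA
properties, 10⁴ sampled pixels for curve recovery, 20×20 grids for the
exhaustive distance oracle, random-search budgets of 4–12 candidates in
smoke tests. All randomness flows from explicit seeds through named
substreams (class map, reflectance, radiance, construction, targets);
XGBoost runs single-threaded with a fixed seed, so tables, models,
attributions and scenario results are bit-reproducible.

## Known limitations

- Per-scene PCA makes cross-year RSEI ordinal, not cardinal.
- No atmospheric correction, cloud masking or CRS reprojection; inputs are
  assumed to be surface reflectance on one projected grid.
- The raster buffer approximates a vector buffer to half a cell.
- Scenario perturbation alters features only inside rings; no land-cover
  transition model (e.g. cellular automata) is attempted.
- Tree-ensemble partial dependence is piecewise-constant; turning points are
  located to the PD grid resolution (0.025 at 41 points on a unit range).
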