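# Methods

`hypyield` implements a complete inversion chain from visible/NIR
(400–1000 nm) canopy reflectance to a per-plot leaf-yield estimate. This
note records the models, the tunable parameters with their defaults, the
numerical choices, and the limits of what the synthetic test-bed can show.

## 1. Synthetic canopy scenes

No field accession ships with the package; every stage is exercised on a
simulator (`hypyield.synthetic`) that reproduces the qualitative structure
of broadleaf canopy spectra:

- a flat visible baseline (reflectance 0.12),
- a Gaussian green reflectance peak at 560 nm (height 0.10, σ = 17 nm),
- a Gaussian chlorophyll absorption trough at 690 nm whose depth is
  `0.03 + 0.07·chl` for a latent chlorophyll score `chl ∈ [0, 1]`
  (σ = 13 nm),
- a logistic red edge centred at 725 nm (scale 9 nm) rising to a NIR
  plateau of height `0.33 + 0.27·lai` for a latent leaf-area score `lai`,
- shallow Gaussian absorption dips at 820 nm (depth 0.030, σ = 10 nm) and
  930 nm (depth 0.045, σ = 14 nm), gated by the red-edge logistic so they
  act only on the NIR plateau.

Feature positions follow the vegetation-spectroscopy literature; the
Gaussian/logistic shapes and widths (≈30–40 nm FWHM) are package choices.
Yield is linear in the latent traits,
`y = c₀ + c₁·chl + c₂·lai (+ γ·chl·lai)` with default coefficients
(0.2, 1.0, 0.6) and γ = 0, plus Gaussian noise; the same `noise_sd`
(default 0.005 reflectance units) drives i.i.d. per-channel spectral noise
and the yield noise. The linear link gives every model a known recovery
target: with `noise_sd = 0` an ordinary least-squares fit on the traits
recovers the coefficients to machine precision, and NDVI is strictly
increasing in `chl`.

Defaults mirror a 200-plot campaign imaged by a 224-channel instrument:
`n_samples = 200`, `n_bands = 224`, traits uniform on [0.2, 0.9]
(chlorophyll) and [0.3, 1.0] (leaf area), 100 ROI pixels per plot with
5% multiplicative intra-ROI variation, and a fixed linear soil ramp
(0.15 → 0.35) as background so ROI/background separation is trivially
verifiable. Spectra are clipped to [0, 1]; within the documented ranges
the clip is inactive.

`planted_band_data` is a separate fixture generator for band-selection
tests: spectra are Gaussian random fields along the band axis (correlation
length 3 channels), with the response linear in 5 planted channels. The
local smoothness matters — it is what makes a ±2-channel recovery
tolerance meaningful.

What the simulator does **not** emulate: radiative-transfer physics (no
PROSAIL), atmospheric effects, directional/BRDF variation, mixed pixels at
ROI borders, spatially correlated noise, or any nonlinear trait–yield
link beyond the optional interaction. Passing tests therefore show that
the pipeline's machinery is correct and leak-free, not that its accuracy
numbers transfer to field data.

## 2. Radiometric correction and ROI features

The empirical line method converts digital numbers per channel,
`ρ = G·DN + O`. Scalar coefficients broadcast to all channels; estimating
G and O from reference panels is out of scope (they are user-supplied).
Out-of-range reflectance is kept, not clipped — clipping would bias
downstream row statistics — and the offending count is logged and stored
on the cube.

A region of interest is a same-shape boolean mask; pixels are read in
row-major order. The plot spectrum is the per-channel arithmetic mean of
the ROI pixels. The ROI pixel set is additionally summarised by a fixed
4-vector ("B" features, in order): pixel count; dispersion (mean over
channels of the within-ROI per-channel sample sd); brightness (grand mean);
heterogeneity (mean spectral angle of pixels to the ROI mean, radians).
This summary is a documented package choice — the source procedure names
the pixel-set block without defining its statistics. Single-pixel ROIs
have zero dispersion and heterogeneity by convention.

ENVI I/O supports BSQ/BIL/BIP interleaves and int16/uint16/float32/float64
payloads; round-trips are lossless. Wavelength anchors resolve to the
nearest grid channel, ties toward the lower index.

## 3. Pretreatments

Standard chemometric definitions (the source names the five methods
without formulas):

- **SNV** — each row centred by its own mean, divided by its own sample
  sd (n−1 denominator, so `[1,2,3] → [−1,0,1]` exactly).
- **MSC** — each row regressed on `[1, reference]` by OLS; corrected row
  is `(row − a)/b`. Reference defaults to the calibration-set mean.
  Slopes below 1e−12 raise a degenerate-fit error.
- **SG** — Savitzky–Golay least-squares smoothing (default window 11,
  polyorder 2). Edges use scipy's polynomial-interpolation convention
  (a polynomial of the stated order fitted over the edge window), which
  reproduces polynomials of degree ≤ polyorder exactly at every point.
- **FD** — forward difference divided by the wavelength step; output has
  one fewer channel, nominal wavelengths at interval midpoints.
- **SS** — per-band standardisation with mean/sd taken from the
  calibration split only; zero-variance bands get sd 1 with a warning.

Methods with fitted state (MSC reference, SS statistics) fit on the
training split and are applied unchanged elsewhere; the source does not
state this, but anything else leaks the test set. Each pretreatment is
applied to raw reflectance, not stacked.

## 4. Vegetation indices and screening

Seven indices at fixed nm anchors (nearest-channel lookup):
NDVI(801,682), ReCI(801,701), NDRE(801,720), GNDVI(801,561),
SAVI(820,680; L=1), SIPI(820,462,712), MSAVI(801,682). SAVI uses
`((NIR−RED)/(NIR+RED+L))·(1+L)` with L = 1 for sparse canopies; MSAVI uses
`0.5·(2·NIR+1 − √((2·NIR+1)² − 8·(NIR−RED)))`. The ratio-type indices are
invariant to a positive rescaling of the whole spectrum; the two
soil-adjusted indices are deliberately not.

Screening runs in three stages on training rows only:

1. **Importance ranking** — impurity importances from a seeded random
   forest (500 trees), normalised to sum to 1.
2. **Forward stepwise retention** — candidates enter in descending
   importance; one is kept if it lowers the 5-fold CV RMSE of the
   incremental forest by more than 1e−4; the scan stops after two
   consecutive failures. The tolerance and the two-failure stopping rule
   are package choices.
3. **Correlation pruning** — the Pearson matrix is computed over all seven
   indices; within the considered set, each pair with r ≥ 0.90 loses its
   lower-importance member. Only *positive* correlations trigger a drop:
   strongly anti-correlated index families (structure- vs pigment-driven)
   are treated as complementary. The orthodox |r| rule is available via
   `use_abs=True`.

The high-level `screen_indices` applies the pruning stage to all seven
candidates rather than to the stepwise survivors, because anti-correlated
families excluded by a greedy forward scan can still carry complementary
signal; the stepwise list is reported alongside for inspection.

## 5. Band selection

All selectors share one fitness oracle: mean seeded k-fold CV RMSE of a
PLS regression restricted to the candidate columns
(components = min(10, |subset|, fold rank)). PLS is the natural reference
model for collinear spectra, and using the same oracle makes subsets
comparable across methods. Default subset sizes are 10 (PSO), 20 (PSAMA),
10 (SPA), 21 (PCA), 20 (LASSO) and schedule-determined for CARS; all are
configuration defaults, not assertions about any particular dataset.

- **PSO** — canonical velocity/position updates
  `v ← w·v + c1·r1·(pbest−x) + c2·r2·(gbest−x)`, `x ← clip(x+v, 0, 1)`,
  with w = 0.7, c1 = c2 = 1.5, 30 particles, 100 iterations. Positions are
  continuous weights in [0,1]^bands decoded to the indices of the k
  largest weights; this keeps the update equations verbatim and the
  subset size controllable. One particle is warm-started from the
  normalised |correlation-with-y| profile (a standard wrapper-selection
  initialisation); the rest are uniform. Disable with
  `warm_start=False`.
- **PSAMA** — identical to PSO except the social attractor: the global
  best is replaced by a scaled-dot-product attention consensus,
  `softmax(gbest·pbestᵢ/√d)`-weighted sum of the personal bests (query =
  global best, keys = values = personal bests). With one particle the
  consensus equals that particle's personal best and the algorithm is
  bit-identical to PSO — a reduction the tests assert.
- **SPA** — classic successive projections: repeatedly project remaining
  columns onto the orthogonal complement of the selected span and take
  the largest residual norm. With no fixed start, every start column is
  tried and the chain with lowest CV fitness wins. On rank-deficient
  spectra every chain collapses early; the longest chain is returned with
  a warning rather than an error.
- **PCA** — components of the *centred* (not variance-scaled) matrix up
  to 95% explained variance; bands ranked by maximal |loading|; scores
  rounded to 10 decimals so degenerate bands tie exactly, ties to the
  lower index. Centring-only is deliberate: reflectance bands share a
  physical scale, and per-band variance scaling would erase the variance
  structure the loadings rank.
- **LASSO** — bands standardised; the penalty is bisected on a log scale
  (40 steps) until the support size is as close as possible to the target
  (preferring ≤); the support is returned ordered by |coefficient|. If
  every probed penalty empties the support, the penalty is relaxed until
  bands reappear, with a warning.
- **CARS** — per iteration, a Monte-Carlo 80% row sample fits PLS on the
  surviving bands; the retention ratio follows `rᵢ = a·e^(−k·i)` with the
  two boundary conditions r₁ = 1 and (final retained count) = 2, i.e.
  `a = (p/2)^(1/(N−1))`, `k = ln(p/2)/(N−1)`; adaptive reweighted sampling
  draws the survivors without replacement with probabilities ∝ |PLS
  coefficient|. The iteration whose survivors minimise the CV fitness
  wins. Default N = 50 iterations.

Every selector is deterministic under its seed (asserted by double runs).

## 6. Regression models and evaluation

The campaign splits 70/15/15 into train ("calibration"), validation and
test ("prediction") by seeded shuffle; fraction floors are taken and the
remainder joins the training split (200 → 140/30/30; 10 → 8/1/1).
Metrics are `R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)²` and RMSE; Rc²/RMSEc score the
training split, Rp²/RMSEp the test split, and the validation split is used
only for tuning and early stopping.

Seven kinds share one fit/predict/evaluate contract:

| kind | tuned hyperparameter | default |
|---|---|---|
| plsr | n_components | 10 |
| rf | n_estimators | 200 |
| knnr | n_neighbors | 10 |
| svr | C | 10 |
| lstm | learning_rate | 0.01 |
| bilstm | learning_rate | 0.01 |
| bilstm_gs | learning_rate, hidden_layer_size | 0.01, 50 |

PLSR/RF/KNN/SVR are scikit-learn estimators; KNN and SVR see standardised
features and SVR additionally a standardised target, so its ε-tube is
scale-free. The recurrent kinds read the feature vector as an ordered
sequence of scalar steps in wavelength order (fused blocks appended in
the order bands → indices → B) and are implemented directly in numpy:
one LSTM layer (gates i/f/g/o, forget bias 1), optional second pass over
the reversed sequence with concatenated final hidden states, a linear
readout, explicit backpropagation through time (verified against finite
differences in the tests), Adam (β = 0.9/0.999), batch 16, up to 200
epochs, early stopping on validation MSE with patience 20 and
best-weight restoration. Inputs and targets are standardised internally.

`grid_search` exhaustively evaluates a hyperparameter grid by seeded
k-fold CV RMSE on the training split (CV on the training split, not the
validation split, which stays reserved for early stopping); ties break
toward the earlier grid point. Default grids: learning rate
{1e−4…1e−1}, hidden size {10, 25, 50, 100}, n_components 1–15,
n_estimators {50,100,200,400}, n_neighbors {1,3,5,10,15}, C
{0.1,1,10,100}. The returned score surface feeds the 2-D hyperparameter
heatmap (CSV and optional PNG, best cell annotated).

## 7. The sweep and the desk-scale profile

Input-set codes follow the grammar `base (+A2) (+B)` with bases A1 (all
bands), A2 (the four screened indices) and A3–A8 (PSO, PSAMA, SPA, PCA,
LASSO, CARS subsets); the standard enumeration is 30 codes × 7 kinds =
210 runs. Band selection operates on pretreated (default SNV) training
spectra; indices are computed from reflectance. Failed runs are recorded
and the sweep continues; results are written as a CSV sorted by Rp² with
a JSON-lines run log (seed, config hash, wall time). Two sweeps from the
same configuration produce byte-identical result tables.

`reduced_protocol()` is the package's desk-scale profile used by the test
suite and the acceptance script: 50 samples × 64 bands, 25-pixel ROIs,
3-fold CV, no per-run tuning (defaults above), swarm 8 × 10 iterations,
CARS 15 iterations, and a light recurrent schedule (hidden 8, 8 epochs,
patience 4). It preserves the full statistical structure and enumeration
while a complete double sweep runs in about a minute on one CPU core.

## 8. Known limitations

- PSO/PSAMA optimise a noisy combinatorial objective through a continuous
  relaxation; they are not guaranteed to find the global best subset, and
  the reported Table-style band lists are data-bound outcomes, not
  reproducible targets.
- The numpy recurrent models are single-layer and CPU-bound; they are
  adequate for hundreds of samples and a few hundred sequence steps, not
  for large imagery.
- Degenerate inputs are handled by convention where a strict reading
  would abort: SS keeps zero-variance bands (sd→1, warning), SPA returns
  short chains on rank-deficient spectra (warning), LASSO relaxes a
  fully-shrinking penalty (warning). SNV and MSC raise on constant rows —
  silently "fixing" a flat spectrum would mask upstream data errors.
- Yield in the simulator is linear in two latent traits; models that can
  exploit nonlinearity (RF, SVR, recurrent kinds) show no advantage over
  PLSR here, and relative model rankings on synthetic sweeps should not
  be read as field conclusions.
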