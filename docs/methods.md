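# Methods

`teaspec` implements a complete hyperspectral chemometrics workflow for
catechin quantitation in fermenting black tea: a synthetic data generator
with known ground truth, spectral pretreatment, characteristic-wavelength
selection, PCA-compressed calibration models (PLS / ELM / SVR) and
pixel-wise content mapping. This note records the models, the defaults and
the reasoning behind the open design choices.

## Fermentation kinetics

Catechins are oxidised enzymatically during fermentation. Each component's
content follows a first-order decay with a non-reactive residual pool:

    C(t) = C0 · [(1 − f) + f · exp(−E(t))]

where `f` is the reactive fraction and `E(t)` the accumulated rate exponent.
Only endpoint decreases are specified as study conditions (EC −96.28 %,
EGC −4.5 %, Total −78 %, C −85 %, EGCG −80 %, ECG −75 %; every non-EGC
component above the −72.06 % floor), plus the qualitative fast (0–2 h) /
slow (2–5 h) phase structure. We therefore parameterise the decay by a
completion level: the layer-mean reactive pool is 98 % converted at 5 h
(`f = d / 0.98` for endpoint decrease `d`), and the base rate constant is
solved numerically so the layer-mean series drops by exactly `d`. This
pins all endpoint anchors to machine precision while producing the
fast-then-slow shape.

Initial contents (% dry mass): Total 15.4 = EGC 0.8 + C 1.2 + EC 2.2 +
EGCG 8.0 + ECG 3.2. The monomer split was chosen so the monomer-weighted
mean decrease (77.8 %) tracks the Total decrease (78 %), keeping the
monomer sum within 10 % of Total at every time point.

**Layer structure.** Stacked fermentation beds react at different rates:
the middle layer lags early (less oxygen than the surface, cooler than the
bottom), the lower layer lags late. A single constant per-layer rate
multiplier cannot reproduce the observed switch of the content-maximal
layer (middle at 2 h, lower at 3–5 h) because content is then monotone in
the multiplier at every time. We therefore use two-phase multipliers
(early 0–2 h / late 2–5 h): upper (1.2, 1.0), middle (0.7, 1.3), lower
(1.0, 0.4). These defaults produce the required argmax switch.

## Forward optical model

Apparent absorbance is Beer–Lambert mixing: `A(λ) = Σᵢ cᵢ εᵢ(λ) + base(λ)`,
with per-monomer absorptivity profiles built from Gaussian peak mixtures
whose centres all lie inside 406–957 nm; reflectance is `R = 10^(−A)`.
Instrument artefacts are applied per spectrum in reflectance space:
affine scatter (`R' = s·R + o`, s ~ N(1, 0.05), o ~ N(0, 0.01)), a linear
baseline drift (amplitude 0.01) and additive Gaussian noise (sd 0.003),
clipped to (0, 1.5]. An optional quadratic term (`A → A + κA²`) bends the
content–absorbance link for nonlinear-model studies.

The default grid is 400–960 nm with 401 bands (1.4 nm spacing) — a desk
scale that preserves the instrument's spectral span while keeping the
selection algorithms fast. The default design is 6 time points × 3 layers
× 10 replicate spectra = 180 spectra (9 replicates give the alternative
162-sample design). Models consume absorbance `−log10(R)` by default;
every stage can run on reflectance instead.

What the generator does *not* emulate: radiometric camera effects,
illumination geometry, wavelength-dependent instrument response, detector
saturation, or real tea chemistry beyond the six catechin contents.
Passing tests therefore demonstrate the correctness and statistical
behaviour of the algorithms under a controlled forward model, not
instrument-grade performance on real tea measurements.

## Pretreatments

Seven standard pretreatments: moving-average smoothing (window 5, edges
use shrunken windows), SNV (row-wise, sd divisor n−1), MSC (row-wise affine
regression on the calibration-mean reference), Savitzky–Golay second
derivative (window 7, polyorder 2, derivative w.r.t. band index; edge bands
use one-sided polynomial fits so the band count is preserved), and
column-wise Center / Z-Score / Min-Max. Column statistics are computed on
calibration rows only and carried in a provenance-tagged object, so the
prediction set can never influence the transform (leakage guard).

## Sample partitioning and wavelength selection

Kennard–Stone max–min partitioning (3:1 calibration:prediction,
`round(0.75·n)` calibration samples) is deterministic and verified against
a brute-force oracle.

The shared selection objective is cross-validated RMSE (5-fold, seeded):
multilinear regression for subsets of ≤ 10 bands, PLS capped at 10 latent
variables above that.

* **SPA** grows greedy chains from every start band by maximal projection
  onto the orthogonal complement of the selected span; the winning chain
  minimises CV-RMSE of a multilinear model.
* **SFLA** searches binary band subsets with 5 memeplexes × 10 frogs and
  50 iterations by default; the worst frog of each memeplex leaps toward
  the local best, the global best, or is redrawn. Elitist tracking makes
  the fitness trace non-increasing.
* **VCPA** draws 500 random binary subsets per loop (inclusion 0.5) over
  the surviving bands, keeps the best 10 %, scores bands by frequency among
  the kept subsets and shrinks the pool along the EDF schedule
  `round(n0·(final/n0)^(k/K))` over 10 loops to 100 survivors.
* **Refinement**: GA (population 30, 100 generations, uniform crossover
  0.9, per-bit mutation 0.05, tournament 3, elitism 1) or IRIV (random
  inclusion matrices; a band whose inclusion raises CV-RMSE is classified
  uninformative/interfering — Mann–Whitney at α = 0.05 separates the two —
  and dropped; a round of drops is only accepted if the surviving subset's
  fitness does not degrade; backward elimination finishes the subset).

The pipeline's default per-component pairing is SPA for total catechins,
VCPA-GA for EGC and ECG, and VCPA-IRIV for C, EC and EGCG; it is a config
entry, not hard-coded. The pipeline-level search budgets are desk-scale
(VCPA 150 draws × 6 loops to 40 survivors; GA 24 × 30; IRIV 60 draws)
so a full six-component run completes in a few minutes on one core; the
module-level defaults above are used when the selectors are called
directly.

## Calibration models

After selection, PCA (fit on calibration rows of the selected bands only)
compresses the subset; the number of score columns fed to a model is chosen
by minimal 10-fold RMSECV, ties to the fewest components, capped at 15.

* **PLS**: NIPALS on centred data (scikit-learn backend), validated against
  an OLS oracle at full rank and for score orthogonality.
* **ELM**: 50 logistic hidden units, input weights and biases drawn once
  from Uniform(−1, 1) under the seed, output weights by ridge-regularised
  least squares (ridge 1e-8) on the centred response. Inputs are centred
  and scaled by a single global factor (the largest column sd) rather than
  per column: PCA scores carry their information in their relative
  variances, and per-column standardisation inflates near-noise directions
  to unit scale, which measurably degrades the network. With global
  scaling the ELM recovers sin(PC1) with held-out R > 0.98.
* **SVR**: epsilon-SVR, RBF kernel, epsilon 0.01 on the standardised
  response. The dense tuning grids are c ∈ 2^(−5…15), g ∈ 2^(−15…3) in
  half-octave steps (these contain the classical optima 2.83 = 2^1.5, 4,
  16, 32 and 0.5, and bracket 0.35, 0.63, 0.063 within half a step); the
  pipeline default is the octave-step subgrid c ∈ 2^(−2…10), g ∈ 2^(−7…1)
  to keep a full run within minutes. Ties take the smaller c, then g.

Evaluation reports Rc and Rp (Pearson), RMSECV, RMSEP and
RPD = sd(prediction references, divisor n−1) / RMSEP, with the standard
grades: RPD in [1.4, 1.8] rough, above 2 accurate, otherwise inadequate
(1.9 falls in neither named band and is graded inadequate). A zero RMSEP
yields an infinite RPD with a logged warning.

## Pixel-wise mapping

Background segmentation is Otsu thresholding on a contrast band (chosen
automatically by maximal between-class variance), tea taken as the darker
class, followed by small-object/small-hole removal — deliberately not a
majority filter, which erodes the corner pixels of curved regions.

Single-pixel spectra are far noisier than the ROI means the calibration
saw, so `denoise_cube` (spectral Savitzky–Golay window 9 plus a masked
5×5 spatial mean that never mixes background into tea pixels) precedes
prediction. The pretreatment of choice for mapped models is the second
derivative: it cancels the per-pixel additive offset and linear baseline
drift exactly, which SNV/MSC only approximate. Tea pixels are flattened,
pretreated with the chain's stored calibration statistics, band-subset,
projected with the calibration PCA loadings and predicted; background
pixels are exactly 0 and negative predictions are clipped to 0 with a log
note. Rendered maps are exact-size PNG rasters with a JSON sidecar
(component, units, colour scale spanning the tea-pixel min/max, or a fixed
scale for cross-stage comparison); an annotated figure with a labelled
colour bar is optional. Cube truth maps use a Gaussian-field content
jitter (sd 0.12, correlation length 3 px) emulating leaf-patch
heterogeneity.

## Numerical and degenerate-input policy

Constant spectra (SNV), near-zero MSC slopes, zero-variance bands
(Z-Score/Min-Max), empty band subsets, zero-variance responses and
unimodal mask images all raise typed errors naming the offending row or
band. Empty subsets drawn by stochastic selectors are repaired by
activating one random band. All stochastic routines take explicit seeds
and are bit-reproducible; ties (RMSECV, SVR grid, band frequency) break
deterministically (fewest components; smaller c then g; lower band index).

## Problem sizes

The test-suite runs use desk-scale sizes chosen as representative working
points: 80–101-band grids for unit tests, the full 401-band grid with 180
spectra for end-to-end recovery, 150 × 200 matrices for planted-band
recovery, and 24–32 px cube frames for mapping. The planted-band suite
uses reduced VCPA/GA/IRIV budgets (120 draws × 5 loops to 30 survivors;
GA 20 × 20; IRIV 60 draws), which recover the planted bands in ≥ 9 of 10
seeds.

## Known limitations

* The default kinetics drive all six contents with one latent fermentation
  state, so contents are mutually collinear by design; studies that need
  independent content variation (nonlinearity comparisons, scatter
  benchmarks) use `perturb_chem_replicates` to add per-monomer lognormal
  spread.
* With the default noise mix, full-spectrum PLS largely absorbs affine
  scatter, so pretreatment rankings on default data are close; the scatter
  benefit of SNV/MSC is demonstrated under a pure planted scatter artefact.
* LS-SVM (an alternative reading of the source workflow's tuning function)
  is not implemented; epsilon-SVR with the documented grids is used and
  recorded in the report.
* ENVI I/O covers BSQ/BIL float rasters with text headers — sufficient for
  round-tripping this package's cubes, not a general ENVI reader.
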