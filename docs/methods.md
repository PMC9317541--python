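# Methods

This note documents the models implemented in `wheatlai`, the choices made
where the design was genuinely open, and what the synthetic test conditions
do and do not establish about real data.

## Forward canopy reflectance model

**Leaf optics (PROSPECT-D plate model).** A leaf is modelled as `Ns`
elementary plates separated by air. Each plate has optical depth
`k(λ) = (Cab·kab + Car·kcar + Cant·kant + Cbrown·kbrown + Cw·kw + Cm·km)/Ns`,
isotropic transmissivity `τ = (1−k)e⁻ᵏ + k²E₁(k)` and Fresnel interfaces
described by the Stern/Allen closed form of the angle-averaged
transmissivity `tav(θ, n)` (validated in-tree against direct numerical
integration of the Fresnel coefficients). The top surface uses a 40°
incidence cone, interior surfaces the full hemisphere; the remaining
`Ns − 1` layers are added with the Stokes solution for a pile of identical
plates, with the conservative/opaque limit handled explicitly.

Parameters (units, sampling ranges of the broad set): Ns 1–2.5 (–),
Cab 0–90 µg cm⁻², Car 0–20 µg cm⁻², Cant = Cbrown = 0, Cw 0.001–0.05 g cm⁻²,
Cm 0.001–0.02 g cm⁻².

**Canopy reflectance (4SAIL).** Four-stream turbid-medium model: extinction
and scattering coefficients are averaged over an ellipsoidal leaf
inclination distribution (Campbell eccentricity parameterisation, mean
angle ALA, 18 five-degree zenith bins), the hot spot uses the standard
20-node exponential-kernel overlap integral, and the Lambertian soil is
coupled analytically. `LAI = 0` returns the soil spectrum exactly (the
analytic limit is substituted rather than evaluated, so the identity is
bit-exact). The returned observation is
`R = skyl·rdot + (1 − skyl)·rsot`, i.e. the bidirectional term for the
direct solar fraction plus the hemispherical-directional term for the
diffuse fraction.

Two conventions follow the study design this package implements:

* **Hot spot only at alignment.** In `simulate_canopy_reflectance` the
  supplied `hspot` takes effect only when `VZA == SZA`; otherwise it is
  reset to 0. (With the nadir-view datasets used throughout, the hot-spot
  path is effectively inactive.)
* **skyl from SZA.** `skyl = clamp(0.847 − 1.61·sin h + 1.04·sin²h, 0, 1)`
  with `h = 90° − SZA`, the empirical clear-sky relation of the standard
  model driver. The direct:diffuse irradiance ratio is treated as
  spectrally flat — the driver's solar irradiance tables are data this
  package does not ship — so `skyl` enters as a plain mixing weight.

**Synthetic coefficient library.** The published PROSPECT-D calibration
tables and reference soil spectra are data files of the reference model
distribution and are not redistributable, so `wheatlai.library` *generates*
a synthetic library: Gaussian absorption bands at the known feature
positions (chlorophyll 420/672 nm, carotenoids < 550 nm, water
970/1200/1450/1940/2500 nm, dry matter rising through the SWIR), a smooth
refractive index (1.52 → 1.40), and logistic-rise soil endmembers with
water features. Amplitudes were calibrated once against canonical fresh-leaf
values (red reflectance ≈ 0.04, NIR reflectance/transmittance ≈ 0.48, SWIR
water band depths) and typical bare-soil reflectance (NDVI ≈ 0.14). The wet
soil endmember darkens progressively with wavelength (wet/dry ratio 0.70 →
0.42); this spectral-shape change is what makes the wetness factor
identifiable from visible/NIR bands alone. Every derived quantity is
therefore *realistic in shape and level but not identical to the published
calibration*; consequences are noted under Limitations.

**Validation strategy.** Because no independent reference executable is
bundled, correctness is checked two ways: (i) closed-form/physical
invariants (energy conservation, bare-soil limit, bounds, Fresnel-integral
agreement of `tav`), and (ii) a dual-route equivalence test — the
vectorised production code is compared, at ≤ 1e-4 per wavelength over a
24-combination panel spanning the sampling ranges, with a deliberately
plain scalar transcription of the same published algorithms
(`tests/reference_rtm.py`) that shares only the coefficient data. This
catches vectorisation, broadcasting and masking errors, though not an error
faithfully transcribed into both routes.

## Band resampling

The five camera bands (Blue 475/20, Green 560/20, Red 668/10, RedEdge
717/10, NIR 840/40 nm centre/bandwidth) use Gaussian response curves with
FWHM equal to the bandwidth, truncated at ±2·bandwidth and renormalised —
a synthetic surrogate for the manufacturer's measured responses, which can
be supplied as CSV tables instead. Band values are response-weighted means;
dataset generation simulates only the ~600 wavelengths inside the band
supports (all other weights are exactly zero, so band values are unchanged;
the suite asserts this).

## Soil calibration

`Rsoil = asoil · (psoil·Rdry + (1−psoil)·Rwet)`, `asoil ∈ [0.01, 3]`,
`psoil ∈ [0, 1]`. The printed form of the mixture is ambiguous about what
the brightness factor multiplies; `asoil` scaling the whole mixture is the
default (a brightness factor on the soil spectrum), with the
dry-only-scaling variant behind a flag. The fit objective is the sum of
absolute band deviations (least squares optional), minimised by a
deterministic 0.01-step grid scan followed by a bounded Nelder–Mead polish;
no random initialisation, and the refined optimum is never accepted if it
is worse than the best grid cell. All five bands enter the fit; excluding
the blue band (whose surrogate response is least certain) was considered
and rejected for the default because the synthetic round-trip shows no
benefit.

## Training datasets and the regressor

Parameter sets p1/p2/p3 share Ns, Cab, Car, ALA (20–70°), hspot
(0.01–0.5), SZA (20–70°), RAA (−90–90°), fixed Cant = Cbrown = 0,
psoil = 1, VZA = 0; they differ in Cm, Cw and LAI (p1: 0.001–0.02 /
0.001–0.05 / 0–8; p2: 0.001–0.01 / 0.001–0.03 / 0–7; p3: as p2 with LAI
0–5). Sampling is plain uniform with a recorded seed; RAA is sampled even
though it is inert at nadir view, to keep the parameter record complete.
`skyl` is recomputed from each row's SZA. Datasets are named `Dp{set}s{soil}`
in their provenance.

Both the five band features and the LAI target are z-score standardised
("zero-mean normalisation" is read as full standardisation — removing the
mean alone would not address scaling). The forest: 200 trees,
min_samples_leaf = 1, max_features = ⌊log₂ 5⌋ = 2, squared-error splits,
bootstrap resampling; predictions are de-standardised tree means, not
clipped (forest means are inherently bounded by the training target range,
which the suite asserts). Hyperparameter tuning is a 3-fold
cross-validated grid search (default grid n_estimators ∈ {5, 50, 100, 200,
300, 400, 500, 1000}, min_samples_leaf ∈ {1, 5, 10, 15}), ties broken
toward the smaller forest then the smaller leaf.

## Evaluation metrics

r (Pearson), r_s (Spearman), RMSE, RRMSE = 100·RMSE/mean(observed), and
R² defined as r² — the determination coefficient of the fitted linear
regression, which is the definition consistent with every reported (r, R²)
pair this package reproduces; the 1:1-line variant `1 − SSres/SStot` is
available behind a flag for sensitivity checks. LAI-level segmentation uses
strata {≤2, (2,5], >5}; groups with fewer than 3 samples report as
undefined. The rank analysis compares per-group means and their ranks and
reports the Spearman correlation of the mean vectors.

## Imaging pipeline

NDVI = (NIR−Red)/(NIR+Red) with zero-sum and nodata guards; vegetation iff
NDVI *strictly* exceeds the threshold (exact-threshold pixels stay
background, consistent with thresholds chosen to classify soil as
background); stage thresholds 0.5 (tillering), 0.65 (stem elongation),
0.75 (flag leaf). LCB correction replaces background pixels with the band
reflectance of the exact soil used to simulate the model's training set;
it touches only background pixels and is idempotent. Plots are trimmed 10 %
per side (on the minimum rotated rectangle, so rotated plots trim along
their own axes); zonal means use pixel-centre containment, appropriate for
cm-scale pixels against metre-scale plots. Rasters are float TIFFs with a
JSON sidecar for pixel size/origin/nodata; ×10 000 integer-scaled rasters
are auto-detected by value range and rescaled with a warning.

## Synthetic scenes and what they can show

`generate_scene` renders plot trials with known truth: within each plot a
seeded random subset of pixels (the cover fraction) takes the band
reflectance of the forward-simulated canopy at the plot's true LAI, the
rest take the soil reflectance; optional Gaussian band noise; binary pixels
by default (a mixed-pixel mode area-weights the endmembers instead).

Two deliberate simplifications matter for interpretation:

* **No within-canopy/within-plot heterogeneity**: every vegetation pixel of
  a plot is identical, so end-to-end recovery results (e.g. r ≥ 0.9 over 20
  plots) are upper bounds on real-scene performance.
* **No clumping in the regressor's world.** An area mixture of pure
  vegetation and *sunlit* soil pixels is not the same spectral object as
  the turbid-medium canopy with the same plot LAI (the turbid model shades
  its soil). Sparse binary-pixel scenes therefore sit off the training
  manifold and are predicted with a low bias by both methods. A direct
  consequence: with the background matching the training soil, perfect
  classification makes RFR+LCB *identical* to RFR (the correction rewrites
  background pixels with their current value), and with a mismatched
  background the raw method's error is confounded with the clumping bias,
  so a guaranteed error *reduction* from LCB cannot be demonstrated under
  this generator. What the suite demonstrates instead is the mechanism
  itself: LCB makes plot predictions nearly invariant (< 0.1 LAI shift) to
  swapping the local background between the training soil and a bright
  spectrally flat residue, while raw-aggregation predictions shift by
  ~0.6 LAI.

## Ground-reference methods

fIPAR = 1 − I_below/I_above, replicate-averaged; LAI = −ln(1−fIPAR)/K with
K = 0.65 for wheat by default; `fit_k` estimates K as the origin-constrained
least-squares slope of −ln(1−fIPAR) on LAI (deterministic, exact on
noiseless data; a direct nonlinear fit is available). Quadrat traits:
LAI = (LA_sub·DW_main)/(QA·DW_sub) — the cm²/cm² ratio is already the
dimensionless m² m⁻² LAI, no numeric conversion — Cw = (LFW−LDW)/LA and
Cm = LDW/LA in g cm⁻².

## Numerical choices

* Wavelength grid fixed at 400–2500 nm / 1 nm; inputs must be on it (band
  responses are the only resampled quantity).
* Vectorised batches process 2000 rows per chunk to bound peak memory.
* `Jfunc1` switches to its second-order series when |(k−m)·LAI| ≤ 1e-3;
  infinite-medium albedo and soil-coupling denominators are floored at
  1e-12 (reachable only for non-physical conservative leaves).
* Splits use floor(n·fraction) training rows from a seeded permutation.
* The soil optimizer and all forests run single-threaded by default for
  reproducibility.

## Problem sizes used by the test suite

Full 40,000-sample pipelines (as in the study) back the end-to-end metric
tests; supporting tests use scaled-down datasets (600–12,000 rows, 20–100
trees) chosen so each property is still decisively exercised. The replicate
stability check (two seeds differing by < 0.05 RMSE) runs at 12,000
samples.

## Known limitations

* Synthetic coefficient library: absolute band reflectances differ from
  simulations built on the published calibration data; the reproduced
  accuracy metrics come out slightly *better* (r ≈ 0.89 vs 0.84–0.86 for
  the broad set) because the synthetic leaf/soil contrast is somewhat
  cleaner. The qualitative structure — saturation above LAI ≈ 5,
  narrowed-range improvement, stratum behaviour — is preserved.
* No clumping/row-structure model, no thermal or fluorescence range, no
  atmospheric effects; radiometric calibration of imagery is assumed done
  upstream.
* Gaussian band responses stand in for the manufacturer's measured curves.
* A single field-level soil spectrum is assumed (no per-pixel soil maps).
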