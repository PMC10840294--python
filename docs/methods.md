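# Methods

This note documents the model behind `ricemap`, the choices made where the
method description left the design open, what the synthetic scenes do and do
not emulate, and the package's numerical conventions.

## Pipeline model

The classifier is a per-pixel matched filter applied independently at four
phenological stages and combined by conjunction.

1. **Stage assignment.** Acquisition dates map to stages through half-open
   day-of-year windows `[start, end)`; a boundary date belongs to the later
   stage, and dates outside all windows (fallow) are excluded. Defaults:
   sowing 60–110, transplanting 110–130, growing 130–230, maturity 230–270 —
   a single-season rice calendar for a subtropical hilly region.
2. **Compositing.** Per stage, the per-pixel arithmetic mean over valid
   (cloud-free, non-nodata) dates. SAR dB values are averaged in dB space,
   because stage-mean backscatter trajectories are conventionally reported in
   dB and the geometric averaging of ascending/descending passes damps
   terrain-induced intensity anomalies. Spectral indices are computed **after**
   compositing reflectance, so each stage yields exactly one feature image
   and one curve; a regression test pins this order (the alternatives differ
   for asymmetric values).
3. **Features.** 10 reflectance bands; NDVI, NDWI, NDREI, REP, MTCI and a
   soil/moisture NDSI (standard Sentinel-2 band definitions; the formula
   table is registry-based and extensible); VH and VV stage means; elevation
   and slope (Horn 3×3, replicated borders, NaN in a window propagates).
   Combined mode has 20 features; optical-only 18; SAR-only 4.
4. **Cloud mask.** A "simple cloud score" in [0, 1]: the minimum of rescaled
   brightness terms (blue; blue+green+red; NIR+SWIR1+SWIR2) and an inverted
   green/SWIR1 snow index. Pixels scoring strictly above 0.3 are masked. The
   breakpoints live in configuration; the defaults are the widely used ones
   for Sentinel-2 reflectance.
5. **Standard curve and SSV.** The curve y is the mean feature vector over
   rice training pixels of the stage composite. Each pixel x scores
   `SSV = CS(x, y) − d_norm(x, y)` with cosine similarity CS (clipped to
   [−1, 1] against rounding) and Euclidean distance d min–max-normalized over
   the stage's valid pixels.
6. **Thresholds and decision.** Per-stage threshold = mean of Q25(rice SSV)
   and Q75(non-rice SSV) at training points, quantiles by linear
   interpolation between order statistics (the numpy default; the convention
   is configurable). A pixel is rice iff all four stage SSVs meet their
   thresholds (inclusive ≥). Published reference thresholds
   (0.98, 0.985, 0.99, 0.985) are available as a bypass. Note the source's
   prose mentions 0.99 for the maturity stage while its printed rule uses
   0.985; the printed rule is taken as the default.
7. **Evaluation.** 2×2 confusion at validation points (rows predicted,
   rice first), UA/PA/OA and Cohen's kappa from the marginals; undefined
   ratios are reported as NaN. Display rounding is half-up to 2 decimals,
   computed from exact rational arithmetic so that ties such as 31/40 = 0.775
   round correctly. Patch analysis labels true-rice connected components
   (8-connected by default) and reports the recognized-pixel fraction per
   field-area bin; slope analysis reports the same fraction per slope
   interval (pixel-weighted; patch-weighted variants would differ only in
   how multi-bin patches are counted and are out of scope).

## Design choices on genuinely open points

* **Feature scaling before similarity** (default `minmax`, per feature, per
  stage, over valid pixels; the curve is transformed with the identical
  record). The feature vector mixes reflectance in [0, 1], backscatter in
  tens of dB, REP around 700 nm, elevation in hundreds of metres. Without
  scaling, the large-magnitude features dominate both CS and d: CS saturates
  near 1 for every pixel and the score degenerates to a terrain/REP distance.
  With min–max scaling all features contribute comparably. `none` is retained
  as a config option for sensitivity analysis. A consequence of scaling plus
  scene-wide distance normalization is that calibrated thresholds on the
  synthetic scenes (≈0.6–0.9) sit below the published 0.98-level values: the
  absolute SSV scale is scene-dependent by construction (see next point), and
  only the quartile *rule*, not the threshold values, transfers between
  scenes.
* **Scene dependence of SSV.** d_min and d_max are the extremes of the
  distance image, so adding or removing pixels changes every score. This
  follows the definition exactly and is documented rather than altered;
  consequently SSV values are comparable within one scene and stage only.
* **Quantile convention.** "25% quartile" is implemented as linear
  interpolation between order statistics (Hyndman–Fan type 7), the dominant
  default in scientific software; it is config-overridable.
* **Nodata.** Propagated, never imputed: a pixel missing any feature at a
  stage is invalid at that stage; a pixel invalid at any stage is nodata in
  the final map. Zero-norm vectors under cosine are nodata and logged.
* **No resampling.** All inputs must be pre-aligned on one grid; mismatches
  are errors. Point-in-pixel uses half-open pixel footprints, so boundary
  points are assigned deterministically.
* **Elevation as a feature.** The feature set includes raw elevation
  alongside slope as the two terrain features. Elevation is informative
  exactly when rice occupies a distinct elevation band (valley floors), and
  the synthetic landscape reproduces that structure; on landscapes where it
  does not hold, dropping elevation from the feature list (it is just a
  registry entry) is advisable.

## The synthetic scene

The generator produces the statistical structure the method assumes, not a
radiative-transfer simulation.

* **Landscape.** A DEM of two Gaussian hills (default amplitude 120 m) on a
  1% regional tilt; Voronoi background regions of water, built-up, natural
  vegetation and dry-land; ~30 rice paddies with log-uniform areas in
  200–3000 m² (right-skewed, like real field inventories). Placement is
  terrain-aware: each field targets a slope band that falls with its area
  and a valley-floor preference that sharpens with area — large consolidated
  fields on flat valley bottoms, small terraced fragments on steeper, higher
  ground, with no paddies above 12°.
* **Resolution effects.** Field geometry lives on a 2× supersampled grid, so
  sensor pixels are area-weighted class mixtures (the coarse truth label is
  the majority class; rice wins exact ties). A 3×3 PSF with half the weight
  on the centre pixel adds sensor blur. Together these are what make
  sub-400 m² fields genuinely hard at 10 m — the degradation is geometric,
  not an injected label error.
* **Signals.** Per class and stage, mean 10-band reflectance and VH/VV dB
  from an editable tabular asset whose rice row follows paddy phenology:
  flooded and dark with VH < −20 dB at transplanting, canopy closure with
  VH ≈ −15 dB and peak NIR/red-edge in growing, senescence afterwards.
  Confusers are built in: water matches rice in spring but never greens;
  dry-land cropland greens in summer but is bright bare soil in spring;
  evergreen vegetation is static with higher C-band backscatter than paddy;
  built-up is bright and stable. Independent Gaussian noise per pixel, date
  and band (defaults σ = 0.015 reflectance, σ = 1.2 dB SAR — the larger SAR
  value mimics residual speckle after multilooking; three dates per stage
  let compositing reduce it). Bright rectangular cloud blobs cover ~10% of
  each optical date and are detected by the package's own cloud score rather
  than ground-truth-masked.
* **Sampling.** Training and validation points are drawn uniformly without
  replacement within each class from one seeded permutation (front/back), so
  same-seed draws are disjoint. Default counts mirror a one-county field
  campaign: 75 rice + 288 non-rice training, 65 + 121 validation.
* **What passing tests show — and don't.** The default scene (256×256,
  seed 0) yields held-out OA ≈ 0.96, kappa ≈ 0.92, and monotone size
  degradation (0.17 / 0.68 / 0.90 for <400 / 400–800 / ≥800 m²). These are
  stochastic properties: across other seeds the OA/kappa floor (0.9 / 0.75)
  holds in roughly four of five runs and the three-bin ordering similarly —
  with ~30 fields the smallest bin contains only a handful of patches, so
  its fraction is high-variance. The tests pin the default conditions. None
  of this demonstrates performance on real imagery: real spectra have
  within-class covariance, phenological timing shifts between fields,
  SAR speckle is not Gaussian-independent, terraced geometry distorts
  backscatter, and cross-year compositing is not modelled. The published
  county-scale accuracies are therefore not reproduced here; what is
  reproduced is every metric computation from the published confusion
  counts, and the qualitative structure (sensor synergy direction,
  size/slope degradation) at desk scale.

## Numerical conventions and degenerate inputs

* Core computations in float64; raster storage float32 (file-based and
  in-memory runs can disagree on a <0.1% sliver of borderline pixels).
* Constant feature band under min–max scaling → 0 everywhere, flagged
  degenerate. Constant distance image → d_norm 0 everywhere. All-nodata
  images are errors.
* Cosine clipped to [−1, 1]; any NaN feature invalidates the pixel.
* A stage with zero acquisitions, zero usable rice training points, or a
  validation set with no usable points are hard errors naming the stage.
* Scene generation, sampling and the pipeline are deterministic given config
  and seed; two runs produce bit-identical rasters.

## Known limitations

* SSV scene dependence (above) means thresholds cannot be transported
  between scenes; only the calibration rule is portable.
* The quartile rule places the threshold between the class quartiles; when
  distributions overlap at a stage, up to a quarter of rice training pixels
  fall below threshold at that stage by construction.
* Patch-size analysis bins by the truth raster's connected components at
  sensor resolution; sub-pixel fields that never reach majority cover in any
  pixel are invisible to both truth and prediction.
* The CLI writes georeferencing as structured TIFF metadata produced and
  consumed by this package; GIS interoperability beyond that (CRS-aware
  reprojection, COG layout) is out of scope.
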