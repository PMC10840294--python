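# ricemap

Identification of paddy-rice fields in hilly terrain from multi-temporal
optical, SAR and terrain rasters, using phenological-stage compositing and a
spectral-similarity decision rule.

## The problem

Rice in hilly regions (e.g. the low mountains of southwest China) is grown in
small, fragmented, scattered paddies — over a third of fields can be under
2000 m². At the 10 m resolution of Sentinel-1/2, such fields are a few pixels,
heavily mixed with levees, terraces and neighbouring land cover, and optical
coverage is degraded by persistent cloud. Mapping them reliably requires
combining optical spectra, SAR backscatter and terrain, and exploiting the one
signature that separates paddy rice from everything else: its *phenological
trajectory* — flooded and dark in spring, a closed green canopy with rising
C-band backscatter in summer, senescing in autumn.

`ricemap` implements this method as a reusable library and CLI for
agricultural remote-sensing practitioners, and ships a synthetic-scene
generator so the whole pipeline is testable end to end without any satellite
download.

## The method

For each of four phenological stages *s* (sowing, transplanting, growing,
maturity, defined as day-of-year windows of a crop calendar), all acquisitions
assigned to the stage are cloud-masked and mean-composited into one
multi-band feature image: 10 surface-reflectance bands, 6 spectral indices
(NDVI, NDWI, NDREI, REP, MTCI, NDSI), stage-mean VH/VV backscatter (dB), and
elevation and slope (Horn's method) — 20 features in combined mode.

A **rice standard feature curve** y is the mean feature vector over rice
training pixels. Every pixel x is scored against y with the **spectral
similarity vector**:

    d(x, y)      = sqrt( Σᵢ (xᵢ − yᵢ)² )
    d_norm(x, y) = (d − d_min) / (d_max − d_min)        over the stage's image
    CS(x, y)     = Σᵢ xᵢyᵢ / (‖x‖ ‖y‖)
    SSV(x, y)    = CS(x, y) − d_norm(x, y)

Per-stage thresholds t_s are calibrated by the quartile rule — the mean of the
25th percentile of rice-sample SSVs and the 75th percentile of non-rice-sample
SSVs — or the published defaults (0.98, 0.985, 0.99, 0.985) can be used. The
decision rule is a four-stage conjunction:

    rice  ⇔  SSV_sowing ≥ t₁ ∧ SSV_transplanting ≥ t₂ ∧ SSV_growing ≥ t₃ ∧ SSV_maturity ≥ t₄

Accuracy is assessed with user/producer accuracy, overall accuracy and
Cohen's kappa against validation points, plus recognition analyses by field
size (connected components) and by slope interval.

## Worked example

```python
from ricemap import *
from ricemap.simulate import (SceneConfig, generate_scene, sample_points,
                              DEFAULT_TRAINING_COUNTS, DEFAULT_VALIDATION_COUNTS)
from ricemap.pipeline import identify_rice

scene = generate_scene(SceneConfig(seed=0))          # 256x256 @ 10 m, ~30 paddies
train = sample_points(scene, DEFAULT_TRAINING_COUNTS, "training", seed=0)
val = sample_points(scene, DEFAULT_VALIDATION_COUNTS, "validation", seed=0,
                    training_counts=DEFAULT_TRAINING_COUNTS)

result = identify_rice(scene.optical, scene.sar, scene.dem,
                       scene.config.calendar, train)
print("calibrated thresholds:", {s: round(t, 3) for s, t in
      zip(("sowing", "transplanting", "growing", "maturity"),
          result.thresholds.as_tuple())})
report = metrics(confusion(result.rice_map, val))
print("held-out accuracy:", report.rounded())
by_size = patch_recognition_by_size(scene.rice_mask, result.rice_map)
for bin_name, stats in by_size.items():
    print(f"  {bin_name}: {stats['proportion']:.2f} recognized "
          f"({stats['patches']} fields)")
```

prints

```
calibrated thresholds: {'sowing': 0.586, 'transplanting': 0.611, 'growing': 0.91, 'maturity': 0.813}
held-out accuracy: {'ua_rice': 1.0, 'pa_rice': 0.89, 'ua_nonrice': 0.95, 'pa_nonrice': 1.0, 'oa': 0.96, 'kappa': 0.92}
  [0, 400) m2: 0.17 recognized (2 fields)
  [400, 800) m2: 0.68 recognized (4 fields)
  >= 800 m2: 0.90 recognized (24 fields)
```

Reading the output: the quartile-calibrated thresholds split rice from
non-rice SSV distributions per stage (they sit well below the published 0.98+
defaults because min–max feature scaling spreads this scene's SSV histogram;
see `docs/methods.md`). Held-out overall accuracy is 0.96 with kappa 0.92, and
recognition degrades from 90% of pixels in fields ≥ 800 m² to 17% in sub-400 m²
fragments — the characteristic resolution limit for fragmented paddies at
10 m.

The same run from a shell:

```bash
ricemap simulate --seed 0 --out-dir scene/          # writes stacks + config.yaml
ricemap run --config scene/config.yaml              # full pipeline + report
ricemap evaluate --pred scene/results/rice_map.tif \
    --samples scene/samples_val.csv --truth scene/truth.tif --out eval.json
```

Subcommands `composite`, `features`, `curves`, `ssv`, `classify` expose the
individual pipeline stages on GeoTIFF inputs.

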