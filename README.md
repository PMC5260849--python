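# forestcloud

Tools for quantifying **cloud-cover enhancement over temperate forests**
from geostationary satellite imagery — built around a fully synthetic,
ground-truthed test bed so that every stage of the analysis can be
validated without downloading a decade of satellite data.

Large lowland forests (the Landes and Sologne regions of France are the
archetypes) heat and moisten the boundary layer differently from the
surrounding cropland. The observable consequence is a higher daytime
cloud frequency over the forest in summer, strongest at the downwind
forest edge (a forest-breeze circulation), and it can vanish abruptly
when a windstorm flattens the forest. This package implements the
observational analysis chain for that phenomenon:

1. **`synthetic`** — generates 15-min, 10-bit digital-count image stacks
   over a categorical forest/non-forest landscape with *known* clear-sky
   levels, Bernoulli cloud occurrence (with a configurable JJA forest
   enhancement of order 0.05–0.15), wind-driven downwind displacement of
   the enhancement, and an optional storm-damage breakpoint.
2. **`detect`** — the empirical broadband-visible cloud detector: a
   per-pixel clear-sky climatology over (10-day period, UTC hour) bins,
   estimated as the steepest section of the count ECDF, then cloud
   flagging where a count exceeds the climatology by a constant
   threshold (10 counts).
3. **`frequency`** — cloud-frequency maps (fraction of valid daylight
   slots flagged cloudy, 06–18 UTC) and daily/dekadal/diurnal box series.
4. **`boxstats`** — Welch t-tests between forest and non-forest boxes and
   day-resampling bootstrap 50%/95% percentile intervals with
   significance shading of the difference.
5. **`wind`** — day classification by regional meridional 10-m wind and
   per-class composites with 90th-percentile exceedance contours.
6. **`seasonal`** — the squared-sine-with-trend model
   `d(t) = c + b·t + A·sin²(π(t − φ))` (period 1 year) fitted to dekadal
   forest-minus-non-forest difference series, with an amplitude
   breakpoint at a storm date.

## Worked example

```python
import forestcloud as fc

lc = fc.demo_landcover(120, 120)            # 110x110 km forest block + boxes
cfg = fc.SimConfig(years=2, seed=11)        # 30% base cloudiness, +0.10 JJA over forest
truth = fc.simulate_truth(lc, cfg)
counts = fc.render_counts(truth)            # 10-bit counts, boost 50, noise 2

clim = fc.build_clearsky_climatology(counts, window_w=3, min_samples=20)
masks = fc.detect_clouds(counts, clim, threshold=10)

fmap = fc.frequency_map(masks, season=(6, 7, 8))
d = fmap.box_mean(lc.boxes["forest"]) - fmap.box_mean(lc.boxes["nonforest_1"])
res = fc.ttest_two_boxes(
    fc.box_daily_series(masks, lc.boxes["forest"], season=(6, 7, 8)),
    fc.box_daily_series(masks, lc.boxes["nonforest_1"], season=(6, 7, 8)),
)
print(f"JJA forest-minus-nonforest frequency difference: {d:.3f}")
print(f"Welch t = {res.t:.1f}, p = {res.p:.2e}  (n = {res.n_a} days)")
```

prints

```
JJA forest-minus-nonforest frequency difference: 0.069
Welch t = 99.9, p = 4.36e-256  (n = 184 days)
```

The detected contrast (0.069) sits below the configured 0.10 because a
few percent of the strongly enhanced forest (dekad, hour) bins lock
onto the cloudy count mode of the distribution, suppressing detections
there; computed on the generator's truth masks the box difference
recovers 0.100 to within binomial error. See `docs/methods.md`.

The same chain is available from a shell:

```bash
forestcloud simulate --out scene/ --seed 11 --grid 120 120
forestcloud climatology --in scene/scene.nc --out clim.nc --window 3
forestcloud detect --in scene/scene.nc --clim clim.nc --threshold 10 --out mask.nc
forestcloud frequency --mask mask.nc --season JJA --out freq.nc
forestcloud run --out demo/ --seed 11          # everything, plus a manifest
```

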