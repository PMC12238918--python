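# oligotrend

Analysis toolkit linking catchment-scale vegetation greening to the
long-term nutrient decline (oligotrophication) of mountain lakes.  The
pipeline covers:

- **watershed** — depression filling (priority-flood, epsilon-free), D8
  flow directions, flow accumulation, outlet snapping, upstream catchment
  delineation, and catchment/lake/drainage areas from a DEM;
- **ndvi** — annual NDVI_max extraction from dated scene stacks, with the
  before-07:00 scene filter and the > 0.2 snow screen; pixel-max-then-mean
  for drainage areas, footprint-mean-then-max for plots;
- **calib** — plot harvests to areal nutrient densities
  (1 g·m⁻² ≡ 1 ton·km⁻²), QC filtering, and the ordinary least-squares
  NDVI_max → density calibration;
- **sequester** — annual per-lake sequestration series, two-period
  contrasts (Welch t-test), cross-lake summaries, and region upscaling
  (mean per-lake density difference × ecoregion area);
- **trends** — annual means, Mann–Kendall with tie correction and an
  exact-permutation oracle, Sen's slope, the inclusive-year percent
  decline convention, and a penalized-spline smooth with per-lake random
  intercepts fitted by backfitting;
- **coverage** — ratio-form Horvitz–Thompson cover estimation from
  unequal-probability survey plots and centered moving averages;
- **synth** — a seeded generator for DEMs with closed lake depressions,
  greening NDVI scene stacks, vegetation plot harvests, lake chemistry,
  and rotating-panel cover surveys, with every planted truth recoverable
  by the downstream stages.

Rasters travel as ESRI ASCII grids, tables as CSV, and fits as JSON, so
the whole pipeline is plain-text.

## CLI

Every stage is a subcommand of `oligotrend`:

```sh
# generate a synthetic bundle (DEM, masks, scenes summary, plots, chemistry, survey)
oligotrend synth --seed 1 --out-dir out/

# delineate catchments for outlet coordinates on any DEM
oligotrend delineate out/dem.asc outlets.csv --snap-radius 250 --out-dir out/catchments

# annual NDVI_max from a scene manifest over a mask
oligotrend ndvi manifest.csv mask.asc --mode catchment --out ndvimax.csv

# calibration, sequestration, trends, coverage
oligotrend calibrate out/veg_plots.csv --nutrient P --out fitP.json
oligotrend sequester out/annual_ndvimax.csv fitP.json out/lakes.csv --out-dir out/seq
oligotrend trends out/chem.csv --response total_p --out trends.csv
oligotrend coverage out/cover_survey.csv --out cover.csv
```

## Layout

```
src/oligotrend/      raster, watershed, ndvi, calib, sequester,
                     trends, coverage, synth, datasets, cli
tests/               unit + property tests per module, tests/test_acceptance.py
scripts/acceptance.py
```
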