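# pestload

Geospatial assessment of non-occupational pesticide exposure for populations
living near treated cropland. The package estimates where herbicide use is
rising and who lives close enough to be affected, using only public-style
inputs: state pesticide-use surveys, county crop-area tables, a categorical
crop-cover raster, and a gridded population count.

It was built around a case study of 2,4-D (2,4-dichlorophenoxyacetic acid)
applied to soybeans in Illinois over 2017–2023, whose published state and
county tables ship with the package, but every stage is generic over crop,
chemical, and region.

## The model

**Application density** (state level, per year):
`D_P = Σ F_i / A_T` — total mass of active ingredient (kg) over planted crop
area (km²), giving kg/km².

**County load** (temporal trend analysis):
`W_C = A_C × D_P` — county crop area times the state density. Trends are
per-county percent changes `100·(W_end − W_start)/W_start`, summarised across
counties by median/mean/min/max; counties with under 40.5 km² (10,000 acres)
planted are flagged as small-area. Counties are also screened bivariately —
population density versus pesticide density, tercile classes on each axis —
to find "counties of concern" (top class on both).

**Buffer exposure** (receptor level): each populated 1000 m population-grid
cell is a receptor at its cell center with a 1 km circular buffer (a 250 m
population core plus a 750 m donut). The crop area `A_B` inside the buffer
gives the buffer load `W_B = A_B × D_P`, and receptors are classified by
inclusive thresholds: proximity (≥ 0.04 km² of crop in the buffer), a dust
threshold (≥ 4.4 kg, the level associated with large increases in indoor-dust
residue concentrations), and a 30 kg reference level. Summing population over
flagged cells yields the exposed fraction of the total population.

## Worked example

```python
from pestload.datasets import state_densities, county_trend_records
from pestload.trends import trend_summary

for year, d in sorted(state_densities().items()):
    print(year, d.rounded(2))
s = trend_summary(county_trend_records())
print(round(s.median_pct, 1), round(s.min_pct, 1), round(s.max_pct, 1), s.n_counties)
```

prints

```
2017 11.25
2020 23.68
2023 50.41
341.4 301.9 711.7 102
```

i.e. the statewide application density rose from 11.25 to 50.41 kg/km² over
six years, and across the 102 counties the load increase had median 341%,
ranging from a 302% to a 712% rise.

The full pipeline runs from the shell. Generate a synthetic landscape (a
clustered 30 m crop raster, a 1000 m population grid with urban hotspots,
county polygons and use tables) and analyse it:

```sh
pestload simulate --seed 7 --out demo --extent-km 9 --population 20000
pestload run --use-csv demo/use.csv --state-area-csv demo/state_area.csv \
    --county-area-csv demo/county_area.csv --crop-geotiff demo/crop.tif \
    --population-geotiff demo/population.tif --counties-geojson demo/counties.geojson \
    --years 2017 --years 2020 --years 2023 --out demo/out
```

`demo/out/summary.json` then holds the per-year densities, the county trend
summary, the concern counties, and per-year exposed populations and
fractions under each threshold rule; per-receptor details are in
`exposure_cells_<year>.csv`.

Real inputs use the same commands: any single-band GeoTIFF crop and
population rasters in a shared projected meter coordinate frame, plus a
GeoJSON FeatureCollection of county polygons with a `county_id` property.

## Layout

- `pestload.units` — area units, `D_P`
- `pestload.trends` — county loads, percent changes, raster-fallback areas
- `pestload.bivariate` — quantile classification, counties of concern
- `pestload.exposure` — buffer crop area, `W_B`, thresholds, summaries
- `pestload.synthetic` — landscape generator
- `pestload.io`, `pestload.config`, `pestload.pipeline`, `pestload.cli` —
  formats, configuration, driver, command line
- `pestload.datasets` — the bundled case-study tables

See `docs/methods.md` for modelling assumptions, parameter defaults, and
known limitations.
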