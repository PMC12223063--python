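# Methods

## Model and assumptions

The package treats pesticide exposure potential as a proximity problem: a
chemical applied at a known statewide intensity is attributed to people by
how much treated crop lies near where they live.

1. **Application density.** `D_P = Σ F_i / A_T` (kg of active ingredient per
   km² of planted crop, per year). All reported formulations are summed with
   no potency weighting — inputs are already expressed as mass of active
   ingredient. Assigning one statewide density assumes applications are
   evenly spread over the crop area; this is the standard simplification
   when field-level application records do not exist.

2. **County loads and trends.** `W_C = A_C × D_P` allocates the state total
   to counties by planted area. Percent changes between a start and end year
   are `100·(end − start)/start`; a zero baseline makes the change undefined
   (flagged, not infinite — real survey baselines are positive but synthetic
   ones may not be). Summary statistics run over counties with defined
   changes; the small-area flag (end-year area < 40.5 km², i.e. 10,000
   acres) marks counties whose percentages rest on little land but does not
   exclude them. Because percent changes are ratios, they are invariant to
   the acre→km² constant; absolute kg values are not, so the package uses
   the exact international acre (0.0040468564224 km²) throughout and accepts
   ≤ 0.05 % discrepancy against tables produced with truncated constants.

3. **Bivariate screening.** Counties are classed 1–3 on population density
   and on pesticide density by empirical terciles (linear interpolation of
   order statistics; a value equal to a break takes the lower class);
   "concern" is the (3, 3) cell. Tercile breaks are the conventional default
   for bivariate choropleths; the class count and break method
   (`quantile` / `equal_interval` / `custom`) are configurable because other
   published maps use other schemes. Rank-based breaks make the screen
   invariant to monotone rescaling of either axis.

4. **Buffer exposure.** Each populated 1000 m population cell is a receptor
   at its cell center. The nominal construction — a 250 m core around the
   population center plus a 750 m donut — is implemented as the single
   1 km-radius disc it equals geometrically; both radii are retained in
   `BufferSpec` for documentation and the total radius is configurable. Crop
   area inside the buffer uses cell-center membership (a crop cell counts
   iff its center is within the radius, inclusive): deterministic, exactly
   reproducible by a brute-force per-cell oracle, and accurate to <1 % of the
   disc area at 30 m cells. Buffers of neighbouring receptors overlap and
   crop area is deliberately counted once per receptor — each buffer is an
   independent assessment of one receptor's surroundings, so no
   area-conservation correction is applied. Threshold comparisons are
   inclusive (≥) for all three rules, extending the "at least" reading of
   the proximity rule to the mass thresholds for consistency.

All geometry is planar Euclidean in meters; inputs must share one projected
coordinate system. No geodesic corrections are made — at county scale the
error is far below the discretization error. Population rasters carry counts
rather than densities, so no pixel-area distortion correction is needed.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| buffer total radius | 1000 | m | encloses the full 1000 m population cell from its center; the distance scale at which nearby cropland measurably raises indoor residue levels |
| proximity threshold | 0.04 | km² | 10 acres of crop within the buffer — a minimal "lives near fields" criterion |
| dust threshold | 4.4 | kg per buffer | literature level associated with >100 % increases in indoor-dust residue concentration |
| reference level | 30.0 | kg per buffer | the study period's initial maximum buffer load, used as a fixed severity benchmark |
| small-area cutoff | 40.5 | km² | 10,000 acres planted; marks counties where percent changes rest on little land |
| coarse-raster warning | 100 | m | above this crop cell size, buffer areas become lumpy relative to a 1 km radius |
| bivariate classes | 3 | — | tercile bivariate-map convention |

## Synthetic landscapes

The generator emulates the structure of the real inputs, not their content:

* **Crop raster** — binary 30 m grid grown from random seed cells by
  4-neighbour accretion (a cell joins with probability proportional to its
  crop-neighbour count), stopping exactly at the target cell count. This
  yields contiguous pseudo-fields with realistic clumping; it does not
  emulate road grids, field rotation, or the 100+ categories of a real
  cropland data layer.
* **Population grid** — a uniform rural floor (weight 0.05) plus
  exponential-decay hotspot kernels (default scale 3 km), scaled to the
  requested total and rounded by largest remainder so the integer counts sum
  exactly. Real gridded census products have block-level allocation
  artefacts this does not reproduce.
* **Counties** — an exact rectangular tiling; real county shapes are
  irregular but the analysis only uses containment and area.
* **Use tables** — geometric growth. Defaults follow the observed
  case-study conditions: a ~2600 km² county-scale landscape (51 km side),
  crop fraction 0.40, population 206,500 in two urban hotspots, and a use
  trajectory growing 27.9 %/yr (the six-year 4.4-fold statewide increase),
  anchored so the start-year density is ≈ 11.25 kg/km².

Determinism: each artifact draws from its own RNG sub-stream
(`crop=0, population=1, counties=2, use=3`) derived from the spec seed, so
identical specs give bit-identical outputs and adding artifacts never
perturbs existing ones.

Passing tests on these landscapes demonstrate the pipeline's arithmetic,
geometry, and bookkeeping — not the realism of any particular exposure
estimate. The real case-study receptor percentages depend on proprietary-
resolution census and crop-cover rasters and can only be reproduced by
feeding those through the documented GeoTIFF/GeoJSON adapters.

## Numerical choices

* Full floating precision end to end; rounding only at presentation
  boundaries (densities 2 dp, percents 1 dp) and in separate output columns.
* Median of an even count is the midpoint of the two central order
  statistics; quantile breaks use linear interpolation; ties at a class
  break take the lower class.
* Undefined percent changes (zero baselines) propagate as NaN internally,
  are excluded from summaries, and serialize as `null`.
* Cell-center membership everywhere (disc and polygon extraction): no
  fractional cells, so results are integers times the cell area and
  brute-force oracles can require exact equality.
* GeoTIFF nodata in population rasters becomes zero population with a
  logged count; disjoint raster/polygon extents return zero area with a
  warning rather than raising.

## Problem sizes

The test suite runs on 6–15 km landscapes (tens of receptors, ≤ 500×500
crop cells) chosen so the full suite completes in seconds; the acceptance
script uses a 24 km landscape (576 receptors over 640,000 crop cells),
20 random rasters × 25 centers for oracle agreement, and a 90,000-cell
all-crop raster for the analytic disc limit. These sizes are the package's
verification defaults; all scale linearly if enlarged.

## Known limitations

* Uniform within-state application density ignores county-level variation
  in application practice and timing.
* Proximity-based load is a potential-exposure index, not a dose: no wind,
  drift physics, volatilization, or indoor/outdoor transfer modelling.
* Cell-center crop extraction under-counts partially covered boundary cells
  for small polygons (bias bounded by the perimeter-cell fraction).
* The bivariate screen's class memberships depend on the break scheme when
  many counties tie near a break.
* The published county kg table carries its own rounding (1 dp) and an
  unstated acre-conversion constant; absolute kg comparisons against it are
  only meaningful to ~0.05 %.
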