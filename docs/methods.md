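# Methods

## The disaggregation model

The package produces 1 km daily maximum air temperature by imposing the
spatial departures of a seasonal satellite LST composite onto a coarse
(~12 km) gridded daily maximum:

```
T_DIS = T_L + R · (T_H − T_H,mean)            (constant-ratio form)
T_DIS = T_L + Z · σ_L,  Z = (T_H − T_H,mean)/σ_H   (standardized form)
```

The physical premise is that under quiescent warm-season conditions
(weak synoptic flow, no frontal passages) near-surface air temperature is
driven by surface sensible heat flux, so its spatial pattern mimics the
LST pattern at reduced amplitude. Daily maxima occur in the early-to-mid
afternoon, near the ~13:30 local-standard-time overpass of the afternoon
polar orbiter that supplies the LST, so a daytime LST composite is the
right template for the daily *maximum*. The model does not move heat: it
redistributes each coarse cell's value across its fine pixels according to
a fixed seasonal pattern. It therefore cannot represent temperature
advection, and a single global `R` is a compromise that underperforms
where true variability ratios are extreme (sharp coastlines, large
within-cell elevation ranges).

### Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `r_ratio` (R) | 0.50 | – | σ_L/σ_H proxy for daily maxima; <1 because air varies less than skin temperature |
| `mode` | `constant_ratio` | – | operational form; `sigma_ratio` uses an explicit per-cell σ_L/σ_H |
| `neighborhood_cells` | 1 | coarse cells | window for σ_L in `sigma_ratio` mode; 1 cell keeps the scheme conservative |
| `min_valid_pixels` | 3 | fine pixels | below this a cell's departures fall back to zero (downscaled = coarse) |
| LST scale / fill | 0.02 / 0 | K per count | scaled-integer scene decoding; raw 0 (0 K) is the fill value |

The constant-ratio form with a single-cell neighborhood is the default
because (a) σ_L estimated over wider neighborhoods is unstable across
strong climatological gradients and (b) any neighborhood wider than one
cell breaks conservation of the coarse field. With zero-mean-per-cell
departures and a single-cell `T_L`, the unweighted mean of `T_DIS` over a
fully valid coarse cell equals `T_L` exactly — asserted to 1e-9 °C in the
tests. `estimate_sigma_ratio` retains the neighborhood machinery as a
diagnostic: it maps σ_L (coarse values over a window of cells, ≥3 wide)
against σ_H (fine composite pixels over the same window) and reports the
domain median, supporting a future spatially varying R. Note an inherent
discretization bias: σ_L is computed from a handful of cell-center values
while σ_H samples the window quasi-continuously, so even a perfectly
coupled world (coarse = scaled block mean of fine) recovers ~0.46–0.48 for
a true 0.5 with a 3×3 window. The estimator is a diagnostic, not a
calibration target.

## Robust compositing

Scenes are 8-day clear-sky LST composites; a warm season (May–September)
supplies ~19 of them. Per pixel, with `n` valid (non-fill) values, the
composite is the mean of the top `ceil(n/2)` sorted values. Rationale:
cloud gaps are fills, and partial cloud contamination produces
erroneously *low* retrievals, so averaging only the upper half tracks the
clear-sky level. `ceil` (rather than `floor`) for odd `n` biases toward
clear-sky values, consistent with that purpose; the odd case is otherwise
a free choice. Consequences worth knowing:

- the composite is never below the pixel's median;
- an injected value below the median leaves the composite exactly
  unchanged when `n` is odd; when `n` is even the upper half widens by one
  *genuine* value (an erroneously low outlier — below the minimum — never
  enters), and the composite may shift slightly toward the median;
- "non-zero" means the raw fill value 0 in scaled-Kelvin units (0 K is
  impossible), not 0 °C; quality-control flags are deliberately not used.

Departures re-center the composite within each coarse cell using only the
cell's *valid* pixels, which guarantees the zero-mean invariant under any
missingness; `σ_H` uses the population (n) denominator because the cell's
pixels enumerate its area rather than sample it. Cells with fewer than
`min_valid_pixels` valid pixels fall back to zero departure and are
QC-flagged, so the downscaled product degrades gracefully to the coarse
product instead of amplifying noise.

## Daily extrema and time

The coarse daily maximum is the max over the 24 hourly values of each
pixel's local-standard-time calendar day (midnight to midnight). The
local offset is `round(lon/15)` hours, ties away from zero — deterministic
and database-free; it can differ from civil standard time by up to an
hour, which shifts the 24 h window but rarely the daily max. A pixel-day
with any missing hour is invalidated outright rather than computing a
partial maximum, which would bias cold. Forcing interpolated from
3-hourly analyses carries a slight cold bias in daily maxima (peaks
between samples are missed); a test asserts that direction.

## Grids, extraction, I/O

All rasters are regular lat/lon with pixel-center registration, row 0 at
the north edge, and half-open pixel boxes `[west, east) × (south, north]`,
which resolves every boundary tie deterministically (points on shared
edges belong to the eastern/southern pixel). Fine pixels are assigned to
the coarse cell containing their *center*; station values are extracted by
containment, not interpolation, because gridded estimates are compared to
stations directly. GeoTIFF I/O writes the two standard georeferencing
tags (ModelPixelScale, ModelTiepoint); NetCDF I/O is CF-style lat/lon via
the NetCDF3-classic engine. Reprojection (e.g. from the sinusoidal
satellite grid) is assumed done upstream; only geographic grids are in
scope.

## Synthetic worlds

The generator builds the structure the method assumes, so every stage and
invariant is testable without downloads:

- a static anomaly field `a` (Gaussian urban bumps, optional coastal
  step), re-centered to zero mean per coarse cell — the conservation
  premise holds exactly by construction;
- coarse daily maxima = 30 °C base + a 2 °C regional gradient + seeded
  day-to-day weather (sd 3 °C), delivered as an hourly cube whose cosine
  diurnal cycle (range 8 °C) peaks at 14:00 local so the sampled daily max
  equals the intended peak exactly;
- fine truth = upsampled coarse peak + `r_true · a` with `r_true = 0.5`,
  mirroring the operational R so that correctly specified downscaling can
  recover truth exactly in the noise-free limit;
- LST scenes = 45 °C base + `a` + Gaussian noise (sd 0.5 °C), with blocky
  rectangular cloud masks (30 % area, stressing per-cell fallbacks in a
  spatially correlated way) and ~1 % cold-contaminated pixels (−15 °C) to
  exercise the upper-half rule; 19 scenes per season;
- stations at seeded random fine-pixel centers observing the fine truth
  with 0.5 °C noise; the default calendar is June–August of three years
  (276 days per station).

All randomness flows from the single recipe seed. What the synthetic
world does *not* contain: advection, elevation/lapse-rate structure,
day-to-day changes in the anomaly pattern, spatially correlated weather
noise, or seasonal phenology. Passing tests therefore demonstrate the
algorithm's internal correctness and its behaviour under cloud/noise
degradation — not skill on real atmospheres.

## Numerical choices

- Compositing sorts per pixel with NaN-last ordering and takes the top-k
  partial sum via a cumulative sum — O(n log n) per pixel, no Python
  loops.
- Zero `σ_H` (uniform cell) gives `Z = 0`/no adjustment, flagged rather
  than erroring; zero-overlap grid pairs warn and return an empty map.
- Equation identities (the two model forms) agree to ≤1e-9 °C; linearity
  in R holds to one rounding of the final add; the R = 0 path is
  bit-exact upsampling.
- Report rounding is 2 decimals, half away from zero, matching how such
  validation tables are printed; the sign convention is estimate minus
  observation (negative = grid runs cold).
- Problem sizes in tests and the acceptance script (96×96 fine / 8×8
  coarse, 5–10 day windows for field comparisons, the full 276-day
  calendar for station validation) were chosen as the smallest worlds that
  exhibit every regime — multiple cells, partial clouds, under-populated
  cells — while keeping the suite interactive.

## Known limitations

- One seasonal departure pattern per year: real intra-seasonal changes in
  the urban/rural contrast (rainfall, phenology) are smoothed away.
- Constant R: coastal and mountainous areas want larger, spatially
  varying ratios; the sigma-ratio machinery is exposed but not default.
- Longitude-derived time zones; civil DST boundaries are ignored.
- Minimum temperatures pass through the same pipeline (the extrema stage
  computes them), but no nighttime-specific compositing logic is claimed.
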