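# Methods

This document describes the models implemented in `pahlur`, their
parameters and defaults, the numerical choices that affect results, and
the known limitations of the synthetic data generator.  All statements
here describe the implementation; no empirical performance figures are
claimed beyond what the test suite and `scripts/acceptance.py` compute.

## 1. Synthetic world and concentration generation

`pahlur.world.generate_world` builds, from a single seeded
`numpy.random.Generator` stream, a rectangular study region containing:

- a study **boundary** polygon with an urbanized core;
- a Voronoi **land-cover** and **land-use** mosaic (artificial,
  agricultural, natural, and water classes);
- **road** polylines of several thematic classes with denser networks
  near the core;
- industrial **point sources** clustered in and around the core;
- a smooth **elevation** raster (ESRI ASCII grid) with a northward
  ramp;
- a handful of **meteorological stations** carrying seasonal variables;
- a **monitoring network** of urban, rural, and background sites.

The same scenario seed always regenerates every layer bit-identically.

`pahlur.concentrations.generate_concentrations` draws, for each species
× season, per-site **total** concentrations from a known *true model*:
a linear equation in selected covariates plus i.i.d. Gaussian noise,
floored at zero.  Intercepts can be *calibrated* so that a configured
phase mean is hit in expectation.  The RNG stream used for
concentration noise is derived from the scenario seed via
`default_rng([seed, 1])` and is therefore independent of the
world-generation stream: regenerating the world does not perturb the
noise draws and vice versa.

### Gas–particle partition

Each total is split into gaseous and particle-bound parts by a logistic
particle fraction

φ = logistic( α·(log K_ow − κ) + β·(T_ref − T_season) )

with defaults α = 1.5, κ = 5.5 (log K_ow of the 50/50 split at the
reference temperature), β = 0.15 /°C, T_ref = 15 °C.  Heavier compounds
and colder seasons shift mass to the particle phase.  **Mass is
conserved exactly**: the implementation computes
`gaseous = total − φ·total` and then `particle = total − gaseous`, so
the two parts sum to the total bit-for-bit in floating point (a naive
`(φ·total, (1−φ)·total)` split does not).

Each phase record is marked *detected* when its value reaches the true
model's detection limit; a per-species, per-season switch can
additionally force gaseous non-detectability (used to emulate heavy
species that are never observed in the gas phase in cold seasons).

## 2. Covariate extraction

Predictor codes combine a variable family, a buffer radius in metres,
and a thematic class, e.g. `lc3000_20` (land-cover class 20 area within
3000 m), `r1000_51` (class-51 road length within 1000 m), `lu5000_5`,
plus unbuffered site variables `dem`, `long`, `lat`, `dis`
(distance to nearest major road), `point` (point sources within a fixed
radius), `w{r}` (water area, an alias for land-cover class 60), and
interpolated meteorology.

Numerical and geometric choices:

- **Union before intersection.** Area and length statistics intersect
  the buffer disc with the *union* of the features of the class, so
  overlapping features are never double-counted.
- Buffer discs are shapely's default 8-segments-per-quadrant polygonal
  approximation of a circle; tests tolerate the resulting
  sub-half-percent area deficit explicitly.
- **Boundary-inclusive counts**: a point source exactly at the buffer
  radius is counted.
- Raster lookups use the cell containing the point, with points on the
  far edge of the extent clamped to the last cell; points outside the
  extent are an error, not NODATA.
- Meteorological variables are interpolated by inverse-distance
  weighting and require at least three stations unless the variable is
  constant across stations (then the constant is returned).
- Invalid geometries (e.g. self-intersecting rings) raise
  `GeometryError` naming the site and predictor; extraction errors
  across a table are aggregated as `"{site}/{code}: message"` so one
  run reports every failure.

The covariate table is indexed by (site, season) and keeps columns in
registry order, so downstream artifacts are deterministic.

## 3. Model development (supervised forward selection)

For one stratum (species × season × phase) with response vector *y*
(the package itself does not transform *y*; callers choose the scale)
and covariate matrix *X*:

1. **Screening.** Each registered column is fit alone (closed-form
   simple regression).  Columns that are constant, or that become
   constant when any single observation is removed (the
   *leave-one-out-stability* rule: at least two values must differ from
   the most frequent one), are excluded — a near-indicator observed at
   one site cannot be cross-validated and carries no generalizable
   signal.  Candidates whose slope violates the predictor's a-priori
   sign are marked ineligible.
2. **Forward selection.** Starting from the intercept-only model, the
   eligible candidate giving the largest adjusted-R² gain is added if
   the gain is at least `gain_threshold` (default 0.01, absolute; a
   relative mode is available), its entering slope has the permitted
   sign, and no already-entered slope flips sign.  Ties in fit are
   broken lexicographically by code, so selection is deterministic.
3. **Backward pruning.** Predictors with p ≥ α (default 0.05) are
   removed, largest p first, refitting after each removal.
4. **Sign-flip removal.** Refitting after a removal can push a
   surviving slope outside its permitted direction; such predictors are
   removed (worst p first).  Steps 3–4 are iterated to a fixed point.
5. **Collinearity filter.** While any variance inflation factor is ≥
   `vif_threshold` (default 5), the worst offender is removed and steps
   3–4 re-run.

Every decision — additions, gain rejections, sign rejections, p-value
removals, sign-flip removals, VIF removals — is recorded as a
`TraceStep`, and `replay_trace` reproduces the final structure from the
trace alone.

**Diagnostics never change the model.** Cook's distance (threshold 1,
flags reported) and Moran's I of the residuals (inverse-distance
weights, permutation p-value, default 9999 permutations in the library
and 999 in the pipeline) are attached to the result for inspection
only.  If an observation has leverage 1, the closed-form Cook's
distance is undefined; the implementation reports `inf` for that
observation instead of aborting the stratum.

## 4. Validation

- **LOOCV.** Leave-one-out cross-validation of a *fixed* structure
  refits the coefficients in each fold (optionally the full selection
  can be re-run per fold with `reselect=True`).  Reported: per-site
  held-out predictions, RMSE, and Pearson r between held-out
  predictions and observations; r is NaN with a warning when either
  side is constant.
- **Detection gate.** A stratum is modelled only if at least 50 %
  (`detection_threshold`) of its records are detects; otherwise it is
  skipped with an explicit reason.  Non-detects in modelled strata are
  substituted by `dl_sqrt2` (DL/√2, default), `dl_half`, or `zero`;
  substitution returns a new array and never mutates the input.
- **Seasonal contrasts.** Kruskal–Wallis tests compare seasons (e.g.
  heating vs non-heating gaseous concentrations); the scipy
  implementation is used.

## 5. Mapping

A regular grid (default 500 m cells) anchored at the lower-left corner
of the boundary envelope is clipped to the boundary; cells with empty
intersection are dropped, and predictions are evaluated at the centroid
of each cell∩boundary piece (not the raw cell centroid).  Negative
equation predictions are floored at zero.  Centroid predictions are
then interpolated by **ordinary kriging** (own implementation: solve
the standard (k+1)×(k+1) system with a Lagrange multiplier per target)
onto an output raster.  The variogram (spherical/exponential/Gaussian)
is fit by least squares on binned empirical semivariances; degenerate
inputs (constant field, too few pairs, failed fit) fall back to a
documented default exponential variogram with zero nugget, sill equal
to the sample variance (or 1 when zero), and range one third of the
coordinate-span diagonal.  Kriging with a zero-variance field returns
the constant directly.  The predictor is exact at the input points.

## 6. Pipeline and file formats

The CLI stages (`simulate`, `extract`, `fit`, `validate`, `map`,
`report`, `all`) communicate only through plain-text artifacts in a
work directory: CSV tables (sites, concentrations, covariates, report,
skipped strata, centroid predictions), GeoJSON layers, YAML
(scenario, registry, config), JSON (models with equations and traces,
validation summaries, variograms, manifest), and ESRI ASCII grids
(elevation, kriged surfaces).  ASCII grids are written with `repr`
floats, so a write/read round trip is bit-lossless.  `manifest.json`
records the seed, the stage log, and library versions.  All derived
RNG streams use `numpy.random.default_rng` with explicit seed
sequences; the same seed yields byte-identical artifacts.

Pipeline defaults: α = 0.05, adjusted-R² gain ≥ 0.01, VIF < 5, Cook's
flag at 1, detection threshold 0.5, non-detect rule `dl_sqrt2`, 999
Moran permutations, exponential variogram, 500 m cells, buffer radii
500–5000 m in 500 m steps (`pahlur.predictors.DEFAULT_BUFFER_SIZES`).

## 7. Limitations of the synthetic generator

- No atmospheric dispersion, chemistry, or emission-inventory realism:
  concentrations are linear in GIS covariates plus noise by
  construction.  The generator exists to exercise extraction,
  selection, validation, and mapping against a known truth, not to
  emulate a real airshed.
- The land mosaic is a Voronoi tessellation; real land-cover patch
  shapes, road network topology, and terrain are far more structured.
- Season enters only through a seasonal mean temperature (partition)
  and season-specific true models; there is no within-season time
  series.
- The logistic partition is a monotone one-parameter-per-input
  caricature of Junge–Pankow-type partitioning; it is calibrated only
  to produce the qualitative pattern (heavy species particle-bound,
  light species gaseous, colder seasons more particulate).
- Detection is a sharp threshold on the true value; real analytical
  noise near the detection limit is not modelled.
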