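# Methods

This note records the models, conventions and open design choices
behind `mcfmap`, in the spirit of a model-description appendix.

## Analysis grids

All analysis happens on a local metric grid, north-up, row 0 at the
northern edge, cell centers at half-cell offsets, and half-open cell
intervals `[edge, edge + cell)` for point-in-cell queries. Predictors
live on two resolutions: a fine grid (30 m analog; DEM, reflectance,
textures) and a coarse analysis grid (fine cell × `coarse_factor`,
240 m with the defaults — the native resolution of the fog product the
masks stand in for). Fine rasters are block-aggregated to coarse by
the mean (mode for categoricals); a block at least half nodata becomes
nodata, and non-divisible shapes are an error rather than an implicit
crop. Nodata is NaN for continuous rasters and an explicit sentinel
for integer ones, and it always propagates — a masked cell is unknown,
never "absent".

## Fog climatology

Monthly frequency at a cell is `#fog / (#fog + #clear)` over that
month's scenes. Invalid retrievals (optically thick cloud, missing
data) are excluded from numerator *and* denominator; counting them as
clear would bias frequencies low. Cells with fewer than
`min_valid_threshold` valid observations in a month are nodata for
that month; the default floor is 10, a documented convention —
frequencies from a handful of scenes are noise. The annual frequency
is the valid-count-weighted mean of the monthly frequencies, which
equals pooling all scenes of the year; this makes the annual map
independent of how scenes are partitioned into months (count
additivity, asserted in tests). Small worlds with few scenes per
month need a lower floor; the pipeline exposes it.

## Terrain features

* **Slope/aspect**: Horn 3×3 kernel on the edge-replicated DEM; slope
  in degrees, aspect as the azimuth of steepest descent clockwise from
  north. Cells adjacent to nodata are nodata.
* **Sky view factor**: for each of 16 azimuths (default) the maximum
  horizon angle θ within 5 km is found by scanning outward with
  nearest-cell sampling at true Euclidean distances;
  `SVF = mean(1 − sin²θ)`, clipping horizons below eye level to zero.
  1.0 on an open plain, 0.5 at the bottom of a symmetric 45° pit
  (closed form, used as a test oracle).
* **Aspect classes**: k-means (k = 4) on the (sin a, cos a) embedding,
  so north-facing cells are not split across the 0/360 wrap. Cells
  flatter than 1° form a dedicated FLAT class outside 1..k — aspect is
  undefined there. Cluster labels are renumbered by ascending circular
  mean aspect, making runs seed-deterministic and label-canonical.
* **Entities and vertical distances**: connected components
  (8-neighborhood by default, to avoid fragmenting diagonal
  ridgelines) of equal aspect class; per cell, distance to ridge =
  entity max − altitude, distance to valley = altitude − entity min.
  Both are invariant to DEM offsets, and per entity their maxima equal
  the entity's elevation range.

Slope and sky view factor are computed and carried as predictors even
though feature selection may drop them — exclusion must emerge from
the data, not be hard-coded.

## Texture features

Five classical structure functions over a moving window (7 px) at
exact axis-aligned lags (1 and 2 px), pooled omnidirectionally.
Dialect, since several exist: for the symmetric measures (variogram,
madogram, rodogram, cross-variogram) each unordered within-window pair
at the exact lag counts once and the estimator is `Σ g(pair) / (2N)`;
the pseudo cross-variogram `Σ (z_a(x) − z_b(x+h))² / (2N)` uses
ordered pairs in all four cardinal directions, which makes it
symmetric in the band order by construction, so unordered band pairs
suffice. Windows are truncated at raster edges (padding would
fabricate data); pairs touching nodata are dropped; centers with fewer
than 8 valid pairs are nodata. Window sums use integral images, so
cost is independent of window size, and the implementation is checked
cell-for-cell against a brute-force pair-enumeration oracle at 1e−12.
Textures are computed at fine resolution and then aggregated, like the
other fine predictors.

## Classification protocol

The ensemble is scikit-learn's `RandomForestClassifier` (500 trees,
default variable subsampling, no class reweighting — the ~35/65 plot
imbalance is handled naturally). The package's contribution is the
protocol around it:

* **OOB predictions** for verification: each training row is judged
  only by trees whose bootstrap excluded it, reconstructed per tree so
  the same machinery can re-score permuted inputs. The reconstruction
  is asserted against the library's own OOB decision function in the
  test suite.
* **Permutation importance** is Breiman-style: the drop in OOB
  accuracy when one feature column is permuted.
* **RFE**: fit at a decreasing schedule of subset sizes (geometric,
  factor 2/3), rank by permutation importance, drop to the next size;
  finally select the smallest size whose OOB accuracy is within one
  standard error (`√(a(1−a)/n)`) of the best. The one-SE rule is a
  documented choice (the method's selection rule is not otherwise
  pinned down) and is deliberately parsimonious: on the synthetic
  world it may keep as few as two or three features, because the
  annual fog frequency nearly encodes the label rule.
* **Map prediction**: per-cell majority vote; any nodata predictor
  makes the cell nodata.

## The synthetic world

The generator produces the study conditions the analysis assumes, not
a radiative-transfer-realistic scene:

* **DEM**: sum of Gaussian hills over a gentle base ramp — a smooth
  closed form, so aspect fields are clean and tests have an exact
  oracle. The default relief is a two-massif main range (peak
  ≈ 4400 m) plus two small isolated massifs (coastal and northern).
* **Fog law** (closed form, per month): winter (monsoon) months get
  `p = base + peak_w · exp(−(alt − c)² / 2σ_w²)` with the bell center
  `c = 2000 m − 600 m · windwardness − 500 m · isolation`; summer
  months a fixed-center, wider, weaker bell (peak 0.3 vs 0.6,
  σ 800 vs 500 m). Windwardness is `max(0, cos(aspect − 45°))`
  scaled by slope (saturating at 10°); isolation is local altitude
  minus the mean in a 1–3 km annulus, scaled by 1.5 km and clipped to
  [0, 1] — the simplest monotone Massenerhebung proxy. No
  quantitative magnitude for the Massenerhebung lowering is
  established in the literature this emulates; it is a free parameter
  with a plausible default, not an asserted value.
* **Scenes**: independent cell-wise Bernoulli draws from the month's
  probability; 30% of retrievals are invalidated independently per
  cell and scene (no spatial structure — sufficient to exercise the
  valid-count bookkeeping, unlike real cloud-correlated gaps).
* **Labels**: MCF conditions where annual fog probability ≥ 0.25
  within an 800–2600 m corridor. This yields the two regimes the
  real system shows: a clean upper boundary driven by altitude alone
  and a lower fringe driven only by fog (windward and isolated
  slopes). Forest is everything below 3100 m outside cleared
  rectangles; the default world clears one lowland patch on the
  northern isolated massif, so a few percent of condition cells are
  removed at the intersection stage.
* **Plots**: 600 vegetation plots at 35/65 MCF/non-MCF balance,
  stratified over altitude deciles of the forested area (minimum 5 per
  non-empty stratum); 400 forest/non-forest points at 55/45. Labels
  are read from the truth grids, so plot labels agree with the truth
  by construction.
* **Reflectance**: per class (non-forest, forest, cloud forest) each
  band draws its configured mean plus spatially correlated Gaussian
  noise (sd 0.05) with class-specific correlation length (2 / 6 / 4
  fine cells), clipped to [0, 1]. Cloud forest is deliberately
  spectrally close to other forest — slightly lower NIR/SWIR from
  moister, shorter canopies — so spectra alone are an imperfect
  predictor and the decisive low-altitude information comes from the
  fog climatology, which is the regime the single-input-set ablation
  (fog > terrain > spectral) is meant to occupy.

Determinism: every stochastic stage draws from
`default_rng([seed, stage_id])`; identical config + seed is
bit-identical, and stages can be rerun independently.

What passing tests on this world do **not** show: robustness to
correlated retrieval gaps, spatially varying spectra within a class,
georeferencing/projection issues, or label noise in real vegetation
plots — none of which the generator emulates.

## Problem sizes

Default study conditions: 400×400 fine grid (12 km × 12 km at 30 m),
coarse factor 8 (50×50 analysis cells), 300 fog scenes, 600 plots.
One full pipeline run (world, climatology, terrain, 96 textures,
two model variants) takes ~15 s on one core. The seed-replication
checks in the test suite run this pipeline across 10 seeds; unit
tests use a 160×160 world and reduced scene counts with a
correspondingly lower valid-observation floor.

## Known limitations

* The verification module flags undefined statistics (zero
  denominators) as missing rather than zero, and defines MCC = 0 when
  a table margin is zero; published tables occasionally print a Bias
  inconsistent with their own counts at 2 decimals, and the package
  reproduces only count-consistent values.
* The sky view factor's nearest-cell ray sampling slightly
  underestimates horizons between azimuth directions; with 16
  directions the error is well below the feature's dynamic range.
* The pseudo cross-variogram convention (4-direction ordered pairs)
  differs from some published dialects by a constant pairing factor;
  the brute-force oracle in the tests pins the convention exactly.
* No spatial cross-validation: verification is out-of-bag at plot
  locations, so spatial autocorrelation between nearby plots inflates
  absolute accuracy estimates (as it does in the design this
  replicates); A-vs-B *contrasts* are less affected.
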