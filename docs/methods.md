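# Methods

## Overview

`wetpot` models potential wetland area (PWA) as a supervised
classification problem: given aligned 10-m rasters of terrain, soil and
multi-temporal SAR predictors plus a binary wetland/non-wetland label
raster, a random forest learns the landscape signature of wetland cells
and is applied to every cell. The package implements the full chain —
predictor derivation, balanced sampling, training, assessment, spatial
prediction and connectivity post-processing — together with a synthetic
landscape generator used as its test bed.

All rasters share one planar equal-area grid: row 0 is north, column 0
is west, cells are square, cell (r, c) addresses its center, and
distances are center-to-center. Grids are "aligned" only when shape,
cell size and origin agree exactly; no reprojection is performed.
Nodata is NaN for float grids and −2147483648 for integer grids.

## Terrain hydrology

**Pit removal** uses priority-flood filling seeded from all boundary
cells (grid edge or nodata-adjacent), raising each newly reached cell to
at least the pour elevation plus `epsilon` (default 10⁻⁴ m). With
positive epsilon the output is flat-free: every interior cell has a
strictly descending 8-neighbor path to the boundary, which is the
precondition for routing. The operation is idempotent and monotone
non-decreasing; a fully enclosed valid region with no outlet is an
error.

**Flow direction** follows the D-infinity triangular-facet construction:
for each cell the downslope gradient is maximized over the eight facets
spanned by a cardinal and a diagonal neighbor. Within a facet the angle
is clamped to [0°, 45°]; flow splits between the two facet neighbors in
proportion to angular proximity, and an angle aligned exactly with a
neighbor sends that neighbor everything. Cells with incomplete
neighborhoods (boundary or nodata-adjacent) fall back to the steepest
single-neighbor descent; a complete facet always dominates its own
edges, so the fallback never changes interior results. A cell with no
in-grid descent is an *outlet* if it touches the edge or nodata, and an
error otherwise.

**Accumulation** a(i) = 1 + Σⱼ p(j→i)·a(j) is evaluated in a topological
order of the routing graph (Kahn's algorithm, which also detects
cycles). Mass is conserved: the accumulation summed over outlets equals
the number of valid cells.

**Channels** are cells whose accumulation meets the threshold
(inclusive; default 45,000 cells = 4.5 km² at 10 m). A coastal mask, if
supplied, injects channel cells along the coast: every valid cell
8-adjacent to the mask is flagged, standing in for flow into oceans.
With no channel in a drainage, upstream distance-down values are nodata
unless outlets are configured to act as channels.

**Distance down** to the channel network is the flow-proportion-weighted
average over downstream paths: d(i) = Σₖ p(i→k)·(seg(i,k) + d(k)),
evaluated downstream-first, with d = 0 on channels. The segment length
is the planar center-to-center distance (HOFD), the elevation drop on
the pit-filled surface (VOFD), or the per-segment hypotenuse (POFD);
the metrics therefore satisfy max(H, V) ≤ P ≤ H + V cell-wise.

**CTI** = ln(a·Δ / tan(β + 0.0001)), where a·Δ is the specific catchment
area (contributing cells × cell size, i.e. per unit contour width of one
cell side) and β is the D-infinity facet slope in radians; the
10⁻⁴ rad addition keeps flat cells finite. The raw index is smoothed
with a 3×3 focal mean and min-max scaled onto integers 0–1000 (nearest
integer, half away from zero; min→0 and max→1000 exactly). The focal
mean is computed as an explicit nine-term shifted sum in a fixed order,
so tiled and untiled computations agree bit-for-bit. The *Slope* and
*Aspect* predictors instead use 4-neighbor central differences in
degrees (one-sided at edges); aspect is the compass bearing of steepest
descent, clockwise from north, with flat cells assigned 0. Using the
facet slope for CTI and the 4-neighbor slope for the Slope predictor is
a deliberate split: the former is the slope the routing actually used,
the latter the conventional cartographic derivative.

**Tiling.** Large rasters can be processed per tile with a buffer
(default 6675 m, rounded up to whole cells) that absorbs edge effects;
results are clipped to the unbuffered tile and mosaicked. For any cell
whose entire upslope area lies inside the buffered tile, tiled
accumulation and CTI equal the untiled values exactly.

## Soil, SAR and label predictors

**PWS.** Per soil map unit, the percents of components whose drainage
class is poorly/very-poorly drained *or* whose hydric rating is yes are
summed, each component counted once (a component meeting both criteria
contributes once; the sum is capped at 100 as a safety net, since a
percent of area cannot exceed it). Units where every component has
unknown drainage and unknown hydric fall back to the unit's PWSL
percentage; with neither, the unit is nodata. The drainage and hydric
criteria are treated symmetrically (an OR rule); users comparing against
workflows that prioritize drainage class should note the convention.

**SAR percentiles.** The band ratio is computed as the dB difference
VV − VH (the linear power ratio expressed in dB; a linear-scale option
exists). Percentiles use linear interpolation between order statistics.
A date counts for the ratio only when both bands are valid; cells with
fewer than two valid dates are nodata.

**Labels.** A categorical wetland-subsystem raster is reclassified with
a total mapping: wetland subsystems → 1, deep/open-water systems
(marine, subtidal estuarine) → 0, excluded riverine/limnetic
subsystems → nodata, and background cells outside every mapped category
→ 0.

**Stack.** The 17 layers are assembled in a fixed order and masked
complete-case: a cell nodata in any layer is unusable everywhere, so
sampling and prediction always see full feature vectors.

## Sampling, classification, assessment

The per-class sample count is round(valid area km² / density), half away
from zero, drawn uniformly without replacement within each class
(capped at the class size with a warning). The default density of one
point per 475 km² per class matches continental-scale practice; the
desk-scale runs below use 0.02 km² per point so a 26 km² scene yields
roughly 1300 points per class. Each point receives an independent
uniform draw u, stored for audit; it trains iff u < 0.7.

The classifier is a scikit-learn random forest: 200 trees on bootstrap
resamples, 4 candidate features per node split (⌊√17⌋), grown to purity
(min_leaf = 1), majority vote, deterministic under its seed. Raw
variable importance is the mean impurity decrease per feature;
normalized importance rescales it to sum to 1.

Assessment tallies the validation confusion matrix and reports, in
percent: overall accuracy, and per-class commission error (predicted
cells that are wrong) and omission error (true cells that were missed).
Ratios with zero denominators are reported as not-applicable. Text
tables round to one decimal; JSON keeps full precision.

## Post-processing

Predicted wetland cells are labeled into maximal 8-connected components
(corner contact connects; nodata is a barrier, never connective).
Cluster statistics cover min/max/mean/median, 5th/95th percentiles
(linear interpolation, matching the SAR convention), standard deviation,
and the share of class area held in single-pixel (0.0001 km² at 10 m)
clusters. The cropland mask lives on a 3×-coarser aligned grid; each
coarse cell paints its 3×3 block and PWA–C is the cell-wise
intersection, so PWA–C ⊆ PWA always. Areal summaries report class area
and percent cover per region id.

## Synthetic landscape generator

The generator emulates the *structure* of the real inputs, coupled
through a latent wetness field (standardized smoothed negative relative
elevation — high in valley bottoms and depressions):

* **DEM**: correlated Gaussian surface (correlation length 12 cells,
  range = `relief`, default 30 m) plus a 0.5% southward tilt, with
  `n_pits` single-cell depressions carved 1 m below their lowest
  neighbor, at least 3 cells apart. Zero relief leaves the pure tilt.
* **Soils**: map units are Voronoi cells of random seeds; component
  percents are Dirichlet-distributed and sum to 100; the probability of
  poor drainage or hydric rating rises linearly with the unit's wetness
  rank; a configurable fraction of units (default 15%) carries only a
  PWSL value to exercise the fallback.
* **SAR**: per date, clean backscatter is a base level minus a gain times
  the wetness rank (VV: −8 − 6·w dB; VH: −14 − 8·w dB) plus a per-date
  level offset (sd 0.5 dB); gamma multiplicative speckle with mean 1 and
  variance 1/looks (default 5 looks) is applied in linear power. This is
  the standard multilook speckle model; incidence-angle and orbit
  geometry are deliberately not modeled.
* **Labels**: s = w₁·z(CTI) + w₂·z(PWS) − w₃·z(VOFD) + ε with
  ε ~ N(0, noise_sd), thresholded at the quantile giving the target
  prevalence (default 0.25). CTI, PWS and VOFD are the *pipeline's own*
  outputs on the generated DEM and soils, so recovering the weights
  exercises the entire chain, not just the classifier.
* **Cropland**: a smoothed noise field on the 3×-coarser grid,
  thresholded at the quantile matching the target fraction (default
  0.30). Scenes whose dimensions are not divisible by 3 have no cropland
  layer, and the pipeline then skips the PWA–C overlay.

Scene generation uses outlets-as-channels and a channel threshold of
max(cells/100, 25), since a desk-scale grid cannot accumulate the
continental 45,000-cell threshold. Every bundle is a pure function of
its config: per-stage random streams derive from (seed, stage index),
so reruns are byte-identical.

What passing tests on this generator do **not** show: robustness to
label noise structure found in real inventories (digitization vintage,
unmapped regions), radiometric SAR effects, soil-survey inconsistencies
across state compilations, or behavior at continental extents. The
generator's couplings are monotone and noise is Gaussian/gamma; real
landscapes are messier.

## Reference run and problem sizes

The parameter-recovery reference is a 512×512-cell scene (26.2 km² at
10 m) with weights (1, 1, 1), noise 0.25, prevalence 0.25 and fixed
seeds; sampling density 0.02 km²/point gives ≈1310 points per class.
Under these conditions validation overall accuracy is ≥ 90% (≈ 94% in
practice, ~44 points above the balanced-sample baseline), CTI, PWS and
VOFD occupy the top importance ranks, and a label-permutation control
drops accuracy to a 99% binomial band around 50%. The end-to-end
pipeline demo uses the default 240×240 scene. Unit and property tests
use 5×5–32×32 grids where dense linear-system, angular-sweep, BFS and
flood-fill oracles are affordable.

## Numerical conventions

* Rounding of scaled CTI and sample counts: nearest, half away from zero.
* Percentiles everywhere: linear interpolation between order statistics.
* Channel threshold comparison: inclusive (≥).
* Flat-cell aspect: 0 by convention; flat-cell CTI: finite via the
  10⁻⁴ rad slope guard.
* fill_nodata: inverse-distance weighting (power 1) over valid cells
  within the radius (default 15 cells); holes wider than twice the
  radius retain a nodata core; idempotent once all holes are filled.
* The global seed expands into per-stage seeds by fixed offsets
  (sampling +101, split +202, forest +303), so stages re-run
  independently yet reproducibly.

## Known limitations

* No CRS handling: all inputs must be pre-aligned on one equal-area
  grid; GeoTIFF georeferencing tags are carried through, not validated.
* Pure-Python/numpy routing loops are comfortable to ~10⁶ cells; larger
  extents should use the buffered tiling path per watershed.
* The RF importance is impurity-based and shares that family's bias
  toward high-cardinality continuous features; permutation importance is
  not implemented.
* Vector (polygon) wetland inventories must be rasterized upstream; the
  package starts from categorical rasters.
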