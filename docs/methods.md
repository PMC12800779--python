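# Methods

This note documents the models, conventions and design choices behind the
package, in the order the pipeline applies them.

## Occurrence handling

Occurrence input is delimited text with Darwin Core-style headers, UTF-8,
comma or tab delimited (auto-detected, overridable). Rows with unparseable
or out-of-bounds coordinates are rejected and logged — never clamped —
because a clamped coordinate silently fabricates a locality.

The precision filter drops records whose stated coordinate uncertainty
exceeds a threshold, default 10,000 m (about half the width of a
quarter-degree hexagon: a record blurrier than that cannot be placed in a
cell with confidence). Records *without* a stated uncertainty are kept by
default: gazetteer-georeferenced historical specimens often lack a formal
precision but are still informative at these scales. A flag drops them
instead. One filtered record set feeds every downstream stage — range
metrics, classification, weights and cell membership — so the maps and the
checklist are computed from the same evidence.

Country assignment tests each point against the focal polygon with
boundary points counting as **inside**. The tie favours endemism, the
conservative direction for a conservation assessment: a specimen collected
on the border contributes to national responsibility rather than being
discarded from it.

## Range metrics

All areas use a Lambert cylindrical equal-area projection of the authalic
sphere (R = 6371.0072 km), centred by default on the centroid of the taxon's
points. Equal-area is the property that matters: the minimum convex polygon
(MCP) area and the km² classification thresholds are area statements, and
the forward/inverse maps are exact closed forms (round-trip error is
floating-point only). No ellipsoidal datum transformation is attempted;
for range areas at national scale the sphere-vs-ellipsoid area difference
is far below the uncertainty in the occurrence data itself.

* **EOO** is the convex-hull area of the projected points. Fewer than three
  non-collinear unique localities (hull thinner than 1e-9 km²) make the
  hull degenerate; the metric then falls back to EOO := AOO and sets a
  flag, the standard convention in batch Red List pre-assessment, so
  single-locality taxa still carry a usable range value.
* **AOO** counts distinct occupied axis-aligned square cells (default
  2 km width, the IUCN standard) anchored at the projection origin,
  times cell area. The anchor is fixed rather than optimised (IUCN permits
  minimising the occupied-cell count) to keep the statistic deterministic;
  with a fixed projection in `GridParams`, AOO is also monotone under
  adding records and invariant under small translations away from cell
  edges.
* Duplicate coordinates collapse for the hull and the cell count but are
  retained in `n_points` and in the inside-country fraction, which are
  statements about sampling, not geometry.

The outside-country EOO (used by NE1) is 0 with fewer than three outside
points, and uses the same fallback rule on the outside subset otherwise.

## Endemism classification

* **E** requires every record inside the country — an evidence statement,
  deliberately independent of all area thresholds.
* **NE2**: global fallback-aware EOO strictly below 10,000 km². The strict
  inequality means a taxon at exactly the threshold does not qualify. The
  fallback-aware EOO lets single-locality cross-border taxa qualify.
* **NE1** operationalises "majority of the range inside, scarce or
  range-restricted beyond" as: inside-record fraction strictly above 0.5,
  AND (≤ 5 outside records OR outside-MCP ≤ 1,000 km²). Majority is
  measured on records, not area: record-level data is what the pipeline
  holds, and the area share of an MCP split by a border is unstable at
  small sample sizes. The two outside criteria form a disjunction because
  "scarce" (few collections) and "range-restricted" (tight cluster) are
  different situations that both warrant national responsibility. The
  defaults (0.5, 5 records, 1,000 km²) are this package's documented
  operationalisation of a qualitative criterion; all are configurable and
  every output row carries the evidence numbers so borderline calls can be
  audited.

Taxa with no occurrence records are reported `UNCLASSIFIABLE` with a
logged reason, never silently dropped.

## Hexagonal grid and weighted endemism

The grid is a tiling of pointy-top hexagons of fixed angular height
(default 0.25°, point to point) built directly in lon-lat space — the
quarter-degree specification is angular, not metric, so the grid is not
projected. Cells are indexed (row, col) in odd-row-offset coordinates and
the tiling is analytic: a point anywhere maps to a cell without
pre-building a bounded grid, so record sets outside any initial bounding
box are handled without special cases. Cells are the Voronoi regions of
the hexagon centres; a point equidistant from several centres (a shared
edge or vertex, detected within 1e-9 deg²) is assigned to the
lexicographically smallest (row, col), which makes "every point in exactly
one cell" exact rather than measure-theoretic.

Per-taxon weights combine the inverse of the two range metrics,
min-normalised over the analysis taxon set:

    w = ( min(AOO)/AOO + min(EOO*)/EOO* ) / 2,    EOO* = max(EOO, AOO)

This choice is deterministic, scale-free, bounded in (0, 1], gives the
narrowest-ranged taxon weight 1 exactly, and is monotone: shrinking a
taxon's range never decreases its weight. Using EOO* keeps
degenerate-hull taxa on the same scale as the rest. Cell weighted endemism
is the sum of member-taxon weights; richness counts species, subspecies
and varieties as separate units. Both maps are computed over the
endemic/near-endemic subset by default (configurable via
`grid_statuses`).

Because inverse-range weighting has no single canonical normalisation in
the literature, absolute WE magnitudes are comparable only within one
analysis run (the min-normalisation ties them to the narrowest taxon in
the set); rankings and hotspot contrasts are the robust outputs.

## Summary conventions

Percentages are rounded half-up (not banker's), 1 decimal by default, 2
for shares of a national flora in the thousands of species. Family tables
use competition ranking (tied families share a rank and consume positions:
1, 2, 2, 2, 5). "Threatened" is exactly VU ∪ EN ∪ CR. Category shares are
over assessed taxa (category ≠ NE); the assessed share itself is over all
described endemic taxa. Hybrids and undescribed taxa appear in the
checklist totals but are excluded from family, growth-form, region and
Red List summaries. A taxon with several growth forms counts once in each,
so form percentages may sum above 100. The discovery curve uses the
basionym year — first valid publication, not later recombination.

## Synthetic data generator

The generator emulates the data structure of a national endemism study on
a tractable geometry:

* a convex irregular hexagonal country ~500 km across near the equator
  (vertices drawn in an equal-area km plane, mapped to lon-lat), with
  ecoregions as Voronoi cells of random interior points clipped to the
  country, so regions tile it exactly;
* five montane "hotspot" centres in the country interior around which
  strict endemics cluster;
* four taxon classes — strict endemic (35%), near-endemic of the
  majority-inside kind (15%), near-endemic of the small-range kind (25%),
  widespread (25%) — with per-class log-uniform target EOOs
  (50–5,000 / 2,000–30,000 / 1,000–8,000 / 50,000–500,000 km²) and
  per-class inside-country record fractions (1 / 0.70–0.90 / 0.50–0.70 /
  0.15–0.45);
* about 25 records per taxon (negative binomial, shape 5, floor 5), giving
  ≈5,000 records for a 200-taxon study;
* georeference precision mixed 60% precise (10–1,000 m), 25% coarse
  (15,000–50,000 m — deliberately above the default filter threshold),
  15% missing;
* Red List labels drawn as LC .34, NT .02, VU .22, EN .19, CR .12, DD .05,
  NE .06 — chosen once to match the aggregate shares a national endemic
  flora typically shows (>90% assessed, ~58% of assessed threatened);
* basionym years uniform on 1893–2020.

Point clouds are isotropic bivariate normals. Because the expected convex
hull area of n Gaussian points scales exactly as σ² · f(n), the spread
needed for a target EOO is σ = √(target / f(n)), with the unit-variance
factor f(n) estimated once per n by pilot simulation (200 replicates,
fixed calibration seed, cached). Cross-border taxa centre on the border
itself and draw their inside and outside point counts separately,
conditioned on the respective side, so the realised inside fraction is
controlled exactly; the majority-inside near-endemics place their outside
records as a tight cluster (σ = 3 km) so the "range-restricted beyond"
criterion is genuinely exercised rather than met by record scarcity alone.

All randomness flows from one root seed through named substreams
(country, taxa, points, uncertainty, categories), so adding a generation
stage never perturbs earlier draws and identical seeds produce
byte-identical output files.

**What the generator does not emulate** — and hence what passing recovery
tests do not show about real data: spatially autocorrelated collecting
bias (roads, herbaria proximity), duplicate specimens across herbaria,
taxonomic identification error, non-convex country shapes with enclaves,
topography-driven range shapes, and coordinate errors beyond the stated
uncertainty (e.g. country-centroid georeferences). Recovery rates on real
occurrence databases will be lower than the ≥ 90% measured here.

## Problem sizes and numerical choices

The standard study size used in tests and in the acceptance script is 200
taxa with a minimum of 20 points per taxon (≈5,000–10,000 records), with
the hotspot contrast measured over ten 50-taxon replicate studies — large
enough that class-recovery and containment rates are stable to a few
percent, while a full pipeline run takes seconds. Collinearity tolerance
for hulls is 1e-9 km²; hex tie-break tolerance 1e-9 deg²; equal-area
round-trips are exact to floating point. Known limitations: no
origin-optimised AOO (deliberate), no alpha hulls or subpopulation counts
for full criterion-B assessment, no phylogenetic or richness-corrected
endemism variants, and no cartographic output beyond per-cell tables and
GeoJSON.
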