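# Methods

## Model and scope

The package computes annual, grid-based indicators of biodiversity data
coverage. Its unit of analysis is the (species, year, scope) triple, where
scope is a species' full expected range ("global") or the part of it
inside one country. The expected range is static within an analysis: a set
of equal-area grid cells supplied directly, or rasterized from polygons.
Occurrence records are reduced to presence counts per (species, year,
cell); repeat visits within a cell-year raise the record count (which
feeds the evenness index) but not coverage.

Assumptions inherited from this design: ranges do not shift during the
analysis window; a single record suffices to "cover" a cell in a year
(no detection-probability or effort correction); annual time bins; and
records outside a species' expected range carry no information about that
range's coverage — they are excluded from the indices and tallied in a
diagnostics table instead.

## Grid and projection

Layers share one grid of square cells (default edge 110 km; 55 and
27.5 km supported, halving the edge nests 4 children exactly in each
parent) in a named cylindrical equal-area projection. Behrmann (standard
parallel 30°) is the default; the projection is a configuration field,
not a constant, because any equal-area choice serves the indices equally.
The forward/inverse mapping is the closed-form cylindrical equal-area
transform on the authalic sphere (R = 6371.007181 km). Cell intervals are
half-open with lower-edge inclusion, making point assignment a partition:
every projected point lands in at most one cell, boundary points
deterministically in the lower-edge cell. Points beyond the grid extent
are rejected and counted, never silently dropped.

Country assignment is exclusive by default (majority overlapped area,
ties to the lexicographically smallest ISO3 code), so per-species
stewardship weights sum to exactly 1 over countries — the property that
makes Steward's SSII sum to the global SSII. A fractional-area assignment
is available for diagnostics but is not used by the headline indices.

## Indices

**SSII.** Coverage is `n_sampled / n_expected` with both counts taken
over the scope's cell set. National coverage restricts the expected cells
to those assigned to the country. Steward's species SSII multiplies
national coverage by the stewardship weight; because the national
expected-cell sets partition the global range, the sum identity
`Σ_c s_{k,c}·SSII_{k,c} = SSII_k(global)` holds to machine precision and
is enforced by a property test.

**National aggregation.** National SSII is the unweighted mean of
national coverage over all species expected in the country; species with
zero records contribute 0, so the index can fall when sampling stops.
Steward's national SSII is the stewardship-weighted mean `Σ w c / Σ w`.
Each species-country row carries its weight explicitly so zero-coverage
species still enter the denominator.

**SSEI.** For per-cell counts r_i over n sampled cells with shares
p_i = r_i/R, `SSEI = −Σ p_i ln p_i / ln(n)`. The natural logarithm is
used throughout (normalization cancels the base; fixing it keeps
intermediate entropies reproducible). The default denominator is
ln(n_sampled) — evenness across the sampled portion of the range — so
SSEI answers a question SSII does not (how well distributed the records
are, given where they got to), and the two indices stay complementary.
ln(n_expected) is available as a configuration switch for users who want
effectiveness relative to the whole range. With fewer than two sampled
cells the normalizer vanishes (0/0); the value is reported missing and
excluded from national means, with optional substitution constants (0 or
1) off by default. Steward's SSEI uses the same weighted-mean
construction as Steward's SSII, applied symmetrically.

A theoretical property worth stating precisely: for mixtures of
single-record and v-record cells, evenness is identical for any uniform
redundancy (all cells 1, 10 or 1000 records score 1), near-maximal when
only a small minority of cells hold a *second* record (v = 2), but
*collapses* for heavy redundancy (v ≥ 100 in >5% of cells), because the
heavy cells then hold nearly all record mass. The v = 1000 mixture curve
lies below the v = 2 curve at every interior mixing proportion.

## Trends and typology

Annual national/global series per taxon feed a decadal trend estimate
(default window 2010–2019): OLS of index on year, two-sided t test on the
slope, significance at α = 0.01. Series are classed increasing/decreasing
when the slope is significant, "none" otherwise; fewer than 3 non-missing
years gives "none" flagged insufficient-data, and exactly constant series
short-circuit to slope 0 (avoiding a degenerate regression). Mann–Kendall
(Kendall tau p, Theil–Sen slope) is available where normality is a
concern. Monte-Carlo tests verify the type-I error rate (≈ α under a
null of 500 seeded replicates) and power (≥ 90% for slope 0.02, noise SD
0.005, 10 years).

Countries are classified into four types by crossing decadal-mean
Steward's SSII against the global mean (the unweighted mean of national
decadal means) with trend class. "Above" is strict — a value exactly
equal to the global mean counts as below, a tie-break that matters only
on constructed inputs. "No or decreasing" pools non-significant and
significantly decreasing trends. Where a country's value must be averaged
across taxa, the mean of class-level indices is used (pooled-species
aggregation is available via the taxon mapping).

The stewardship-preference diagnostic is the percent difference
`100·(Steward's − National)/National` of decadal means; National SSII is
the denominator, and the value is missing when it is 0.

## Synthetic data generator

`make_world` emulates the three input layers: countries as contiguous
column blocks on the grid, species ranges as connected cell blobs grown
by random frontier expansion (size uniform on a configured interval,
default 4–16 cells on a 12×8 grid), and per-species-year record totals
drawn Poisson around λ(1+g)^t (default λ = 50 records/species/year,
g = 0). Records are allocated across expected cells by a symmetric
Dirichlet-multinomial with concentration 1/θ: θ = 0 is the uniform limit,
large θ piles records into few cells, so one parameter spans the full
evenness axis. All randomness flows from one master seed through named
per-layer streams, so adding a layer never shifts existing draws and
identical seeds give bit-identical worlds.

What the generator does **not** emulate: real range-map geometry and
coastlines, spatial autocorrelation of sampling effort, detection biases,
taxonomic error, or range dynamics. Passing tests therefore demonstrate
the correctness of the index arithmetic, aggregation and trend machinery
on inputs with known truth — not that the indicators are unbiased on real
GBIF-scale data, whose biases the indicators are designed to expose
rather than correct.

Problem sizes in the test and acceptance suites are kept modest (grids of
tens to ~100 cells, tens of species, 100–500 Monte-Carlo replicates),
which is ample for the exact identities and the binomial tolerances used.

## Numerical choices and edge cases

- Indices are computed at full precision; rounding (two decimals for
  coverage, one for the weighted means) is presentation only.
- Missing values are serialized as empty fields, never 0 — for SSEI, 0
  (maximally uneven) and missing (undefined) are distinct states.
- Empty expected ranges raise an error rather than returning 0: a species
  with no expected cells in a scope has no defined index there.
- Duplicate (species, cell) range rows are deduplicated with a warning;
  conflicting country assignments for one cell are an error, not a
  warning, because they would break the stewardship partition.
- The record-allocation Dirichlet draw is skipped at θ = 0 rather than
  approximated with a large concentration, so the uniform limit is exact.

## Known limitations

No occupancy modelling or detection correction; no environmental-space
coverage; no coordinate-uncertainty filtering; the optional polygon path
(GeoJSON via shapely) is intended for toy geometries, not production
boundary processing; and the exact grid used by published global analyses
(projection, origin, coastal-cell treatment) is configurable here rather
than fixed, so absolute values on real data depend on that choice.
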