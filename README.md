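# ssii — spatiotemporal biodiversity data-coverage indicators

Knowing *where* a species occurs is only as good as the records behind the
map. This package computes two indicators that quantify, per species and
per year, how well occurrence records (e.g. GBIF-style point observations)
cover a species' expected geographic range, and how effectively those
records are distributed across it. It is aimed at biodiversity informatics
practitioners and national/global monitoring programmes tracking progress
in closing spatial knowledge gaps.

## The indices

All layers are indexed on an equal-area grid (square cells of e.g. 110 km
in a cylindrical equal-area projection). For species *k* with expected
range cells *N_k* (from an expert range map or model), of which *n_k(t)*
hold at least one record in year *t*:

- **SSII** (Species Status Information Index): the proportion of expected
  range cells with data, `SSII_k(t) = n_k(t) / N_k ∈ [0, 1]`. At national
  scope the expected cells are restricted to those inside the country.

- **National stewardship** `s_{k,c}`: the fraction of species *k*'s global
  range cells falling in country *c* (1 for endemics; weights per species
  sum to 1). **Steward's SSII** is national coverage times stewardship,
  `s_{k,c} · SSII_{k,c}(t)`; summed over countries it recovers the global
  SSII exactly.

- **National SSII** for a taxon: the unweighted mean of national coverage
  over all species expected in the country (unrecorded species count as
  0). **Steward's national SSII** is the stewardship-weighted mean
  `Σ s_k c_k / Σ s_k`.

- **SSEI** (Species Sampling Effectiveness Index): the Shannon entropy of
  the per-cell record distribution normalized by its maximum,
  `SSEI = −Σ pᵢ ln pᵢ / ln n` over the *n* sampled cells with record
  shares *pᵢ*. 1 means perfectly even sampling; values near 0 mean records
  piled into few cells; undefined (missing) when fewer than two cells are
  sampled.

On top of the annual series the package estimates decadal change rates
(OLS slope with a two-sided t test, default window 2010–2019, α = 0.01;
Mann–Kendall optional) and classifies countries into four types by
crossing decadal-mean Steward's SSII (above/below the global mean) with
trend direction (increasing vs. no-or-decreasing).

## Worked example

The bundled two-species fixture has species `sp1` endemic to country AAA
(6 expected cells, 5 with records) and species `sp2` with a 10-cell global
range, 3 cells in AAA (2 with records) and 7 unrecorded cells in BBB:

```python
import ssii
from ssii.grid import grid_occurrences

world = ssii.fig1_fixture()
gridded, _ = grid_occurrences(world.occurrences, world.grid)
sp = ssii.species_indices_table(world.ranges, world.countries, gridded, [2019])
table, _ = ssii.annual_index_table(sp, world.taxa)
```

The species-level national rows:

```text
species_id country  n_expected  n_sampled  ssii  weight  stewards_ssii
       sp1     AAA           6          5 0.833     1.0          0.833
       sp2     AAA           3          2 0.667     0.3          0.200
       sp2     BBB           7          0 0.000     0.7          0.000
```

`sp1` has national coverage 5/6 ≈ 0.83 and, being endemic, the same
Steward's value. `sp2` covers 2/3 ≈ 0.67 of its national range, scaled by
stewardship 0.3 to 0.20. Aggregating:

```text
  scope country  year  national_ssii  stewards_ssii  pct_species_recorded
country     AAA  2019          0.750          0.795                 100.0
country     BBB  2019          0.000          0.000                   0.0
 global          2019          0.517            NaN                 100.0
```

Country AAA's National SSII is the mean of 0.833 and 0.667 (0.75), and its
Steward's national SSII is the stewardship-weighted mean
(1.0·0.833 + 0.3·0.667)/1.3 ≈ 0.795 (0.8 to one decimal). BBB holds 70% of
`sp2`'s range but no records, so all its indices are 0; note `sp2`'s
global SSII (0.2) equals the sum of its Steward's values across AAA and
BBB.

## Command line

```sh
ssii synth --preset world --seed 7 --out inputs/   # synthetic input layers
ssii run --occurrences inputs/occurrences.csv --ranges inputs/ranges.csv \
         --countries inputs/countries.csv --grid inputs/grid.json \
         --taxa inputs/taxa.csv --year-start 2010 --year-end 2019 --out results/
```

`run` writes species-year indices, the annual national/global index
table, decadal trends, the national typology, stewardship-preference
diagnostics and a run manifest; `grid`, `indices`, `trends` and
`typology` expose the stages individually.

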