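"""Synthetic worlds for exercising the indicator pipeline.

Generates toy grids, block countries, blob-shaped species ranges and
occurrence streams with controllable sampling intensity, per-cell record
concentration (evenness) and temporal trends, plus exact fixtures for the
two-species worked example and the theoretical evenness curves.

Everything is reproducible from a single seed: each layer draws from its
own named child generator, so adding a layer never shifts the draws of
existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .grid import GridSpec, build_grid

# fixed stream indices per layer (order must never change)
_STREAMS = {"ranges": 0, "occurrences": 1, "trend": 2}


@dataclass
class WorldConfig:
    """Configuration of a synthetic world.

    Parameters
    ----------
    n_cols, n_rows : int
        Grid extent in cells.
    cell_size_km : float
        Cell edge length (default 110 km, the coarse analysis resolution).
    n_countries : int
        Countries tiling the grid as contiguous column blocks.
    n_species : dict
        Species per taxon, e.g. ``{"birds": 20, "mammals": 10}``.
    range_size : tuple
        (min, max) number of cells per species range, drawn uniformly.
    lam : float
        Expected records per species per year at the first year.
    theta : float
        Record-concentration parameter (>= 0). 0 allocates records
        uniformly at random over the range; larger values concentrate
        them into fewer cells (Dirichlet-multinomial with concentration
        ``1/theta``).
    growth : float
        Annual multiplicative intensity trend; year ``t`` draws around
        ``lam * (1 + growth) ** t``.
    years : sequence of int
        Calendar years to simulate.
    seed : int
        Master seed for all layers.
    """

    n_cols: int = 12
    n_rows: int = 8
    cell_size_km: float = 110.0
    n_countries: int = 3
    n_species: dict = field(default_factory=lambda: {"birds": 10, "mammals": 5})
    range_size: tuple[int, int] = (4, 16)
    lam: float = 50.0
    theta: float = 0.0
    growth: float = 0.0
    years: Sequence[int] = tuple(range(2010, 2020))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_countries < 1 or self.n_cols < self.n_countries:
            raise ValueError("need 1 <= n_countries <= n_cols")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if min(self.n_species.values(), default=1) < 1:
            raise ValueError("n_species counts must be positive")
        if self.range_size[1] > self.n_cols * self.n_rows:
            raise ValueError("range size exceeds grid")


@dataclass
class World:
    """A complete synthetic input bundle for the pipeline."""

    config: WorldConfig
    grid: GridSpec
    countries: pd.DataFrame      # cell_id, country
    ranges: pd.DataFrame         # species_id, cell_id
    taxa: pd.Series              # species_id -> taxon
    occurrences: pd.DataFrame    # species, decimalLongitude, decimalLatitude, year


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[stream]])


def _block_countries(grid: GridSpec, n_countries: int) -> pd.DataFrame:
    """Countries as contiguous column blocks named C00, C01, ..."""
    edges = np.linspace(0, grid.n_cols, n_countries + 1).round().astype(int)
    cell_ids = np.arange(grid.n_cells)
    cols = cell_ids % grid.n_cols
    country_of_col = np.empty(grid.n_cols, dtype=object)
    for k in range(n_countries):
        country_of_col[edges[k]:edges[k + 1]] = f"C{k:02d}"
    return pd.DataFrame({"cell_id": cell_ids, "country": country_of_col[cols]})


def _grow_blob(grid: GridSpec, size: int, rng: np.random.Generator) -> set[int]:
    """Connected cell blob grown by random frontier expansion."""
    start = int(rng.integers(grid.n_cells))
    blob = {start}
    frontier = {start}
    while len(blob) < size:
        neigh = set()
        for cid in frontier:
            r, c = grid.rowcol(cid)
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < grid.n_rows and 0 <= cc < grid.n_cols:
                    n = grid.cell_id(rr, cc)
                    if n not in blob:
                        neigh.add(n)
        if not neigh:
            break
        take = min(len(neigh), size - len(blob))
        picked = rng.choice(sorted(neigh), size=take, replace=False)
        blob.update(int(p) for p in picked)
        frontier = set(int(p) for p in picked)
    return blob


def _allocate_records(n: int, cells: Sequence[int], theta: float,
                      rng: np.random.Generator) -> dict[int, int]:
    """Distribute n records over cells with concentration theta.

    theta = 0 is the uniform limit (plain multinomial with equal
    probabilities); theta > 0 draws cell probabilities from a symmetric
    Dirichlet with concentration 1/theta, so large theta piles records
    into few cells.
    """
    k = len(cells)
    if theta == 0:
        p = np.full(k, 1.0 / k)
    else:
        p = rng.dirichlet(np.full(k, 1.0 / theta))
    counts = rng.multinomial(n, p)
    return {c: int(v) for c, v in zip(cells, counts) if v > 0}


def make_world(config: WorldConfig) -> World:
    """Generate grid, countries, ranges, taxa and point occurrences."""
    grid = build_grid("behrmann", config.cell_size_km,
                      (0.0, 0.0,
                       config.n_cols * config.cell_size_km,
                       config.n_rows * config.cell_size_km))
    countries = _block_countries(grid, config.n_countries)

    rng_ranges = _rng(config.seed, "ranges")
    rng_occ = _rng(config.seed, "occurrences")

    range_rows, taxa_rows = [], []
    species_ranges: dict[str, list[int]] = {}
    for taxon in sorted(config.n_species):
        for i in range(config.n_species[taxon]):
            sp = f"{taxon}_{i:03d}"
            size = int(rng_ranges.integers(config.range_size[0],
                                           config.range_size[1] + 1))
            blob = sorted(_grow_blob(grid, size, rng_ranges))
            species_ranges[sp] = blob
            range_rows.extend((sp, c) for c in blob)
            taxa_rows.append((sp, taxon))
    ranges = pd.DataFrame(range_rows, columns=["species_id", "cell_id"])
    taxa = pd.Series(dict(taxa_rows), name="taxon")

    occ_rows = []
    year0 = min(config.years)
    for sp in sorted(species_ranges):
        cells = species_ranges[sp]
        for year in config.years:
            lam_t = config.lam * (1.0 + config.growth) ** (year - year0)
            n = int(rng_occ.poisson(lam_t))
            if n == 0:
                continue
            for cid, cnt in _allocate_records(n, cells, config.theta,
                                              rng_occ).items():
                lon, lat = grid.cell_center_lonlat(cid)
                occ_rows.extend((sp, lon, lat, year) for _ in range(cnt))
    occurrences = pd.DataFrame(
        occ_rows, columns=["species", "decimalLongitude",
                           "decimalLatitude", "year"])
    return World(config=config, grid=grid, countries=countries,
                 ranges=ranges, taxa=taxa, occurrences=occurrences)


def fig1_fixture() -> World:
    """Exact two-species worked example on a 6x3 grid of 110-km cells.

    Two countries split the grid into left (AAA, 9 cells) and right
    (BBB, 9 cells) halves. Species 1 is endemic to AAA with a 6-cell
    range, 5 of them sampled (national coverage 5/6, stewardship 1).
    Species 2 has a 10-cell global range, 3 cells in AAA (stewardship
    0.3) of which 2 are sampled (national coverage 2/3), and no records
    in BBB. The resulting indices for country AAA are 0.83 and 0.67
    (species SSII), 0.83 and 0.2 (Steward's species SSII), 0.75
    (National SSII) and 0.8 (Steward's National SSII).
    """
    grid = build_grid("behrmann", 110.0, (0.0, 0.0, 660.0, 330.0))
    cols = np.arange(grid.n_cells) % grid.n_cols
    countries = pd.DataFrame({
        "cell_id": np.arange(grid.n_cells),
        "country": np.where(cols < 3, "AAA", "BBB"),
    })
    # species 1: columns 0-1, all 3 rows (6 cells, all in AAA)
    sp1_cells = [grid.cell_id(r, c) for r in range(3) for c in range(2)]
    # species 2: column 2 (3 cells in AAA) + columns 3-5 rows 0-1 minus one
    # (7 cells in BBB) = 10 global cells
    sp2_a = [grid.cell_id(r, 2) for r in range(3)]
    sp2_b = [grid.cell_id(r, c) for r in range(3) for c in range(3, 5)] \
        + [grid.cell_id(0, 5)]
    ranges = pd.DataFrame(
        [("sp1", c) for c in sp1_cells] + [("sp2", c) for c in sp2_a + sp2_b],
        columns=["species_id", "cell_id"])
    taxa = pd.Series({"sp1": "vertebrates", "sp2": "vertebrates"},
                     name="taxon")

    year = 2019
    sampled = [("sp1", c) for c in sp1_cells[:5]] + \
              [("sp2", c) for c in sp2_a[:2]]
    occ_rows = []
    for sp, cid in sampled:
        lon, lat = grid.cell_center_lonlat(cid)
        occ_rows.append((sp, lon, lat, year))
    occurrences = pd.DataFrame(
        occ_rows, columns=["species", "decimalLongitude",
                           "decimalLatitude", "year"])
    config = WorldConfig(n_cols=6, n_rows=3, n_countries=2,
                         n_species={"vertebrates": 2}, years=(year,), seed=0)
    return World(config=config, grid=grid, countries=countries,
                 ranges=ranges, taxa=taxa, occurrences=occurrences)


def figd_counts(n_cells: int, proportion_single: float,
                alt_value: int) -> np.ndarray:
    """Per-cell counts mixing single-record and ``alt_value``-record cells.

    ``round(p * n_cells)`` cells receive one record, the remainder
    receive ``alt_value``. Used to trace the theoretical evenness curves.
    """
    if n_cells < 2:
        raise ValueError("n_cells must be >= 2")
    if not 0.0 <= proportion_single <= 1.0:
        raise ValueError("proportion_single must be in [0, 1]")
    n_single = round(proportion_single * n_cells)
    return np.array([1] * n_single + [alt_value] * (n_cells - n_single),
                    dtype=float)


def trend_scenario(base: float, slope: float, noise_sd: float,
                   years: Sequence[int], seed: int = 0) -> pd.DataFrame:
    """Annual index series ``base + slope * t + Normal(0, noise_sd)``."""
    years = np.asarray(list(years), dtype=int)
    if len(years) < 3:
        raise ValueError("need at least 3 years")
    rng = _rng(seed, "trend")
    t = years - years.min()
    values = base + slope * t + rng.normal(0.0, noise_sd, size=len(years))
    return pd.DataFrame({"year": years, "value": values})
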