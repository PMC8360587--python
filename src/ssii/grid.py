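"""Equal-area analysis grid: projection, cell indexing, gridding of layers.

All spatial layers (species ranges, country boundaries, occurrence points)
are indexed on one shared grid of square cells in a cylindrical equal-area
projection. Cell identifiers are row-major integers starting at 0 in the
lower-left corner. Cell intervals are half-open, ``[x_low, x_high) x
[y_low, y_high)``, so every projected point belongs to at most one cell and
boundary points fall deterministically to the lower-edge cell.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, box
from shapely.geometry.base import BaseGeometry

#: Authalic Earth radius in kilometres (sphere of equal surface area).
EARTH_RADIUS_KM = 6371.007181

#: Sentinel cell id for points outside the grid extent.
OUT_OF_EXTENT = -1

#: Country code for grid cells not claimed by any country.
UNASSIGNED = "UNASSIGNED"

#: Standard parallels of the named cylindrical equal-area projections.
_STANDARD_PARALLELS = {
    "behrmann": 30.0,
    "lambert_cea": 0.0,
    "gall_peters": 45.0,
}


class ConfigurationError(ValueError):
    """Invalid grid or run configuration."""


class InputFormatError(ValueError):
    """A required column or field is missing or malformed."""


@dataclass(frozen=True)
class GridSpec:
    """Definition of the equal-area analysis grid.

    Parameters
    ----------
    projection_id : str
        Named cylindrical equal-area projection (``behrmann``,
        ``lambert_cea`` or ``gall_peters``). Determines the standard
        parallel used to project geographic coordinates.
    cell_size_km : float
        Edge length of the square cells in projected kilometres.
    x0, y0 : float
        Projected coordinates (km) of the grid's lower-left corner.
    n_cols, n_rows : int
        Grid extent in cells.
    """

    projection_id: str
    cell_size_km: float
    x0: float
    y0: float
    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if self.cell_size_km <= 0:
            raise ConfigurationError("cell_size_km must be positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ConfigurationError("grid must have at least one row and column")
        if self.projection_id not in _STANDARD_PARALLELS:
            raise ConfigurationError(
                f"unknown projection {self.projection_id!r}; "
                f"choose from {sorted(_STANDARD_PARALLELS)}"
            )

    # -- identifiers ----------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.n_cols * self.n_rows

    def cell_id(self, row: int, col: int) -> int:
        """Row-major identifier of cell at (row, col), origin lower-left."""
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"(row={row}, col={col}) outside grid")
        return row * self.n_cols + col

    def rowcol(self, cell_id: int) -> tuple[int, int]:
        if not (0 <= cell_id < self.n_cells):
            raise IndexError(f"cell_id {cell_id} outside grid")
        return divmod(cell_id, self.n_cols)

    def cell_bounds(self, cell_id: int) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of a cell in projected km."""
        row, col = self.rowcol(cell_id)
        s = self.cell_size_km
        return (self.x0 + col * s, self.y0 + row * s,
                self.x0 + (col + 1) * s, self.y0 + (row + 1) * s)

    def cell_polygon(self, cell_id: int) -> BaseGeometry:
        return box(*self.cell_bounds(cell_id))

    def cell_center_xy(self, cell_id: int) -> tuple[float, float]:
        xmin, ymin, xmax, ymax = self.cell_bounds(cell_id)
        return (xmin + xmax) / 2.0, (ymin + ymax) / 2.0

    def cell_center_lonlat(self, cell_id: int) -> tuple[float, float]:
        return self.unproject(*self.cell_center_xy(cell_id))

    # -- projection -----------------------------------------------------

    @property
    def _cos_phi_s(self) -> float:
        return math.cos(math.radians(_STANDARD_PARALLELS[self.projection_id]))

    def project(self, lon, lat):
        """Forward cylindrical equal-area projection (degrees -> km)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        c = self._cos_phi_s
        x = EARTH_RADIUS_KM * np.radians(lon) * c
        y = EARTH_RADIUS_KM * np.sin(np.radians(lat)) / c
        return x, y

    def unproject(self, x, y):
        """Inverse projection (km -> degrees)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        c = self._cos_phi_s
        lon = np.degrees(x / (EARTH_RADIUS_KM * c))
        lat = np.degrees(np.arcsin(np.clip(y * c / EARTH_RADIUS_KM, -1.0, 1.0)))
        if lon.ndim == 0:
            return float(lon), float(lat)
        return lon, lat

    # -- point location -------------------------------------------------

    def locate_xy(self, x, y):
        """Cell ids for projected points; OUT_OF_EXTENT beyond the grid."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell_size_km).astype(np.int64)
        row = np.floor((y - self.y0) / self.cell_size_km).astype(np.int64)
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        ids = np.where(inside, row * self.n_cols + col, OUT_OF_EXTENT)
        if ids.ndim == 0:
            return int(ids)
        return ids

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: Mapping) -> "GridSpec":
        return cls(**{k: d[k] for k in
                      ("projection_id", "cell_size_km", "x0", "y0",
                       "n_cols", "n_rows")})

    @classmethod
    def from_json(cls, path) -> "GridSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_grid(projection_id: str, cell_size_km: float,
               extent: tuple[float, float, float, float]) -> GridSpec:
    """Build a grid of square cells tiling a projected bounding box.

    ``extent`` is (xmin, ymin, xmax, ymax) in projected kilometres.
    Partial edge cells are included (column/row counts are rounded up).
    """
    if cell_size_km <= 0:
        raise ConfigurationError("cell_size_km must be positive")
    xmin, ymin, xmax, ymax = extent
    if not (xmax > xmin and ymax > ymin):
        raise ConfigurationError("extent must have positive width and height")
    n_cols = math.ceil((xmax - xmin) / cell_size_km)
    n_rows = math.ceil((ymax - ymin) / cell_size_km)
    return GridSpec(projection_id=projection_id, cell_size_km=cell_size_km,
                    x0=xmin, y0=ymin, n_cols=n_cols, n_rows=n_rows)


def locate_point(grid: GridSpec, lon: float, lat: float) -> int:
    """Cell id of a geographic point, or OUT_OF_EXTENT.

    Raises
    ------
    ValueError
        On non-finite coordinates or coordinates outside the valid
        geographic domain.
    """
    if not (math.isfinite(lon) and math.isfinite(lat)):
        raise ValueError("non-finite coordinates")
    if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
        raise ValueError(f"coordinates out of range: ({lon}, {lat})")
    x, y = grid.project(lon, lat)
    return grid.locate_xy(x, y)


# Column aliases accepted for Darwin-Core-style occurrence tables.
_OCC_ALIASES = {
    "species_id": ("species_id", "species", "scientificName"),
    "lon": ("lon", "decimalLongitude", "longitude"),
    "lat": ("lat", "decimalLatitude", "latitude"),
    "year": ("year",),
}


def _resolve_occurrence_columns(df: pd.DataFrame) -> dict[str, str]:
    resolved = {}
    for canon, aliases in _OCC_ALIASES.items():
        for a in aliases:
            if a in df.columns:
                resolved[canon] = a
                break
        else:
            raise InputFormatError(
                f"occurrence table lacks required column {canon!r} "
                f"(accepted names: {', '.join(aliases)})")
    return resolved


def grid_occurrences(records: pd.DataFrame, grid: GridSpec
                     ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Aggregate point occurrence records to per-(species, year, cell) counts.

    Returns
    -------
    gridded : DataFrame
        Columns ``species_id, year, cell_id, n_records`` with
        ``n_records >= 1``; one row per (species, year, cell).
    rejections : dict
        Tally of dropped rows by reason (``missing_coordinate``,
        ``invalid_coordinate``, ``missing_year``, ``out_of_extent``).
        Kept + rejected always equals the input row count.
    """
    cols = _resolve_occurrence_columns(records)
    df = records[[cols["species_id"], cols["lon"], cols["lat"], cols["year"]]].copy()
    df.columns = ["species_id", "lon", "lat", "year"]
    n_in = len(df)
    rejections = {"missing_coordinate": 0, "invalid_coordinate": 0,
                  "missing_year": 0, "out_of_extent": 0}

    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    missing_coord = lon.isna() | lat.isna()
    rejections["missing_coordinate"] = int(missing_coord.sum())

    invalid = (~missing_coord) & ~(lon.between(-180, 180) & lat.between(-90, 90))
    rejections["invalid_coordinate"] = int(invalid.sum())

    year = pd.to_numeric(df["year"], errors="coerce")
    bad_year = (~missing_coord) & (~invalid) & year.isna()
    rejections["missing_year"] = int(bad_year.sum())

    keep = ~(missing_coord | invalid | bad_year)
    df = df.loc[keep]
    if df.empty:
        gridded = pd.DataFrame(columns=["species_id", "year", "cell_id", "n_records"])
        gridded = gridded.astype({"year": int, "cell_id": int, "n_records": int},
                                 errors="ignore")
        return gridded, rejections

    x, y = grid.project(lon[keep].to_numpy(), lat[keep].to_numpy())
    cell = grid.locate_xy(x, y)
    out = cell == OUT_OF_EXTENT
    rejections["out_of_extent"] = int(out.sum())

    kept = pd.DataFrame({
        "species_id": df["species_id"].to_numpy()[~out],
        "year": year[keep].to_numpy()[~out].astype(int),
        "cell_id": cell[~out],
    })
    gridded = (kept.groupby(["species_id", "year", "cell_id"], sort=True)
               .size().rename("n_records").reset_index())
    assert int(gridded["n_records"].sum()) + sum(rejections.values()) == n_in
    return gridded, rejections


def rasterize_polygons(polygons: Sequence[BaseGeometry], grid: GridSpec,
                       rule: str = "any-overlap") -> list[set[int]]:
    """Cells selected by each polygon feature under a selection rule.

    Geometries are in projected grid coordinates (km). Rules:

    - ``any-overlap``: positive intersection area with the cell;
    - ``center-in``: the cell centre lies within the polygon;
    - ``majority-area``: the polygon covers more than half the cell area.
    """
    if rule not in ("any-overlap", "center-in", "majority-area"):
        raise ValueError(f"unknown rasterization rule {rule!r}")
    cell_area = grid.cell_size_km ** 2
    out: list[set[int]] = []
    for i, geom in enumerate(polygons):
        if geom is None or geom.is_empty or not geom.is_valid:
            raise ValueError(f"feature {i}: invalid or empty geometry")
        # restrict the scan to cells whose rows/cols intersect the bbox
        gxmin, gymin, gxmax, gymax = geom.bounds
        c0 = max(0, math.floor((gxmin - grid.x0) / grid.cell_size_km))
        c1 = min(grid.n_cols - 1, math.floor((gxmax - grid.x0) / grid.cell_size_km))
        r0 = max(0, math.floor((gymin - grid.y0) / grid.cell_size_km))
        r1 = min(grid.n_rows - 1, math.floor((gymax - grid.y0) / grid.cell_size_km))
        cells: set[int] = set()
        for row in range(r0, r1 + 1):
            for col in range(c0, c1 + 1):
                cid = grid.cell_id(row, col)
                cell_poly = grid.cell_polygon(cid)
                if rule == "center-in":
                    cx, cy = grid.cell_center_xy(cid)
                    if geom.contains(Point(cx, cy)):
                        cells.add(cid)
                else:
                    a = geom.intersection(cell_poly).area
                    if rule == "any-overlap" and a > 0:
                        cells.add(cid)
                    elif rule == "majority-area" and a > 0.5 * cell_area:
                        cells.add(cid)
        out.append(cells)
    return out


def assign_cells_to_countries(country_layer, grid: GridSpec,
                              fractional: bool = False) -> pd.DataFrame:
    """Assign grid cells to countries.

    ``country_layer`` is either a tabular mapping (DataFrame with columns
    ``cell_id, country``) or a mapping ``{iso3: shapely geometry}`` in
    projected km. Under the default exclusive rule each cell goes to the
    country with the largest overlapped area; ties break to the
    lexicographically smallest ISO3 code; unclaimed cells get
    ``UNASSIGNED``. With ``fractional=True`` (polygon input only) the
    returned table carries an extra ``fraction`` column with per-country
    area shares.

    Returns a DataFrame with columns ``cell_id, country`` (+ ``fraction``),
    covering every cell of the grid.
    """
    if isinstance(country_layer, pd.DataFrame):
        df = country_layer[["cell_id", "country"]].copy()
        df["cell_id"] = df["cell_id"].astype(int)
        conflicts = df.groupby("cell_id")["country"].nunique()
        bad = conflicts[conflicts > 1]
        if len(bad):
            raise InputFormatError(
                f"conflicting country assignment for cell(s) {list(bad.index)[:10]}")
        df = df.drop_duplicates()
        outside = df.loc[(df["cell_id"] < 0) | (df["cell_id"] >= grid.n_cells)]
        if len(outside):
            raise InputFormatError(
                f"cell ids outside grid extent: {sorted(outside['cell_id'])[:10]}")
        full = pd.DataFrame({"cell_id": np.arange(grid.n_cells)})
        full = full.merge(df, on="cell_id", how="left")
        full["country"] = full["country"].fillna(UNASSIGNED)
        if fractional:
            full["fraction"] = 1.0
        return full

    # polygon path: mapping iso3 -> geometry
    rows = []
    for cid in range(grid.n_cells):
        cell_poly = grid.cell_polygon(cid)
        shares = {}
        for iso3 in sorted(country_layer):
            a = country_layer[iso3].intersection(cell_poly).area
            if a > 0:
                shares[iso3] = a
        if not shares:
            rows.append((cid, UNASSIGNED, 1.0))
        elif fractional:
            total = cell_poly.area
            for iso3, a in shares.items():
                rows.append((cid, iso3, a / total))
        else:
            top_area = max(shares.values())
            winners = sorted(k for k, v in shares.items()
                             if math.isclose(v, top_area, rel_tol=1e-12))
            rows.append((cid, winners[0], 1.0))
    out = pd.DataFrame(rows, columns=["cell_id", "country", "fraction"])
    if not fractional:
        out = out.drop(columns="fraction")
    return out
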