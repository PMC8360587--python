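"""Grid construction, point location, gridding and country assignment."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

import ssii
from ssii.grid import (OUT_OF_EXTENT, UNASSIGNED, ConfigurationError,
                       InputFormatError, assign_cells_to_countries,
                       build_grid, grid_occurrences, locate_point,
                       rasterize_polygons)


@pytest.mark.parametrize("extent,cell,cols,rows", [
    ((0, 0, 660, 330), 110, 6, 3),      # exact tiling
    ((0, 0, 650, 330), 110, 6, 3),      # ceil on partial column
    ((0, 0, 660, 330), 55, 12, 6),      # halved cells: 4 children per parent
])
def test_build_grid_tiling(extent, cell, cols, rows):
    g = build_grid("behrmann", cell, extent)
    assert (g.n_cols, g.n_rows) == (cols, rows)
    assert g.n_cells == cols * rows


def test_build_grid_rejects_bad_config():
    with pytest.raises(ConfigurationError):
        build_grid("behrmann", -1, (0, 0, 100, 100))
    with pytest.raises(ConfigurationError):
        build_grid("behrmann", 10, (0, 0, 0, 100))
    with pytest.raises(ConfigurationError):
        ssii.GridSpec("no_such_projection", 10, 0, 0, 2, 2)


def test_cell_id_rowcol_roundtrip():
    g = build_grid("behrmann", 110, (0, 0, 660, 330))
    for cid in range(g.n_cells):
        row, col = g.rowcol(cid)
        assert g.cell_id(row, col) == cid


def test_locate_point_center_and_edges():
    g = build_grid("behrmann", 110, (0, 0, 660, 330))
    # projected centre of cell 7 maps back to 7
    lon, lat = g.cell_center_lonlat(7)
    assert locate_point(g, lon, lat) == 7
    # a point exactly on the shared x-edge of cells 3 and 4 belongs to the
    # cell whose half-open interval contains it (the one on the higher-x
    # side of the boundary, i.e. the lower edge of cell 4)
    xedge = g.cell_bounds(4)[0]
    ymid = g.cell_bounds(4)[1] + g.cell_size_km / 2
    assert g.locate_xy(xedge, ymid) == 4
    assert g.locate_xy(xedge - 1e-9, ymid) == 3
    # beyond the extent
    assert g.locate_xy(-1.0, ymid) == OUT_OF_EXTENT
    with pytest.raises(ValueError):
        locate_point(g, float("nan"), 0.0)
    with pytest.raises(ValueError):
        locate_point(g, 0.0, 95.0)


def test_locate_point_matches_rectangle_scan():
    """Vectorised location equals exhaustive rectangle containment."""
    g = build_grid("behrmann", 110, (0, 0, 660, 330))
    rng = np.random.default_rng(7)
    lon_max, lat_max = g.unproject(660.0, 330.0)
    lons = rng.uniform(-1, lon_max + 1, 100)
    lats = rng.uniform(-1, lat_max + 1, 100)
    for lon, lat in zip(lons, lats):
        x, y = g.project(lon, lat)
        expected = OUT_OF_EXTENT
        for cid in range(g.n_cells):
            xmin, ymin, xmax, ymax = g.cell_bounds(cid)
            if xmin <= x < xmax and ymin <= y < ymax:
                expected = cid
                break
        assert locate_point(g, lon, lat) == expected


def test_grid_occurrences_aggregates_and_validates():
    g = build_grid("behrmann", 110, (0, 0, 660, 330))
    lon, lat = g.cell_center_lonlat(5)
    records = pd.DataFrame({
        "species": ["a"] * 3 + ["bad"],
        "decimalLongitude": [lon] * 3 + [lon],
        "decimalLatitude": [lat] * 3 + [95.0],
        "year": [2000] * 4,
    })
    gridded, rej = grid_occurrences(records, g)
    assert len(gridded) == 1
    assert gridded.iloc[0]["n_records"] == 3
    assert rej["invalid_coordinate"] == 1
    assert int(gridded["n_records"].sum()) + sum(rej.values()) == len(records)


def test_grid_occurrences_matches_manual_groupby():
    g = build_grid("behrmann", 110, (0, 0, 660, 330))
    rng = np.random.default_rng(3)
    cells = rng.integers(0, g.n_cells, 10)
    pts = [g.cell_center_lonlat(c) for c in cells]
    records = pd.DataFrame({
        "species": rng.choice(["a", "b"], 10),
        "decimalLongitude": [p[0] for p in pts],
        "decimalLatitude": [p[1] for p in pts],
        "year": rng.choice([2001, 2002], 10),
    })
    gridded, rej = grid_occurrences(records, g)
    manual = (records.assign(cell_id=list(cells))
              .groupby(["species", "year", "cell_id"]).size())
    assert sum(rej.values()) == 0
    for row in gridded.itertuples():
        assert manual[(row.species_id, row.year, row.cell_id)] == row.n_records
    assert int(gridded["n_records"].sum()) == 10


def test_grid_occurrences_missing_column():
    g = build_grid("behrmann", 110, (0, 0, 660, 330))
    with pytest.raises(InputFormatError, match="year"):
        grid_occurrences(pd.DataFrame({"species": [], "decimalLongitude": [],
                                       "decimalLatitude": []}), g)


def test_resolution_nesting_conserves_totals():
    """Halving the cell size splits each parent into 4 children and
    conserves gridded record totals."""
    coarse = build_grid("behrmann", 110, (0, 0, 660, 330))
    fine = build_grid("behrmann", 55, (0, 0, 660, 330))
    # each fine cell's centre lies in exactly one coarse cell; each coarse
    # cell receives exactly 4 fine centres
    parents = [coarse.locate_xy(*fine.cell_center_xy(c))
               for c in range(fine.n_cells)]
    counts = pd.Series(parents).value_counts()
    assert (counts == 4).all() and len(counts) == coarse.n_cells

    rng = np.random.default_rng(11)
    pts_x = rng.uniform(0, 660, 200)
    pts_y = rng.uniform(0, 330, 200)
    lon, lat = coarse.unproject(pts_x, pts_y)
    records = pd.DataFrame({"species": "s", "decimalLongitude": lon,
                            "decimalLatitude": lat, "year": 2000})
    g1, _ = grid_occurrences(records, coarse)
    g2, _ = grid_occurrences(records, fine)
    assert g1["n_records"].sum() == g2["n_records"].sum() == 200


@pytest.mark.parametrize("rule,expected", [
    ("any-overlap", {2}), ("majority-area", {2}), ("center-in", set()),
])
def test_rasterize_rule_semantics(rule, expected):
    g = build_grid("behrmann", 100, (0, 0, 300, 100))
    # covers 60% of cell 2 only (cell 2 spans x 200-300, y 0-100) in two
    # strips that leave the cell centre (250, 50) uncovered
    from shapely.ops import unary_union
    poly = unary_union([box(200, 0, 230, 100), box(270, 0, 300, 100)])
    assert rasterize_polygons([poly], g, rule)[0] == expected


def test_rasterize_exact_cover_all_rules():
    g = build_grid("behrmann", 100, (0, 0, 300, 100))
    poly = box(0, 0, 300, 100)
    for rule in ("any-overlap", "center-in", "majority-area"):
        assert rasterize_polygons([poly], g, rule)[0] == {0, 1, 2}


def test_rasterize_matches_area_scan():
    """Random polygon against brute-force per-cell intersection areas."""
    g = build_grid("behrmann", 50, (0, 0, 300, 200))
    rng = np.random.default_rng(5)
    pts = rng.uniform([0, 0], [300, 200], (8, 2))
    from shapely.geometry import MultiPoint
    poly = MultiPoint(pts).convex_hull
    got = rasterize_polygons([poly], g, "majority-area")[0]
    expected = {c for c in range(g.n_cells)
                if poly.intersection(g.cell_polygon(c)).area
                > 0.5 * g.cell_size_km ** 2}
    assert got == expected


def test_rasterize_invalid_geometry():
    g = build_grid("behrmann", 100, (0, 0, 300, 100))
    with pytest.raises(ValueError, match="feature 0"):
        rasterize_polygons([box(0, 0, 0, 0)], g)


def test_country_assignment_tabular_partition():
    g = build_grid("behrmann", 100, (0, 0, 400, 100))
    table = pd.DataFrame({"cell_id": [0, 1, 2, 3],
                          "country": ["AAA", "AAA", "BBB", "BBB"]})
    out = assign_cells_to_countries(table, g)
    assert out["country"].value_counts().to_dict() == {"AAA": 2, "BBB": 2}
    assert out["cell_id"].is_unique


def test_country_assignment_majority_and_tiebreak():
    g = build_grid("behrmann", 100, (0, 0, 100, 100))
    # 70/30 split -> majority
    layer = {"AAA": box(0, 0, 70, 100), "BBB": box(70, 0, 100, 100)}
    out = assign_cells_to_countries(layer, g)
    assert out.loc[0, "country"] == "AAA"
    # exact 50/50 -> lexicographically smallest ISO3
    layer = {"COL": box(0, 0, 50, 100), "BRA": box(50, 0, 100, 100)}
    out = assign_cells_to_countries(layer, g)
    assert out.loc[0, "country"] == "BRA"


def test_country_assignment_unassigned_and_conflicts():
    g = build_grid("behrmann", 100, (0, 0, 200, 100))
    out = assign_cells_to_countries({"AAA": box(0, 0, 100, 100)}, g)
    assert out.set_index("cell_id")["country"].to_dict() == {
        0: "AAA", 1: UNASSIGNED}
    with pytest.raises(InputFormatError, match="conflicting"):
        assign_cells_to_countries(
            pd.DataFrame({"cell_id": [0, 0], "country": ["AAA", "BBB"]}), g)


def test_fractional_assignment_shares_sum_to_one():
    g = build_grid("behrmann", 100, (0, 0, 100, 100))
    layer = {"AAA": box(0, 0, 30, 100), "BBB": box(30, 0, 100, 100)}
    out = assign_cells_to_countries(layer, g, fractional=True)
    assert out.groupby("cell_id")["fraction"].sum().iloc[0] == pytest.approx(1)
    assert dict(zip(out["country"], out["fraction"])) == pytest.approx(
        {"AAA": 0.3, "BBB": 0.7})
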