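"""Readers, writers, run configuration and the end-to-end pipeline.

All interchange is delimited text (CSV) with explicit headers; missing
values are written as empty fields, never as 0, because 0 and "missing"
are semantically distinct for SSEI. Every output table is re-readable by
the package's own readers.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .grid import (GridSpec, InputFormatError, assign_cells_to_countries,
                   grid_occurrences, _resolve_occurrence_columns)
from .indices import (species_indices_table, stewardship_table,
                      out_of_range_diagnostics)
from .aggregate import (annual_index_table, trend_table, typology_table,
                        stewardship_preference)

logger = logging.getLogger("ssii")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    occurrences_path: str
    ranges_path: str
    countries_path: str
    grid_path: str
    taxa_path: str | None = None
    years: tuple[int, int] = (2010, 2019)          # inclusive window
    trend_window: tuple[int, int] = (2010, 2019)
    alpha: float = 0.01
    ssei_denominator: str = "sampled"              # or "expected"
    ssei_degenerate: float = math.nan              # value for n_sampled <= 1
    trend_method: str = "ols"                      # or "mk"
    output_dir: str = "ssii_output"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.years[1] < self.years[0]:
            raise ValueError("years window reversed")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("years", "trend_window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if raw.get("ssei_degenerate") is None:
            raw["ssei_degenerate"] = math.nan
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        if math.isnan(d["ssei_degenerate"]):
            d["ssei_degenerate"] = None
        return d


def read_occurrences(path) -> tuple[pd.DataFrame, dict[str, int]]:
    """Read a Darwin-Core-style occurrence table (CSV/TSV, gzip ok).

    Rows with missing coordinates or an unparseable year are dropped and
    tallied in the returned validation report; remaining rows are typed.
    """
    path = Path(path)
    sep = "\t" if ".tsv" in path.suffixes or path.suffix == ".tsv" else ","
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        logger.warning("empty occurrence file: %s", path)
        return (pd.DataFrame(columns=["species", "decimalLongitude",
                                      "decimalLatitude", "year"]),
                {"missing_coordinate": 0, "bad_year": 0})
    cols = _resolve_occurrence_columns(df)
    df = df.rename(columns={v: k for k, v in cols.items()})
    df = df.rename(columns={"species_id": "species",
                            "lon": "decimalLongitude",
                            "lat": "decimalLatitude"})
    report = {"missing_coordinate": 0, "bad_year": 0}
    lon = pd.to_numeric(df["decimalLongitude"], errors="coerce")
    lat = pd.to_numeric(df["decimalLatitude"], errors="coerce")
    bad_coord = lon.isna() | lat.isna()
    year = pd.to_numeric(df["year"], errors="coerce")
    bad_year = (~bad_coord) & year.isna()
    report["missing_coordinate"] = int(bad_coord.sum())
    report["bad_year"] = int(bad_year.sum())
    keep = ~(bad_coord | bad_year)
    out = pd.DataFrame({
        "species": df.loc[keep, "species"],
        "decimalLongitude": lon[keep],
        "decimalLatitude": lat[keep],
        "year": year[keep].astype(int),
    }).reset_index(drop=True)
    return out, report


def write_occurrences(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_cell_layers(range_path, country_path, grid: GridSpec
                     ) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Read range (species_id, cell_id) and country (cell_id, country)
    cell layers, validating ids against the grid.

    Duplicate (species, cell) rows are deduplicated with a warning count;
    conflicting countries for one cell raise a consistency error.
    """
    ranges = pd.read_csv(range_path)
    for col in ("species_id", "cell_id"):
        if col not in ranges.columns:
            raise InputFormatError(f"range layer lacks column {col!r}")
    ranges["cell_id"] = ranges["cell_id"].astype(int)
    bad = ranges.loc[(ranges["cell_id"] < 0)
                     | (ranges["cell_id"] >= grid.n_cells), "cell_id"]
    if len(bad):
        raise InputFormatError(
            f"range cell ids outside grid: {sorted(set(bad))[:10]}")
    n0 = len(ranges)
    ranges = ranges.drop_duplicates(["species_id", "cell_id"]).reset_index(drop=True)
    warnings = {"duplicate_range_rows": n0 - len(ranges)}
    if warnings["duplicate_range_rows"]:
        logger.warning("deduplicated %d duplicate range rows",
                       warnings["duplicate_range_rows"])

    country_df = pd.read_csv(country_path)
    for col in ("cell_id", "country"):
        if col not in country_df.columns:
            raise InputFormatError(f"country layer lacks column {col!r}")
    assignment = assign_cells_to_countries(country_df, grid)
    return ranges, assignment, warnings


def read_taxa(path) -> pd.Series:
    df = pd.read_csv(path)
    for col in ("species_id", "taxon"):
        if col not in df.columns:
            raise InputFormatError(f"taxa mapping lacks column {col!r}")
    return df.set_index("species_id")["taxon"]


def write_world(world, out_dir) -> dict[str, str]:
    """Write a synthetic world in the pipeline's interchange formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "grid": str(out / "grid.json"),
        "occurrences": str(out / "occurrences.csv"),
        "ranges": str(out / "ranges.csv"),
        "countries": str(out / "countries.csv"),
        "taxa": str(out / "taxa.csv"),
    }
    world.grid.to_json(paths["grid"])
    world.occurrences.to_csv(paths["occurrences"], index=False)
    world.ranges.to_csv(paths["ranges"], index=False)
    world.countries.to_csv(paths["countries"], index=False)
    world.taxa.rename_axis("species_id").reset_index().to_csv(
        paths["taxa"], index=False)
    manifest = {"config": _jsonable(asdict(world.config)),
                "version": __version__}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run the full indicator pipeline and write all output tables.

    Stages: read inputs -> grid occurrence points -> stewardship weights
    -> species-year indices -> annual national/global index table ->
    decadal trends -> national typology -> stewardship-preference
    diagnostics. Outputs land in ``config.output_dir`` together with a
    machine-readable run manifest.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read-inputs"
    try:
        grid = GridSpec.from_json(config.grid_path)
        occ, occ_report = read_occurrences(config.occurrences_path)
        ranges, assignment, layer_warnings = read_cell_layers(
            config.ranges_path, config.countries_path, grid)
        if config.taxa_path:
            taxa = read_taxa(config.taxa_path)
        else:
            taxa = pd.Series("all", index=ranges["species_id"].unique())
        logger.info("read %d occurrence rows, %d species ranges",
                    len(occ), ranges["species_id"].nunique())

        stage = "grid-occurrences"
        gridded, rejections = grid_occurrences(occ, grid)
        logger.info("gridded %d records (%s rejected)",
                    int(gridded["n_records"].sum()), sum(rejections.values()))

        stage = "stewardship"
        stewardship = stewardship_table(ranges, assignment)

        stage = "species-indices"
        years = list(range(config.years[0], config.years[1] + 1))
        sp_idx = species_indices_table(
            ranges, assignment, gridded, years, stewardship,
            ssei_denominator=config.ssei_denominator,
            ssei_degenerate=config.ssei_degenerate)

        stage = "aggregate"
        index_table, missing_taxa = annual_index_table(sp_idx, taxa)

        stage = "trends"
        trends_taxon = trend_table(index_table, window=config.trend_window,
                                   alpha=config.alpha,
                                   method=config.trend_method, by_taxon=True)
        trends_country = trend_table(index_table, window=config.trend_window,
                                     alpha=config.alpha,
                                     method=config.trend_method,
                                     by_taxon=False)

        stage = "typology"
        typology = typology_table(trends_country)

        stage = "diagnostics"
        national_means = trend_table(index_table, value_col="national_ssii",
                                     window=config.trend_window,
                                     alpha=config.alpha, by_taxon=False)
        pref = trends_country.merge(
            national_means[["country", "mean_value"]].rename(
                columns={"mean_value": "national_mean"}), on="country")
        pref["pct_difference"] = [
            stewardship_preference(n, s) for n, s in
            zip(pref["national_mean"], pref["mean_value"])]
        pref = pref[["country", "national_mean", "mean_value",
                     "pct_difference"]].rename(
            columns={"mean_value": "stewards_mean"})
        oor = out_of_range_diagnostics(ranges, gridded)

        stage = "write-outputs"
        tables = {
            "species_year_indices": sp_idx,
            "index_table": index_table,
            "trends_by_taxon": trends_taxon,
            "trends_by_country": trends_country,
            "typology": typology,
            "stewardship_preference": pref,
            "stewardship": stewardship,
            "out_of_range_records": oor,
        }
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        manifest = {
            "version": __version__,
            "config": _jsonable(config.to_dict()),
            "validation": {"occurrence_read": occ_report,
                           "gridding_rejections": rejections,
                           **layer_warnings,
                           "species_without_taxon":
                               missing_taxa["species_id"].tolist()},
            "status": "success",
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        return tables
    except Exception:
        (out / "PARTIAL").write_text(f"failed at stage: {stage}\n")
        logger.exception("pipeline failed at stage %s", stage)
        raise
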