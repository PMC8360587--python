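"""National and global aggregation, trend estimation and typologies.

Species-level indices are averaged to annual national and global values
per taxonomic group, change over a decadal window is estimated by
ordinary least squares (with a Mann-Kendall option), and countries are
classified into four types by crossing decadal-mean Steward's SSII
(above/below the global mean) with trend direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grid import UNASSIGNED


def national_ssii(coverages: Sequence[float]) -> float:
    """National SSII: unweighted mean coverage across all species expected
    in a country (species without records contribute 0)."""
    vals = np.asarray(coverages, dtype=float)
    if vals.size == 0:
        return math.nan
    return float(vals.mean())


def stewards_national_ssii(coverages: Sequence[float],
                           weights: Sequence[float]) -> float:
    """Steward's national SSII: stewardship-weighted mean coverage,
    ``sum(w_i c_i) / sum(w_i)``."""
    c = np.asarray(coverages, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if c.size == 0 or w.sum() == 0:
        return math.nan
    return float((w * c).sum() / w.sum())


def national_ssei(values: Sequence[float]) -> float:
    """National SSEI: mean over species with a defined SSEI (species with
    fewer than two sampled cells are excluded); missing if none."""
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return math.nan
    return float(vals.mean())


def pct_species_recorded(expected_species: Iterable,
                         recorded_species: Iterable) -> float:
    """Percentage of expected species with at least one record."""
    expected = set(expected_species)
    if not expected:
        return math.nan
    recorded = set(recorded_species) & expected
    return 100.0 * len(recorded) / len(expected)


def annual_index_table(species_indices: pd.DataFrame,
                       taxa: Mapping | pd.Series,
                       years: Sequence[int] | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate species-year indices to one row per scope-taxon-year.

    Parameters
    ----------
    species_indices : DataFrame
        Output of :func:`ssii.indices.species_indices_table`.
    taxa : mapping or Series
        ``species_id -> taxon`` (e.g. birds/mammals/amphibians/reptiles).
    years : sequence of int, optional
        Restrict to these years (default: all present).

    Returns
    -------
    table : DataFrame
        Columns ``scope, country, taxon, year, national_ssii,
        stewards_ssii, national_ssei, pct_species_recorded, n_records,
        n_species_expected``. Global-scope rows carry the Global SSII in
        the ``national_ssii`` column and an empty country.
    diagnostics : DataFrame
        Species lacking a taxon assignment (excluded from taxon means).
    """
    taxa = pd.Series(dict(taxa)) if not isinstance(taxa, pd.Series) else taxa
    df = species_indices.copy()
    df["taxon"] = df["species_id"].map(taxa)
    missing = (df.loc[df["taxon"].isna(), ["species_id"]]
               .drop_duplicates().reset_index(drop=True))
    df = df[df["taxon"].notna()]
    if years is not None:
        df = df[df["year"].isin(list(years))]
    # UNASSIGNED pseudo-country rows exist to preserve the stewardship sum
    # identity; they are not national estimates.
    df = df[(df["scope"] == "global") | (df["country"] != UNASSIGNED)]

    rows = []
    for (scope, country, taxon, year), g in df.groupby(
            ["scope", "country", "taxon", "year"], sort=True):
        recorded = g.loc[g["n_records"] > 0, "species_id"]
        if scope == "country":
            weights = _country_weights(g)
            stew = stewards_national_ssii(g["ssii"].to_numpy(), weights)
        else:
            stew = math.nan
        rows.append((scope, country, taxon, int(year),
                     national_ssii(g["ssii"].to_numpy()),
                     stew,
                     national_ssei(g["ssei"].to_numpy()),
                     pct_species_recorded(g["species_id"], recorded),
                     int(g["n_records"].sum()),
                     g["species_id"].nunique()))
    table = pd.DataFrame(rows, columns=[
        "scope", "country", "taxon", "year", "national_ssii", "stewards_ssii",
        "national_ssei", "pct_species_recorded", "n_records",
        "n_species_expected"])
    return table, missing


def _country_weights(g: pd.DataFrame) -> np.ndarray:
    if "weight" in g.columns:
        return np.nan_to_num(g["weight"].to_numpy(dtype=float), nan=0.0)
    # fall back to recovering w from stewards_ssii = ssii * w; for
    # zero-coverage species the weight is unrecoverable and treated as 0,
    # slightly biasing the weighted mean, so carrying an explicit weight
    # column is preferred
    return np.where(g["ssii"] > 0,
                    np.divide(g["stewards_ssii"], g["ssii"],
                              out=np.zeros(len(g)), where=(g["ssii"] > 0).to_numpy()),
                    0.0)


@dataclass
class TrendResult:
    """Decadal trend of an annual index series."""

    key: tuple
    window: tuple[int, int]
    mean_value: float
    slope: float
    p_value: float
    trend_class: str            # "increasing" | "decreasing" | "none"
    insufficient_data: bool = False


def decadal_trend(series: pd.DataFrame | Sequence[tuple[int, float]],
                  alpha: float = 0.01,
                  window: tuple[int, int] | None = None,
                  method: str = "ols",
                  key: tuple = ()) -> TrendResult:
    """Trend of an annual (year, value) series within a window.

    Ordinary least squares of value on year with a two-sided t test on
    the slope (default), or Mann-Kendall (``method="mk"``: Theil-Sen
    slope, Kendall tau p value). The series is classed ``increasing`` if
    the slope is positive and p < alpha, ``decreasing`` if negative and
    p < alpha, otherwise ``none``. Fewer than 3 non-missing values give
    class ``none`` with missing slope/p, flagged ``insufficient_data``.
    """
    if isinstance(series, pd.DataFrame):
        years = series["year"].to_numpy(dtype=float)
        values = series["value"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(series), dtype=float)
        years, values = (arr[:, 0], arr[:, 1]) if arr.size else (arr, arr)
    if window is not None:
        m = (years >= window[0]) & (years <= window[1])
        years, values = years[m], values[m]
    else:
        window = (int(years.min()), int(years.max())) if years.size else (0, 0)
    ok = ~np.isnan(values)
    years, values = years[ok], values[ok]

    if len(values) < 3:
        return TrendResult(key=key, window=window,
                           mean_value=float(values.mean()) if len(values) else math.nan,
                           slope=math.nan, p_value=math.nan,
                           trend_class="none", insufficient_data=True)

    if np.allclose(values, values[0]):
        slope, p = 0.0, 1.0
    elif method == "ols":
        fit = stats.linregress(years, values)
        slope, p = float(fit.slope), float(fit.pvalue)
    elif method == "mk":
        tau = stats.kendalltau(years, values)
        slope = float(stats.theilslopes(values, years).slope)
        p = float(tau.pvalue)
    else:
        raise ValueError(f"unknown trend method {method!r}")

    if p < alpha and slope > 0:
        cls = "increasing"
    elif p < alpha and slope < 0:
        cls = "decreasing"
    else:
        cls = "none"
    return TrendResult(key=key, window=window, mean_value=float(values.mean()),
                       slope=slope, p_value=p, trend_class=cls)


def trend_table(index_table: pd.DataFrame, value_col: str = "stewards_ssii",
                window: tuple[int, int] = (2010, 2019), alpha: float = 0.01,
                method: str = "ols", by_taxon: bool = True) -> pd.DataFrame:
    """Decadal trends per country (and taxon) from an annual index table.

    With ``by_taxon=False`` the per-year value is first averaged across
    taxa (mean of class-level indices), giving one series per country.
    """
    df = index_table[index_table["scope"] == "country"].copy()
    if by_taxon:
        keys = ["country", "taxon"]
    else:
        keys = ["country"]
        df = (df.groupby(["country", "year"])[value_col].mean()
              .reset_index())
    rows = []
    for key, g in df.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        res = decadal_trend(
            g.rename(columns={value_col: "value"})[["year", "value"]],
            alpha=alpha, window=window, method=method, key=key)
        rows.append((*key, res.window[0], res.window[1], res.mean_value,
                     res.slope, res.p_value, res.trend_class,
                     res.insufficient_data))
    cols = keys + ["window_start", "window_end", "mean_value", "slope",
                   "p_value", "trend_class", "insufficient_data"]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class TypologyAssignment:
    """One of four national types from status x trend of Steward's SSII."""

    country: str
    quadrant: int               # 1..4, 0 = unclassified
    mean_value: float
    global_mean: float
    trend_class: str


def classify_typology(mean_value: float, global_mean: float,
                      trend_class: str, country: str = "") -> TypologyAssignment:
    """Quadrant from decadal-mean coverage vs the global mean and trend.

    1. below the global mean, no or decreasing trend;
    2. below the global mean, increasing trend;
    3. above the global mean, no or decreasing trend;
    4. above the global mean, increasing trend.

    "Above" is strict; a mean exactly equal to the global mean counts as
    below. "No or decreasing" pools the ``none`` and ``decreasing``
    classes. A missing mean gives quadrant 0 (unclassified).
    """
    if math.isnan(mean_value) or math.isnan(global_mean):
        return TypologyAssignment(country, 0, mean_value, global_mean,
                                  trend_class)
    above = mean_value > global_mean
    increasing = trend_class == "increasing"
    quadrant = {(False, False): 1, (False, True): 2,
                (True, False): 3, (True, True): 4}[(above, increasing)]
    return TypologyAssignment(country, quadrant, mean_value, global_mean,
                              trend_class)


def typology_table(trends: pd.DataFrame) -> pd.DataFrame:
    """Classify every country given its decadal trend row.

    ``trends`` must carry one row per country (``by_taxon=False`` trend
    table, or pre-averaged across taxa). The global mean is the
    unweighted mean of national decadal means.
    """
    per_country = (trends.groupby("country")
                   .agg(mean_value=("mean_value", "mean"))
                   .reset_index())
    if "trend_class" in trends.columns and trends["country"].is_unique:
        per_country = per_country.merge(
            trends[["country", "trend_class"]], on="country")
    else:
        raise ValueError("typology needs one trend row per country; "
                         "build trends with by_taxon=False")
    global_mean = float(per_country["mean_value"].mean())
    rows = [classify_typology(r.mean_value, global_mean, r.trend_class,
                              r.country)
            for r in per_country.itertuples()]
    return pd.DataFrame([(a.country, a.quadrant, a.mean_value, a.global_mean,
                          a.trend_class) for a in rows],
                        columns=["country", "quadrant", "mean_value",
                                 "global_mean", "trend_class"])


def stewardship_preference(national_ssii_value: float,
                           stewards_ssii_value: float) -> float:
    """Percent difference between Steward's and National SSII.

    ``100 * (stewards - national) / national``; positive values indicate
    preferential coverage of species for which the nation holds high
    stewardship. Missing when National SSII is 0.
    """
    if national_ssii_value == 0 or math.isnan(national_ssii_value):
        return math.nan
    return 100.0 * (stewards_ssii_value - national_ssii_value) / national_ssii_value
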