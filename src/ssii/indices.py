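"""Species-level coverage and sampling-effectiveness indices.

Two indices are computed from a species' expected range (a set of
equal-area grid cells) and its occurrence records in a given year:

* **SSII** (Species Status Information Index) — the proportion of
  expected range cells holding at least one record that year. At national
  scope the expected range is restricted to the cells assigned to the
  country; *Steward's* SSII multiplies national coverage by the country's
  stewardship weight (the fraction of the global range it holds), so that
  summing Steward's SSII over countries recovers the global SSII exactly.

* **SSEI** (Species Sampling Effectiveness Index) — the Shannon entropy
  of the per-cell record distribution normalized by its maximum, i.e.
  ``H / ln(n)`` with ``H = -sum p_i ln p_i`` over the ``n`` sampled cells.
  It is 1 for perfectly even sampling, approaches 0 as records pile into
  a single cell, and is undefined (missing) when fewer than two cells are
  sampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import UNASSIGNED


class UndefinedRangeError(ValueError):
    """A species has an empty expected range."""


def species_coverage(expected_cells: Iterable[int],
                     sampled_cells: Iterable[int]) -> float:
    """Proportion of expected cells with records: |sampled| / |expected|.

    ``sampled_cells`` must already be restricted to the expected range.
    """
    expected = set(expected_cells)
    sampled = set(sampled_cells)
    if not expected:
        raise UndefinedRangeError("expected range is empty")
    if not sampled <= expected:
        raise ValueError("sampled cells must be a subset of expected cells")
    return len(sampled) / len(expected)


def stewardship_weights(species_id, expected_cells: Iterable[int],
                        assignment: pd.DataFrame) -> pd.DataFrame:
    """National stewardship of one species: the share of its expected
    range cells falling in each country.

    ``assignment`` maps ``cell_id -> country`` (exclusive). Weights over
    all countries (including UNASSIGNED) sum to 1; an endemic species has
    a single weight of 1.
    """
    expected = sorted(set(expected_cells))
    if not expected:
        raise UndefinedRangeError("expected range is empty")
    lookup = assignment.set_index("cell_id")["country"]
    countries = lookup.reindex(expected).fillna(UNASSIGNED)
    counts = countries.value_counts()
    out = pd.DataFrame({
        "species_id": species_id,
        "country": counts.index,
        "weight": counts.to_numpy() / len(expected),
    })
    return out.sort_values("country").reset_index(drop=True)


def stewardship_table(ranges: pd.DataFrame,
                      assignment: pd.DataFrame) -> pd.DataFrame:
    """Stewardship weights for every species in a range layer.

    ``ranges`` has columns ``species_id, cell_id``. Vectorised
    equivalent of calling :func:`stewardship_weights` per species.
    """
    df = ranges.drop_duplicates(["species_id", "cell_id"]).merge(
        assignment[["cell_id", "country"]], on="cell_id", how="left")
    df["country"] = df["country"].fillna(UNASSIGNED)
    counts = (df.groupby(["species_id", "country"], sort=True)
              .size().rename("n_cells").reset_index())
    totals = counts.groupby("species_id")["n_cells"].transform("sum")
    counts["weight"] = counts["n_cells"] / totals
    return counts[["species_id", "country", "weight"]]


def stewards_species_ssii(national_coverage: float, weight: float) -> float:
    """Steward's species SSII: national coverage times stewardship weight."""
    if not (0.0 <= national_coverage <= 1.0 and 0.0 <= weight <= 1.0):
        raise ValueError("coverage and weight must lie in [0, 1]")
    return national_coverage * weight


def species_global_ssii(expected_cells: Iterable[int],
                        gridded: pd.DataFrame, species_id, year: int) -> float:
    """Global SSII: coverage over the full expected range in one year."""
    expected = set(expected_cells)
    sub = gridded[(gridded["species_id"] == species_id)
                  & (gridded["year"] == year)]
    sampled = set(sub["cell_id"]) & expected
    return species_coverage(expected, sampled)


def species_ssei(record_counts: Sequence[float],
                 denominator: str = "sampled",
                 n_expected: int | None = None,
                 degenerate: float = math.nan) -> float:
    """Normalized Shannon entropy of a species' per-cell record counts.

    Parameters
    ----------
    record_counts : sequence of positive counts
        Records per sampled cell (cells without records are not listed).
    denominator : {"sampled", "expected"}
        Normalize entropy by ``ln(n_sampled)`` (default: evenness across
        the sampled portion of the range) or by ``ln(n_expected)``.
    n_expected : int, optional
        Required when ``denominator="expected"``.
    degenerate : float
        Value returned when the normalizer is undefined (one sampled cell
        under the default, or no records at all). NaN (missing) by
        default; 0.0 or 1.0 may be substituted.

    Returns
    -------
    float in [0, 1], or ``degenerate`` when undefined.
    """
    counts = np.asarray(record_counts, dtype=float)
    if counts.size and np.any(counts <= 0):
        raise ValueError("record counts must be positive")
    n = counts.size
    if denominator == "sampled":
        norm_n = n
    elif denominator == "expected":
        if n_expected is None:
            raise ValueError("n_expected required for denominator='expected'")
        norm_n = n_expected
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if n == 0 or norm_n <= 1:
        return degenerate
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    return h / math.log(norm_n)


@dataclass
class SpeciesYearIndices:
    """Per-species, per-year index bundle at global or national scope."""

    species_id: object
    year: int
    scope: str                  # "global" or "country"
    country: str | None
    n_expected: int
    n_sampled: int
    n_records: int
    ssii: float
    stewards_ssii: float | None  # country scope only
    ssei: float                  # NaN when undefined


def species_year_indices(expected_cells: Iterable[int],
                         stewardship: pd.DataFrame,
                         gridded: pd.DataFrame,
                         species_id, year: int,
                         country: str | None = None,
                         assignment: pd.DataFrame | None = None,
                         ssei_denominator: str = "sampled",
                         ssei_degenerate: float = math.nan
                         ) -> SpeciesYearIndices:
    """All indices for one species-year at global or national scope.

    At national scope the expected cells and records are restricted to
    the country's assigned cells (``assignment`` required) and Steward's
    SSII applies the species' stewardship weight for that country.
    """
    expected = set(expected_cells)
    if not expected:
        raise UndefinedRangeError("expected range is empty")

    stewards = None
    if country is not None:
        if assignment is None:
            raise ValueError("assignment required for national scope")
        lookup = assignment.set_index("cell_id")["country"]
        known = set(lookup.unique()) | {UNASSIGNED}
        if country not in known:
            raise KeyError(f"unknown country code {country!r}")
        expected = {c for c in expected if lookup.get(c, UNASSIGNED) == country}
        if not expected:
            raise UndefinedRangeError(
                f"species {species_id!r} has no expected cells in {country}")

    sub = gridded[(gridded["species_id"] == species_id)
                  & (gridded["year"] == year)
                  & (gridded["cell_id"].isin(expected))]
    sampled = set(sub["cell_id"])
    n_records = int(sub["n_records"].sum())
    ssii = species_coverage(expected, sampled)
    ssei = species_ssei(sub["n_records"].to_numpy(),
                        denominator=ssei_denominator,
                        n_expected=len(expected),
                        degenerate=ssei_degenerate)
    if country is not None:
        w = stewardship[(stewardship["species_id"] == species_id)
                        & (stewardship["country"] == country)]["weight"]
        weight = float(w.iloc[0]) if len(w) else 0.0
        stewards = stewards_species_ssii(ssii, weight)

    return SpeciesYearIndices(
        species_id=species_id, year=year,
        scope="country" if country is not None else "global",
        country=country, n_expected=len(expected), n_sampled=len(sampled),
        n_records=n_records, ssii=ssii, stewards_ssii=stewards, ssei=ssei)


def species_indices_table(ranges: pd.DataFrame,
                          assignment: pd.DataFrame,
                          gridded: pd.DataFrame,
                          years: Sequence[int],
                          stewardship: pd.DataFrame | None = None,
                          ssei_denominator: str = "sampled",
                          ssei_degenerate: float = math.nan) -> pd.DataFrame:
    """Per-species-year index rows for all species, scopes and years.

    Produces one ``global`` row per species-year plus one ``country`` row
    per species-year for every country holding part of the species'
    range. Years without records yield SSII 0 and missing SSEI. Records
    outside a species' expected range are ignored here (they are tallied
    separately as diagnostics).

    Returns a tidy DataFrame with columns ``species_id, scope, country,
    year, n_expected, n_sampled, n_records, ssii, weight, stewards_ssii,
    ssei`` (``weight`` is the national stewardship weight, defined for
    country rows only).
    """
    if stewardship is None:
        stewardship = stewardship_table(ranges, assignment)
    ranges = ranges.drop_duplicates(["species_id", "cell_id"])
    cell_country = assignment.set_index("cell_id")["country"]

    # annotate ranges with country; n_expected per species x country
    rng = ranges.copy()
    rng["country"] = cell_country.reindex(rng["cell_id"]).fillna(UNASSIGNED).to_numpy()

    # keep only in-range records, annotated with country
    rec = gridded.merge(rng, on=["species_id", "cell_id"], how="inner")

    rows = []
    weights = stewardship.set_index(["species_id", "country"])["weight"]
    for species_id, srng in rng.groupby("species_id", sort=True):
        n_expected_global = len(srng)
        n_exp_by_country = srng.groupby("country").size()
        srec_all = rec[rec["species_id"] == species_id]
        for year in years:
            srec = srec_all[srec_all["year"] == year]
            # global scope
            counts = srec["n_records"].to_numpy()
            rows.append((species_id, "global", "", year, n_expected_global,
                         len(srec), int(counts.sum()),
                         len(srec) / n_expected_global, math.nan, math.nan,
                         species_ssei(counts, ssei_denominator,
                                      n_expected_global, ssei_degenerate)))
            # national scopes
            by_country = dict(tuple(srec.groupby("country")))
            for country, n_exp in n_exp_by_country.items():
                crec = by_country.get(country)
                if crec is None:
                    n_sampled, n_rec, ccounts = 0, 0, np.empty(0)
                else:
                    n_sampled = len(crec)
                    n_rec = int(crec["n_records"].sum())
                    ccounts = crec["n_records"].to_numpy()
                cov = n_sampled / n_exp
                w = float(weights.get((species_id, country), 0.0))
                rows.append((species_id, "country", country, year, int(n_exp),
                             n_sampled, n_rec, cov, w, cov * w,
                             species_ssei(ccounts, ssei_denominator,
                                          int(n_exp), ssei_degenerate)))
    return pd.DataFrame(rows, columns=[
        "species_id", "scope", "country", "year", "n_expected", "n_sampled",
        "n_records", "ssii", "weight", "stewards_ssii", "ssei"])


def out_of_range_diagnostics(ranges: pd.DataFrame,
                             gridded: pd.DataFrame) -> pd.DataFrame:
    """Records falling outside their species' expected range.

    These are excluded from SSII/SSEI (the indices are defined relative
    to the expected range) and reported per species and year.
    """
    merged = gridded.merge(
        ranges.drop_duplicates(["species_id", "cell_id"]).assign(_in=True),
        on=["species_id", "cell_id"], how="left")
    out = merged[merged["_in"].isna()]
    return (out.groupby(["species_id", "year"])["n_records"].sum()
            .rename("n_out_of_range_records").reset_index())
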