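"""Assemblage time-series standardization.

Samples are partitioned into equal-area spatial units; each (study, unit)
pair defines one assemblage time series. Years with poor sampling coverage
are removed, sampling effort is equalized across years by repeated
sample-based rarefaction, and short or species-poor series are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SpatialUnitGrid",
    "RarefiedIteration",
    "assign_spatial_units",
    "sample_coverage",
    "filter_by_coverage",
    "rarefy_timeseries",
    "apply_series_filters",
]

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class SpatialUnitGrid:
    """Deterministic equal-area square grid keyed by cell area.

    Marine samples use ~96 km^2 cells and freshwater samples ~99 km^2 cells,
    matching the areas of the hexagonal grid and subbasin layers they stand
    in for. Coordinates are mapped through a sinusoidal equal-area projection
    anchored at (0, 0), so every (lat, lon) falls in exactly one cell.
    """

    cell_area_km2_marine: float = 96.0
    cell_area_km2_freshwater: float = 99.0

    def cell_area(self, realm: str) -> float:
        area = (
            self.cell_area_km2_freshwater
            if realm == "freshwater"
            else self.cell_area_km2_marine
        )
        if area <= 0:
            raise ValueError("cell area must be positive")
        return area

    def cell_id(self, lat, lon, realm: str) -> np.ndarray:
        side = np.sqrt(self.cell_area(realm))
        lat_r = np.deg2rad(np.asarray(lat, float))
        lon_r = np.deg2rad(np.asarray(lon, float))
        x = EARTH_RADIUS_KM * lon_r * np.cos(lat_r)
        y = EARTH_RADIUS_KM * lat_r
        ix = np.floor(x / side).astype(int)
        iy = np.floor(y / side).astype(int)
        return np.char.add(
            np.char.add(ix.astype(str), "_"), iy.astype(str)
        )


@dataclass
class RarefiedIteration:
    """One rarefaction draw: every year of a series has the same sample count."""

    iteration_index: int
    table: pd.DataFrame


def assign_spatial_units(
    table: pd.DataFrame, grid: SpatialUnitGrid | None = None
) -> pd.DataFrame:
    """Assign each sample to a grid cell; (study_id, unit_id) keys a series.

    Rows with missing or out-of-range coordinates are rejected with a logged
    reason. The returned table's ``unit_id`` column is replaced by the grid
    cell identifier (prefixed with the realm so marine and freshwater grids
    cannot collide).
    """
    grid = grid or SpatialUnitGrid()
    out = table.reset_index(drop=True).copy()
    lat = pd.to_numeric(out["latitude"], errors="coerce")
    lon = pd.to_numeric(out["longitude"], errors="coerce")
    bad = lat.isna() | lon.isna() | (lat < -90) | (lat > 90) | (lon < -180) | (lon >= 180)
    if bad.any():
        logger.warning(
            "rejecting %d rows with missing/out-of-range coordinates", int(bad.sum())
        )
        out = out[~bad].reset_index(drop=True)
        lat = lat[~bad].reset_index(drop=True)
        lon = lon[~bad].reset_index(drop=True)
    units = np.empty(len(out), dtype=object)
    for realm, idx in out.groupby("realm").groups.items():
        loc = out.index.get_indexer(idx)
        units[loc] = [
            f"{realm[:1]}{c}"
            for c in grid.cell_id(lat.loc[idx], lon.loc[idx], str(realm))
        ]
    out["unit_id"] = units
    return out


def sample_coverage(abundances, method: str = "estimator") -> float:
    """Abundance-based sample coverage of one pooled annual sample.

    ``estimator`` (default) returns the singleton/doubleton coverage
    estimator

        C-hat = 1 - (f1/n) * [(n-1) f1 / ((n-1) f1 + 2 f2)],

    the estimated fraction of individuals in the community belonging to
    species detected in the sample. ``richness_ratio`` instead returns the
    ratio of observed to Chao1-estimated species richness — an alternative
    reading of "coverage" that some standardization workflows use.
    """
    a = np.asarray(abundances)
    if a.size == 0:
        raise ValueError("abundance vector is empty")
    if not np.issubdtype(a.dtype, np.number) or (a < 1).any():
        raise ValueError("abundances must be positive counts")
    n = a.sum()
    f1 = int((a == 1).sum())
    f2 = int((a == 2).sum())
    if method == "estimator":
        if n <= 1:
            return 0.0
        denom = (n - 1) * f1 + 2 * f2
        if denom == 0:
            return 1.0
        return float(1.0 - (f1 / n) * ((n - 1) * f1 / denom))
    if method == "richness_ratio":
        s_obs = a.size
        chao1 = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
        return float(s_obs / chao1)
    raise ValueError(f"unknown coverage method: {method!r}")


def filter_by_coverage(
    table: pd.DataFrame, threshold: float = 0.85, method: str = "estimator"
) -> pd.DataFrame:
    """Drop series-years whose pooled annual coverage falls below threshold.

    Coverage is computed on species abundances pooled over the year's samples
    within each (study, unit) series.
    """
    if "abundance" not in table.columns:
        raise ValueError("abundance column required for the coverage filter")
    if table.empty or threshold <= 0:
        return table.copy()
    pooled = (
        table.groupby(["study_id", "unit_id", "year", "species_id"])["abundance"]
        .sum()
        .reset_index()
    )
    keep_keys = set()
    n_dropped = 0
    for key, grp in pooled.groupby(["study_id", "unit_id", "year"]):
        cov = sample_coverage(grp["abundance"].to_numpy(), method=method)
        if cov >= threshold:
            keep_keys.add(key)
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("coverage filter removed %d series-years", n_dropped)
    idx = pd.MultiIndex.from_frame(table[["study_id", "unit_id", "year"]])
    return table[idx.isin(keep_keys)].copy()


def rarefy_timeseries(
    table: pd.DataFrame, n_iterations: int = 100, seed: int = 0
) -> list[RarefiedIteration]:
    """Equalize the number of samples per year by repeated random subsampling.

    For every (study, unit) series, each year's samples are subsampled
    without replacement down to the series' minimum annual sample count.
    Samples taken in the series' modal climatic season are preferred; the
    remaining slots (and ties) are filled uniformly at random. Repeated
    ``n_iterations`` times with an independent draw each; deterministic
    given ``seed``. Rows are never mutated — rarefaction only selects samples.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    # per-series bookkeeping: modal season, per-year sample ids, min count
    samples = (
        table[["study_id", "unit_id", "year", "season", "sample_id"]]
        .drop_duplicates()
        .sort_values(["study_id", "unit_id", "year", "sample_id"])
    )
    series_info = []
    for (study, unit), ser in samples.groupby(["study_id", "unit_id"]):
        modal_season = ser["season"].mode().iloc[0]
        per_year = {
            yr: list(zip(g["sample_id"], g["season"]))
            for yr, g in ser.groupby("year")
        }
        k = min(len(v) for v in per_year.values())
        series_info.append((study, unit, modal_season, per_year, k))

    iterations = []
    for it in range(1, n_iterations + 1):
        chosen: list[str] = []
        for study, unit, modal, per_year, k in series_info:
            for yr, sample_seasons in per_year.items():
                keys = rng.random(len(sample_seasons))
                ranked = sorted(
                    range(len(sample_seasons)),
                    key=lambda i: (sample_seasons[i][1] != modal, keys[i]),
                )
                chosen.extend(sample_seasons[i][0] for i in ranked[:k])
        sub = table[table["sample_id"].isin(chosen)].copy()
        iterations.append(RarefiedIteration(iteration_index=it, table=sub))
    return iterations


def apply_series_filters(
    table: pd.DataFrame,
    min_species: int = 5,
    min_duration_years: int = 2,
    min_sampled_years: int = 2,
) -> pd.DataFrame:
    """Keep only series with enough species, span and sampled years.

    ``min_species`` counts distinct species across the whole sampling period
    of a series; ``min_duration_years`` is the inclusive first-to-last-year
    span; ``min_sampled_years`` the number of distinct years sampled. The
    operation is idempotent.
    """
    if table.empty:
        return table.copy()
    keep = []
    for key, grp in table.groupby(["study_id", "unit_id"]):
        n_sp = grp["species_id"].nunique()
        years = grp["year"].unique()
        span = int(years.max() - years.min() + 1)
        if (
            n_sp >= min_species
            and span >= min_duration_years
            and len(years) >= min_sampled_years
        ):
            keep.append(key)
        else:
            logger.info(
                "dropping series %s: %d species, span %d, %d sampled years",
                key, n_sp, span, len(years),
            )
    idx = pd.MultiIndex.from_frame(table[["study_id", "unit_id"]])
    return table[idx.isin(keep)].copy()
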