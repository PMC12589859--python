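"""Macroecological covariates for non-native plants.

Builds the four predictors of trophic integration — introduced range size
(area of occupancy on an equal-area grid), earliest introduction year,
great-circle distance from the native-range centroid to the continental
reference point, and taxonomic relatedness to the native flora — plus
genus-mode imputation of the woodiness growth form.

Grid cells are abstract integer indices: no map projection is performed and
a cell contributes its full nominal area when occupied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EUROPE_CENTROID",
    "EARTH_RADIUS_KM",
    "ImputationReport",
    "fill_woodiness",
    "classify_relatedness",
    "native_centroid",
    "great_circle_km",
    "apply_proximity_exclusion",
    "compute_aoo",
    "earliest_introduction",
]

#: centroid of the merged European botanical countries (lat, lon)
EUROPE_CENTROID = (59.56, 28.21)

#: mean Earth radius, km
EARTH_RADIUS_KM = 6371.0088

UNKNOWN = "unknown"


@dataclass
class ImputationReport:
    n_imputed: int
    n_unresolved: int


def fill_woodiness(
    plants: pd.DataFrame,
    woodiness_col: str = "woodiness",
    genus_col: str = "genus",
) -> tuple[pd.DataFrame, ImputationReport]:
    """Impute missing woodiness states by the modal state within the genus.

    Observed states are never overwritten.  A genus with no observed state,
    or with a tie between states, leaves its unknowns unresolved (a mode is
    undefined at a tie).  NaN entries are treated as unknown.
    """
    plants = plants.copy()
    state = plants[woodiness_col].fillna(UNKNOWN)
    observed = state != UNKNOWN

    def genus_mode(s: pd.Series) -> str:
        counts = s[s != UNKNOWN].value_counts()
        if counts.empty:
            return UNKNOWN
        if len(counts) > 1 and counts.iloc[0] == counts.iloc[1]:
            return UNKNOWN
        return counts.index[0]

    modes = state.groupby(plants[genus_col]).agg(genus_mode)
    fill = plants[genus_col].map(modes)
    out = state.where(observed, fill)
    n_imputed = int(((out != UNKNOWN) & ~observed).sum())
    n_unresolved = int((out == UNKNOWN).sum())
    plants[woodiness_col] = out
    logger.info(
        "woodiness gap-fill: %d imputed from genus mode, %d unresolved",
        n_imputed, n_unresolved,
    )
    return plants, ImputationReport(n_imputed, n_unresolved)


def classify_relatedness(
    nonnative_plants: pd.DataFrame,
    native_genera: set[str],
    native_families: set[str],
) -> pd.Series:
    """Label each non-native as congeneric, confamilial or unrelated.

    Congeneric: shares a genus with at least one native species; confamilial:
    shares only a family; unrelated: neither.  The three labels partition the
    non-native set.
    """
    congeneric = nonnative_plants["genus"].isin(native_genera)
    confamilial = ~congeneric & nonnative_plants["family"].isin(native_families)
    out = pd.Series(
        np.select([congeneric, confamilial], ["congeneric", "confamilial"], "unrelated"),
        index=nonnative_plants.index,
        name="relatedness",
    )
    return out


def native_centroid(
    region_codes: list[str], region_centroids: pd.DataFrame
) -> tuple[float, float]:
    """Unweighted mean of the region centroids of a species' native range.

    Averaging is done on latitude/longitude directly; longitudes are not
    wrapped, so ranges straddling the antimeridian average poorly (a known
    limitation of centroid averaging over disjunct ranges).
    """
    if not region_codes:
        raise ValueError("species has no native regions")
    table = region_centroids.set_index("region_code") if "region_code" in region_centroids.columns else region_centroids
    missing = [c for c in region_codes if c not in table.index]
    if missing:
        raise KeyError(f"no centroid entry for region(s) {missing}")
    sub = table.loc[region_codes]
    return float(sub["lat"].mean()), float(sub["lon"].mean())


def _check_coords(lat: np.ndarray, lon: np.ndarray) -> None:
    if np.any(~np.isfinite(lat)) or np.any(~np.isfinite(lon)):
        raise ValueError("non-finite coordinate")
    if np.any(np.abs(lat) > 90.0) or np.any(np.abs(lon) > 360.0):
        raise ValueError("coordinate out of range")


def great_circle_km(lat1, lon1, lat2, lon2):
    """Haversine great-circle distance in km on a sphere of mean Earth radius.

    Accepts scalars or arrays; symmetric, non-negative, at most half the
    Earth's circumference.
    """
    lat1, lon1, lat2, lon2 = map(np.asarray, (lat1, lon1, lat2, lon2))
    _check_coords(lat1, lon1)
    _check_coords(lat2, lon2)
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = np.radians(lat2 - lat1)
    dlam = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


def apply_proximity_exclusion(
    plants: pd.DataFrame, threshold_km: float = 2500.0,
    dist_col: str = "centroid_dist_km",
) -> tuple[pd.DataFrame, int]:
    """Drop species whose native-range centroid lies within ``threshold_km``.

    Guards against artificial proximity from averaging disjunct ranges.
    Strictly-less-than: a species exactly at the threshold is retained.
    """
    close = plants[dist_col] < threshold_km
    n_removed = int(close.sum())
    logger.info("proximity exclusion (<%g km): removed %d species", threshold_km, n_removed)
    return plants.loc[~close].copy(), n_removed


def compute_aoo(
    cell_ids: set, region_cells: set, cell_area_km2: float = 2500.0
) -> float:
    """Area of occupancy: occupied cells inside the region × cell area."""
    if not region_cells:
        raise ValueError("region_cells must be non-empty")
    if cell_area_km2 <= 0:
        raise ValueError("cell_area_km2 must be positive")
    return len(set(cell_ids) & set(region_cells)) * cell_area_km2


def aoo_from_occurrences(
    occurrences: pd.DataFrame,
    region_cells: set[tuple[int, int]],
    cell_area_km2: float = 2500.0,
) -> pd.Series:
    """Per-species AOO from an occurrence table with ``species``, ``i``, ``j``.

    Vectorised equivalent of :func:`compute_aoo` applied species-wise:
    duplicate cells collapse, cells outside the region contribute nothing.
    Species with no in-region cells get 0.
    """
    if not region_cells:
        raise ValueError("region_cells must be non-empty")
    occ = occurrences.drop_duplicates(subset=["species", "i", "j"])
    code = occ["i"].to_numpy(np.int64) * (1 << 20) + occ["j"].to_numpy(np.int64)
    region_code = np.fromiter(
        (i * (1 << 20) + j for i, j in region_cells), dtype=np.int64, count=len(region_cells)
    )
    inside = np.isin(code, region_code)
    counts = occ.loc[inside].groupby("species").size()
    all_species = occ["species"].unique()
    return (
        counts.reindex(all_species, fill_value=0).astype(float) * cell_area_km2
    ).rename("aoo_km2")


def earliest_introduction(
    records: pd.DataFrame, cutoff_year: int = 1492,
    species_col: str = "species", year_col: str = "year",
) -> tuple[pd.Series, int]:
    """Earliest first-record year per species, excluding pre-Columbian records.

    Takes the minimum year over a species' regional records; species whose
    earliest record is at or before ``cutoff_year`` are dropped (the
    operational definition covers introductions after 1492 only) and counted.
    """
    earliest = records.groupby(species_col)[year_col].min()
    keep = earliest > cutoff_year
    n_dropped = int((~keep).sum())
    logger.info("introduction-date cutoff (<=%d): dropped %d species", cutoff_year, n_dropped)
    return earliest[keep], n_dropped
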