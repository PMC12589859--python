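"""Read and validate interaction edge lists; per-plant microherbivory richness.

The interaction table is an edge list of documented plant–microherbivore
associations.  Records identified only to plant genus are excluded, names are
mapped through an optional synonym table before de-duplication, and exact
duplicate associations collapse to one edge.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["read_interactions", "read_plants", "richness_per_plant"]

INTERACTION_COLUMNS = ("plant_name", "herbivore_name")


def _apply_synonyms(names: pd.Series, synonym_map: pd.DataFrame | None) -> pd.Series:
    if synonym_map is None or synonym_map.empty:
        return names
    lookup = dict(zip(synonym_map["name"], synonym_map["accepted_name"]))
    return names.map(lambda n: lookup.get(n, n))


def read_interactions(
    path: str | Path, synonym_map: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Read the interaction edge list.

    Plant names are mapped to accepted names through ``synonym_map`` (columns
    ``name``, ``accepted_name``) when given; genus-only records (single-token
    plant name, or ``plant_rank == 'genus-only'`` if a rank column exists) are
    dropped with a logged count; exact duplicate pairs collapse.
    """
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        raise ValueError(f"empty interaction table: {path}")
    missing = [c for c in INTERACTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"interaction table missing column(s) {missing}")
    if df[list(INTERACTION_COLUMNS)].isna().any().any():
        raise ValueError("interaction table contains empty names")

    df["plant_name"] = _apply_synonyms(df["plant_name"], synonym_map)

    if "plant_rank" in df.columns:
        genus_only = df["plant_rank"].eq("genus-only")
    else:
        genus_only = df["plant_name"].str.split().str.len() == 1
    n_genus_only = int(genus_only.sum())
    if n_genus_only:
        logger.info("dropped %d genus-only interaction records", n_genus_only)
    df = df.loc[~genus_only]

    before = len(df)
    df = df.drop_duplicates(subset=list(INTERACTION_COLUMNS)).reset_index(drop=True)
    if before - len(df):
        logger.info("collapsed %d duplicate associations", before - len(df))
    out = df[list(INTERACTION_COLUMNS)]
    out.attrs["n_genus_only_dropped"] = n_genus_only
    out.attrs["n_duplicates_collapsed"] = before - len(df)
    return out


def read_plants(path: str | Path) -> pd.DataFrame:
    """Read the plant attribute table (taxonomy, origin, woodiness, geography)."""
    df = pd.read_csv(path)
    required = ["accepted_name", "genus", "family", "origin"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"plant table missing column(s) {missing}")
    bad = set(df["origin"]) - {"native", "non-native"}
    if bad:
        raise ValueError(f"unrecognised origin values {sorted(bad)}")
    return df


def richness_per_plant(interactions: pd.DataFrame) -> pd.Series:
    """Number of distinct associated microherbivore species per plant.

    Conservation: the richness values sum to the number of distinct
    (plant, herbivore) pairs.
    """
    if interactions.empty:
        raise ValueError("interaction table is empty")
    return (
        interactions.groupby("plant_name")["herbivore_name"]
        .nunique()
        .rename("richness")
    )
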