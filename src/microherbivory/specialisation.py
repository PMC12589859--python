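"""Host breadth and phagy classification of microherbivores.

Host breadth is the number of distinct plant species (native and non-native)
a microherbivore uses across the full dataset.  The categorical host-
specialisation index counts distinct host species, genera and families and
assigns one of four classes, checked narrow to broad:

* monophagous — one host species;
* oligophagous — more than one host species across at most 4 genera within
  a single family;
* mesophagous — more than one host species across more than one genus within
  at most 3 families;
* polyphagous — more than one host species across more than one genus within
  more than 3 families.

The narrow-to-broad precedence resolves the overlap where a multi-genus,
single-family host set satisfies both the oligophagous and mesophagous
conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "PHAGY_CLASSES",
    "host_breadth",
    "classify_phagy",
    "build_profiles",
    "per_plant_mean_breadth",
    "integration_filter",
    "per_plant_composition",
    "composition_summary",
]

PHAGY_CLASSES = ("monophagous", "oligophagous", "mesophagous", "polyphagous")

#: introduced-range-size thresholds (km²) above which a non-native is
#: considered trophically well integrated, by growth form; the woody
#: threshold is lower because the richness–range slope is steeper in woody
#: species
DEFAULT_INTEGRATION_THRESHOLDS = {"non-woody": 1.1e6, "woody": 2.7e5}


def host_breadth(interactions: pd.DataFrame) -> pd.Series:
    """Distinct host-plant species count per microherbivore (>= 1)."""
    if interactions.empty:
        raise ValueError("interaction table is empty")
    return (
        interactions.groupby("herbivore_name")["plant_name"]
        .nunique()
        .rename("n_host_species")
    )


def classify_phagy(n_species: int, n_genera: int, n_families: int) -> str:
    """Assign the host-specialisation class for one (species, genera, families) triple."""
    if not 1 <= n_families <= n_genera <= n_species:
        raise ValueError(
            f"inconsistent host counts: species={n_species}, genera={n_genera}, "
            f"families={n_families} (need 1 <= families <= genera <= species)"
        )
    if n_species == 1:
        return "monophagous"
    if n_genera <= 4 and n_families == 1:
        return "oligophagous"
    if n_genera > 1 and n_families <= 3:
        return "mesophagous"
    return "polyphagous"


def build_profiles(interactions: pd.DataFrame, plants: pd.DataFrame) -> pd.DataFrame:
    """Per-herbivore host counts (species, genera, families) and phagy class.

    ``plants`` supplies the genus/family of each host; interactions with
    plants absent from the table are ignored with no warning (they carry no
    taxonomic information).
    """
    tax = plants.set_index("accepted_name")[["genus", "family"]]
    joined = interactions.join(tax, on="plant_name", how="inner")
    prof = joined.groupby("herbivore_name").agg(
        n_host_species=("plant_name", "nunique"),
        n_host_genera=("genus", "nunique"),
        n_host_families=("family", "nunique"),
    )
    prof["phagy"] = [
        classify_phagy(s, g, f)
        for s, g, f in zip(prof["n_host_species"], prof["n_host_genera"], prof["n_host_families"])
    ]
    return prof


def per_plant_mean_breadth(
    interactions: pd.DataFrame, breadths: pd.Series
) -> pd.Series:
    """Arithmetic mean host breadth of each plant's interaction partners."""
    missing = set(interactions["herbivore_name"]) - set(breadths.index)
    if missing:
        raise KeyError(f"no host breadth for herbivore(s) {sorted(missing)[:5]}")
    joined = interactions.assign(breadth=interactions["herbivore_name"].map(breadths))
    return joined.groupby("plant_name")["breadth"].mean().rename("mean_host_breadth")


def integration_filter(
    plants: pd.DataFrame, thresholds: dict[str, float] | None = None
) -> pd.DataFrame:
    """Keep natives plus non-natives above the growth-form range-size threshold.

    Thresholds are strict: a plant exactly at its threshold is dropped.
    """
    thresholds = DEFAULT_INTEGRATION_THRESHOLDS if thresholds is None else thresholds
    native = plants["origin"].eq("native")
    limit = plants["woodiness"].map(thresholds)
    integrated = plants["aoo_km2"] > limit
    return plants.loc[native | integrated].copy()


def per_plant_composition(
    interactions: pd.DataFrame, profiles: pd.DataFrame
) -> pd.DataFrame:
    """Per-plant proportions of partners in each phagy class (rows sum to 1)."""
    joined = interactions.assign(
        phagy=interactions["herbivore_name"].map(profiles["phagy"])
    )
    if joined["phagy"].isna().any():
        bad = joined.loc[joined["phagy"].isna(), "herbivore_name"].iloc[0]
        raise KeyError(f"herbivore {bad!r} has no phagy classification")
    counts = (
        joined.groupby(["plant_name", "phagy"], observed=True).size().unstack(fill_value=0)
    )
    counts = counts.reindex(columns=PHAGY_CLASSES, fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0)


def composition_summary(
    plants: pd.DataFrame,
    composition: pd.DataFrame,
    by: list[str] | None = None,
    weights: pd.Series | None = None,
) -> pd.DataFrame:
    """Mean per-plant phagy composition within groups.

    ``by`` names grouping columns of ``plants`` (default origin × woodiness).
    ``weights``, if given, is a per-plant weight series (e.g. each plant's
    total recorded interactions); otherwise plants are weighted equally.
    Group rows sum to 1.
    """
    by = ["origin", "woodiness"] if by is None else by
    merged = plants.set_index("accepted_name")[by].join(composition, how="inner")
    w = (
        pd.Series(1.0, index=merged.index)
        if weights is None
        else weights.reindex(merged.index).astype(float)
    )
    if w.isna().any() or (w <= 0).any():
        raise ValueError("weights must be positive and cover every plant")

    def wmean(group: pd.DataFrame) -> pd.Series:
        ww = w.loc[group.index]
        vals = group[list(PHAGY_CLASSES)]
        return vals.mul(ww, axis=0).sum() / ww.sum()

    out = merged.groupby(by, observed=True).apply(wmean, include_groups=False)
    return out


def residence_time_bins(
    intro_years: pd.Series, reference_year: int = 2025, width: int = 50
) -> pd.Series:
    """Bin residence time (years since introduction) into fixed-width bins.

    Returns an ordered categorical labelled by bin start, e.g. ``"100-149"``.
    """
    residence = reference_year - intro_years
    if (residence < 0).any():
        raise ValueError("introduction year after the reference year")
    start = (residence // width) * width
    labels = start.astype(int).map(lambda s: f"{s}-{s + width - 1}")
    order = [f"{s}-{s + width - 1}" for s in sorted(start.dropna().astype(int).unique())]
    return pd.Series(
        pd.Categorical(labels, categories=order, ordered=True),
        index=intro_years.index,
        name="residence_bin",
    )
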