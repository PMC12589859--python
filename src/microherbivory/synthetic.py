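"""Synthetic bipartite plant–microherbivore networks with known ground truth.

The generator emulates the statistical structure of a continent-wide
plant–microherbivore association dataset: a flora of roughly 10,000 species
split into native/non-native and woody/non-woody groups, a heavy-tailed
per-plant richness distribution (mode 1) driven by a log-linear latent model
with family-level random intercepts, and a herbivore pool spanning the
monophagous-to-polyphagous spectrum with strict specialists concentrated on
native hosts.

Every realised quantity (covariates as the pipeline will recompute them, the
latent linear predictor, per-plant richness) is recorded in a
:class:`SyntheticTruth` so downstream stages can be tested for exact
bookkeeping and for statistical parameter recovery.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .covariates import EUROPE_CENTROID, great_circle_km

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_flora",
    "generate_interactions",
    "write_dataset",
]

EARTH_RADIUS_KM = 6371.0088

# Grid-cell indices 0..(GRID_SIDE-1) on each axis lie inside the focal region.
GRID_SIDE = 100


@dataclass
class SyntheticConfig:
    """Generating parameters for a synthetic flora and interaction network.

    Group sizes default to the composition of the European analysis set
    (5751/1061 native and 2074/1379 non-native non-woody/woody species).
    Slopes are on the log10-richness scale: per log10 km² of introduced
    range, per calendar year of introduction, and per km of native-range
    centroid distance.  Intercepts are calibrated so that group mean
    richness on the raw scale is realistic for a European-style dataset
    (about 6.2 and 4.1 for native woody/non-woody, 2.2 and 1.8 for
    non-native) given the lognormal noise.
    """

    n_native_nonwoody: int = 5751
    n_native_woody: int = 1061
    n_nonnative_nonwoody: int = 2074
    n_nonnative_woody: int = 1379
    n_families: int = 157
    genera_per_family: int = 10

    beta_range_nonwoody: float = 0.218
    beta_range_woody: float = 0.308
    beta_year_nonwoody: float = -0.00097
    beta_year_woody: float = -0.0014
    beta_dist: float = -2.31e-5

    intercept_native_nonwoody: float = 0.4583
    intercept_native_woody: float = 0.6327
    intercept_nonnative_nonwoody: float = 0.9010
    intercept_nonnative_woody: float = 1.2695

    sd_family: float = 0.12
    sd_resid: float = 0.35

    specialist_fraction: float = 0.4
    specialist_native_pref: float = 0.9
    generalist_breadth_mean: float = 5.0

    missing_woodiness_fraction: float = 0.05
    year_range: tuple[int, int] = (1493, 2000)
    dist_range_km: tuple[float, float] = (2654.0, 17523.0)
    cell_count_range: tuple[int, int] = (1, 4000)
    cell_area_km2: float = 2500.0
    outside_cell_fraction: float = 0.1
    max_regions_per_species: int = 3

    synonym_fraction: float = 0.02
    n_genus_only: int = 50

    seed: int = 0

    def validate(self) -> None:
        counts = (
            self.n_native_nonwoody,
            self.n_native_woody,
            self.n_nonnative_nonwoody,
            self.n_nonnative_woody,
            self.n_families,
            self.genera_per_family,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if self.n_total_plants == 0:
            raise ValueError("configuration generates zero plants")
        if self.n_families == 0 or self.genera_per_family == 0:
            raise ValueError("need at least one family and one genus per family")
        if self.sd_family < 0 or self.sd_resid < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0.0 <= self.specialist_fraction <= 1.0:
            raise ValueError("specialist_fraction must lie in [0, 1]")
        if not 0.0 <= self.missing_woodiness_fraction <= 1.0:
            raise ValueError("missing_woodiness_fraction must lie in [0, 1]")
        if self.generalist_breadth_mean < 2.0:
            raise ValueError("generalist_breadth_mean must be >= 2")

    @property
    def n_total_plants(self) -> int:
        return (
            self.n_native_nonwoody
            + self.n_native_woody
            + self.n_nonnative_nonwoody
            + self.n_nonnative_woody
        )

    def intercept(self, origin: str, woodiness: str) -> float:
        key = f"intercept_{origin.replace('-', '')}_{woodiness.replace('-', '')}"
        return getattr(self, key)


@dataclass
class SyntheticTruth:
    """Realised generating quantities of one simulated dataset."""

    config: SyntheticConfig
    family_effects: dict[str, float]
    #: per plant: linear predictor including the family effect (expected
    #: log10 richness) and the realised integer richness
    latent_log10_richness: pd.Series = field(repr=False, default=None)
    richness: pd.Series = field(repr=False, default=None)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": dataclasses.asdict(self.config),
            "family_effects": self.family_effects,
            "latent_log10_richness": self.latent_log10_richness.to_dict(),
            "richness": {k: int(v) for k, v in self.richness.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Deterministic independent RNG streams derived from one seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _destination_point(lat: float, lon: float, bearing_deg: float, dist_km: float) -> tuple[float, float]:
    """Point reached travelling ``dist_km`` on a great circle from (lat, lon)."""
    delta = dist_km / EARTH_RADIUS_KM
    theta = math.radians(bearing_deg)
    phi1, lam1 = math.radians(lat), math.radians(lon)
    phi2 = math.asin(
        math.sin(phi1) * math.cos(delta) + math.cos(phi1) * math.sin(delta) * math.cos(theta)
    )
    lam2 = lam1 + math.atan2(
        math.sin(theta) * math.sin(delta) * math.cos(phi1),
        math.cos(delta) - math.sin(phi1) * math.sin(phi2),
    )
    lon2 = (math.degrees(lam2) + 540.0) % 360.0 - 180.0
    return math.degrees(phi2), lon2


def generate_flora(config: SyntheticConfig) -> pd.DataFrame:
    """Generate the plant attribute table.

    Returns one row per species with nested family/genus labels, origin,
    true and observed (possibly masked) woodiness, occupied grid cells,
    introduction year and native-range centroid for non-natives, and the
    realised covariates exactly as the pipeline will recompute them
    (``aoo_km2`` from in-region cells, ``centroid_dist_km`` from the mean of
    the species' region centroids to the fixed continental reference point).
    """
    config.validate()
    rng_tax, rng_cells, rng_year, rng_geo, rng_mask = _rngs(config.seed, 5)

    groups = [
        ("native", "non-woody", config.n_native_nonwoody),
        ("native", "woody", config.n_native_woody),
        ("non-native", "non-woody", config.n_nonnative_nonwoody),
        ("non-native", "woody", config.n_nonnative_woody),
    ]
    rows: list[dict] = []
    counter = 0
    for origin, woodiness, n in groups:
        for _ in range(n):
            fam_i = int(rng_tax.integers(config.n_families))
            gen_i = int(rng_tax.integers(config.genera_per_family))
            family = f"Fam{fam_i:03d}"
            genus = f"Gen{fam_i:03d}x{gen_i}"
            name = f"{genus} sp{counter}"
            rows.append(
                {
                    "accepted_name": name,
                    "genus": genus,
                    "family": family,
                    "origin": origin,
                    "woodiness_true": woodiness,
                }
            )
            counter += 1
    plants = pd.DataFrame(rows)

    n_plants = len(plants)
    # occupied cells: log-uniform count, cells mostly inside the focal region
    lo, hi = config.cell_count_range
    counts = np.floor(
        10 ** rng_cells.uniform(math.log10(lo), math.log10(hi + 1), n_plants)
    ).astype(int)
    counts = np.clip(counts, lo, hi)
    n_region_cells = GRID_SIDE * GRID_SIDE
    cells_in: list[list[int]] = []
    cells_out: list[list[int]] = []
    for k in counts:
        inside = rng_cells.choice(n_region_cells, size=int(k), replace=False)
        n_out = int(round(config.outside_cell_fraction * k))
        outside = n_region_cells + rng_cells.choice(n_region_cells, size=n_out, replace=False)
        cells_in.append(inside.tolist())
        cells_out.append(outside.tolist())
    plants["cells_inside"] = cells_in
    plants["cells_outside"] = cells_out
    plants["aoo_km2"] = np.where(
        plants["origin"].eq("non-native"), counts * config.cell_area_km2, np.nan
    )

    nonnative = plants["origin"].eq("non-native").to_numpy()
    n_nn = int(nonnative.sum())

    years = np.full(n_plants, np.nan)
    years[nonnative] = rng_year.integers(
        config.year_range[0], config.year_range[1] + 1, n_nn
    )
    plants["intro_year"] = years

    # place native-range region centroids so the realised centroid distance
    # spans the configured range
    target_dist = rng_geo.uniform(*config.dist_range_km, n_nn)
    bearings = rng_geo.uniform(0.0, 360.0, n_nn)
    n_regions = rng_geo.integers(1, config.max_regions_per_species + 1, n_nn)
    region_codes_col: list[str] = [""] * n_plants
    centroid_lat = np.full(n_plants, np.nan)
    centroid_lon = np.full(n_plants, np.nan)
    dist_col = np.full(n_plants, np.nan)
    region_registry: dict[str, tuple[float, float]] = {}
    nn_positions = np.flatnonzero(nonnative)
    for j, pos in enumerate(nn_positions):
        lat0, lon0 = _destination_point(*EUROPE_CENTROID, bearings[j], target_dist[j])
        codes = []
        lats, lons = [], []
        for r in range(int(n_regions[j])):
            code = f"R{pos:05d}{r}"
            lat = float(np.clip(lat0 + rng_geo.uniform(-0.5, 0.5), -89.9, 89.9))
            lon = (lon0 + rng_geo.uniform(-0.5, 0.5) + 540.0) % 360.0 - 180.0
            region_registry[code] = (lat, lon)
            codes.append(code)
            lats.append(lat)
            lons.append(lon)
        region_codes_col[pos] = ";".join(codes)
        clat, clon = float(np.mean(lats)), float(np.mean(lons))
        centroid_lat[pos] = clat
        centroid_lon[pos] = clon
        dist_col[pos] = great_circle_km(clat, clon, *EUROPE_CENTROID)
    plants["native_regions"] = region_codes_col
    plants["centroid_lat"] = centroid_lat
    plants["centroid_lon"] = centroid_lon
    plants["centroid_dist_km"] = dist_col
    plants.attrs["region_centroids"] = region_registry

    # mask a fraction of woodiness states to exercise genus-mode imputation
    observed = plants["woodiness_true"].copy()
    mask = rng_mask.random(n_plants) < config.missing_woodiness_fraction
    observed[mask] = "unknown"
    plants["woodiness"] = observed

    return plants


def _latent_predictor(plants: pd.DataFrame, config: SyntheticConfig, family_effects: dict[str, float]) -> np.ndarray:
    origin = plants["origin"].to_numpy()
    woody = plants["woodiness_true"].to_numpy()
    eta = np.empty(len(plants))
    for i in range(len(plants)):
        eta[i] = config.intercept(origin[i], woody[i]) + family_effects[plants["family"].iat[i]]
    nn = origin == "non-native"
    if nn.any():
        required = ["aoo_km2", "intro_year", "centroid_dist_km"]
        missing = plants.loc[nn, required].isna().any(axis=1)
        if missing.any():
            bad = plants.loc[nn].loc[missing, "accepted_name"].iloc[0]
            raise ValueError(f"plant {bad!r} lacks covariates required by the latent model")
        b_range = np.where(woody[nn] == "woody", config.beta_range_woody, config.beta_range_nonwoody)
        b_year = np.where(woody[nn] == "woody", config.beta_year_woody, config.beta_year_nonwoody)
        eta[nn] += (
            b_range * np.log10(plants.loc[nn, "aoo_km2"].to_numpy())
            + b_year * plants.loc[nn, "intro_year"].to_numpy()
            + config.beta_dist * plants.loc[nn, "centroid_dist_km"].to_numpy()
        )
    return eta


def _geometric_breadths(rng: np.random.Generator, n: int, mean: float) -> np.ndarray:
    """Heavy-tailed generalist host-set sizes >= 2 with the given mean."""
    p = 1.0 / (mean - 1.0)
    return 1 + rng.geometric(min(1.0, p), size=n)


def generate_interactions(
    plants: pd.DataFrame, config: SyntheticConfig
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw per-plant richness from the latent model and assign herbivores.

    Richness is ``max(1, round(10**eta))`` with
    ``eta = intercept + covariate effects + family effect + noise``; only
    interacting plants exist downstream, so the floor mirrors the absence of
    zero-richness records in observational association data.  Herbivore
    identities realise the per-plant richness exactly: a ``specialist_fraction``
    of herbivores receive one host (native with probability
    ``specialist_native_pref``), the remainder receive multi-host sets drawn
    within one family (oligophagous), within two to three families
    (mesophagous) or across the flora (polyphagous).
    """
    config.validate()
    rng_noise, rng_assign = _rngs(config.seed + 1_000_003, 2)

    families = sorted(plants["family"].unique())
    fam_fx = {f: float(rng_noise.normal(0.0, config.sd_family)) for f in families}
    eta = _latent_predictor(plants, config, fam_fx)
    noise = rng_noise.normal(0.0, config.sd_resid, len(plants))
    richness = np.maximum(1, np.rint(10 ** (eta + noise)).astype(int))

    names = plants["accepted_name"].to_numpy()
    genus = plants["genus"].to_numpy()
    family = plants["family"].to_numpy()
    native = plants["origin"].eq("native").to_numpy()

    remaining = richness.copy()
    n_pairs = int(richness.sum())
    s = config.specialist_fraction
    m = config.generalist_breadth_mean

    pairs_plant: list[int] = []
    pairs_herb: list[int] = []
    herb_id = 0

    # Plan generalist host-set sizes until the share of single-host
    # herbivores among all herbivores reaches the specialist fraction:
    # with B slots consumed by g generalists, the n_pairs - B leftover
    # slots each become one specialist.
    planned: list[tuple[int, int]] = []  # (scope, breadth)
    budget = n_pairs
    if s < 1.0:
        while budget > 0 and budget / (budget + len(planned)) > s:
            scope = int(rng_assign.choice(3, p=[0.25, 0.25, 0.5]))
            b = int(_geometric_breadths(rng_assign, 1, m)[0])
            if scope == 0:
                b = min(b, 4)  # oligophagy: <= 4 genera within one family
            b = min(b, budget)
            planned.append((scope, b))
            budget -= b
    n_specialists = budget
    n_generalists = len(planned)

    # --- specialists: one host each, preferentially native -----------------
    n_specialists = min(n_specialists, n_pairs)
    go_native = rng_assign.random(n_specialists) < config.specialist_native_pref
    for prefer_native, count in ((True, int(go_native.sum())), (False, int((~go_native).sum()))):
        pool_mask = native if prefer_native else ~native
        slots = np.repeat(np.arange(len(plants)), remaining * pool_mask)
        if len(slots) < count:  # fall back to the full pool
            extra = np.repeat(np.arange(len(plants)), remaining * ~pool_mask)
            slots = np.concatenate([slots, extra])
        take = rng_assign.permutation(len(slots))[:count]
        chosen = slots[take]
        for p in chosen:
            pairs_plant.append(int(p))
            pairs_herb.append(herb_id)
            herb_id += 1
        np.subtract.at(remaining, chosen, 1)

    # --- generalists: scoped multi-host sets -------------------------------
    fam_index: dict[str, np.ndarray] = {
        f: np.flatnonzero(family == f) for f in families
    }
    fam_arr = np.array(families)
    for scope, b in planned:
        open_slots = int(remaining.sum())
        if open_slots == 0:
            break
        if scope == 0:
            fam_weights = np.array([remaining[fam_index[f]].sum() for f in families], float)
            if fam_weights.sum() == 0:
                break
            f = fam_arr[rng_assign.choice(len(families), p=fam_weights / fam_weights.sum())]
            candidates = fam_index[f]
        elif scope == 1:
            fam_weights = np.array([remaining[fam_index[f]].sum() for f in families], float)
            alive = np.flatnonzero(fam_weights > 0)
            k = min(len(alive), int(rng_assign.integers(2, 4)))
            pick = rng_assign.choice(alive, size=k, replace=False, p=fam_weights[alive] / fam_weights[alive].sum())
            candidates = np.concatenate([fam_index[fam_arr[i]] for i in pick])
        else:
            candidates = np.arange(len(plants))
        w = remaining[candidates].astype(float)
        avail = candidates[w > 0]
        if len(avail) < b:  # widen to the whole flora if the scope is exhausted
            candidates = np.arange(len(plants))
            avail = candidates[remaining > 0]
        b = min(b, len(avail))
        if b == 0:
            break
        w = remaining[avail].astype(float)
        # weighted sampling without replacement (Efraimidis–Spirakis keys)
        keys = np.log(w) + rng_assign.gumbel(size=len(avail))
        chosen = avail[np.argsort(keys)[-b:]]
        for p in chosen:
            pairs_plant.append(int(p))
            pairs_herb.append(herb_id)
        herb_id += 1
        np.subtract.at(remaining, chosen, 1)

    # --- leftovers become additional strict specialists --------------------
    for p in np.flatnonzero(remaining):
        for _ in range(int(remaining[p])):
            pairs_plant.append(int(p))
            pairs_herb.append(herb_id)
            herb_id += 1
    remaining[:] = 0

    interactions = pd.DataFrame(
        {
            "plant_name": names[pairs_plant],
            "herbivore_name": [f"H{h:06d}" for h in pairs_herb],
        }
    )

    truth = SyntheticTruth(
        config=config,
        family_effects=fam_fx,
        latent_log10_richness=pd.Series(eta, index=names, name="latent_log10_richness"),
        richness=pd.Series(richness, index=names, name="richness"),
    )
    return interactions, truth


def write_dataset(outdir: str | Path, config: SyntheticConfig) -> dict[str, Path]:
    """Write the five pipeline input CSVs plus a ground-truth JSON.

    Files: ``interactions.csv`` (with synonym substitutions and genus-only
    noise rows the ingest stage must handle), ``plants.csv``,
    ``occurrences.csv`` (non-native species × occupied grid cell),
    ``region_centroids.csv`` and ``synonym_map.csv``; ``truth.json`` records
    the generating parameters and latent values.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    plants = generate_flora(config)
    interactions, truth = generate_interactions(plants, config)
    rng = _rngs(config.seed + 2_000_003, 1)[0]

    # synonym substitution on a fraction of interaction rows
    syn_plants = plants["accepted_name"].sample(
        frac=config.synonym_fraction, random_state=int(rng.integers(2**31))
    )
    synonym_map = pd.DataFrame(
        {"name": [n + "syn" for n in syn_plants], "accepted_name": syn_plants}
    )
    syn_lookup = dict(zip(synonym_map["accepted_name"], synonym_map["name"]))
    out_inter = interactions.copy()
    hit = out_inter["plant_name"].isin(syn_lookup)
    out_inter.loc[hit, "plant_name"] = out_inter.loc[hit, "plant_name"].map(syn_lookup)

    # genus-only noise rows (dropped at ingest)
    if config.n_genus_only > 0:
        g = rng.choice(plants["genus"].unique(), size=config.n_genus_only)
        noise = pd.DataFrame(
            {"plant_name": g, "herbivore_name": [f"H{h:06d}" for h in rng.integers(0, 10, config.n_genus_only)]}
        )
        out_inter = pd.concat([out_inter, noise], ignore_index=True)

    paths = {}
    paths["interactions"] = outdir / "interactions.csv"
    out_inter.to_csv(paths["interactions"], index=False)

    plant_cols = [
        "accepted_name", "genus", "family", "origin", "woodiness",
        "intro_year", "native_regions",
    ]
    paths["plants"] = outdir / "plants.csv"
    plants[plant_cols].to_csv(paths["plants"], index=False)

    nn = plants[plants["origin"].eq("non-native")]
    occ_rows = []
    for name, inside, outside in zip(nn["accepted_name"], nn["cells_inside"], nn["cells_outside"]):
        for c in inside + outside:
            occ_rows.append((name, c // GRID_SIDE, c % GRID_SIDE))
    paths["occurrences"] = outdir / "occurrences.csv"
    pd.DataFrame(occ_rows, columns=["species", "i", "j"]).to_csv(paths["occurrences"], index=False)

    reg = plants.attrs["region_centroids"]
    paths["region_centroids"] = outdir / "region_centroids.csv"
    pd.DataFrame(
        [(code, lat, lon) for code, (lat, lon) in reg.items()],
        columns=["region_code", "lat", "lon"],
    ).to_csv(paths["region_centroids"], index=False)

    paths["synonym_map"] = outdir / "synonym_map.csv"
    synonym_map.to_csv(paths["synonym_map"], index=False)

    paths["truth"] = outdir / "truth.json"
    truth.to_json(paths["truth"])
    return paths
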