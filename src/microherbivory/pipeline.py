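"""End-to-end orchestration: simulate → ingest → covariates → specialisation → models.

A :class:`PipelineConfig` either points at the five input CSVs or carries a
``simulate`` block (a :class:`~microherbivory.synthetic.SyntheticConfig`)
that writes them first.  :func:`run_pipeline` executes the stages, keeps a
filter ledger (rows in = rows out + rows dropped at every exclusion), and
writes covariate tables, fit reports and a run manifest; identical
config + seed yields identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import covariates as cov
from . import ingest, models, specialisation
from .synthetic import SyntheticConfig, write_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

STAGES = ("simulate", "build", "specialisation", "models", "report")


@dataclass
class PipelineConfig:
    """Flat pipeline configuration; every filtering threshold is a key."""

    output_dir: str = "pipeline_out"
    #: input CSV paths; ignored when ``simulate`` is set
    interactions: str | None = None
    plants: str | None = None
    occurrences: str | None = None
    region_centroids: str | None = None
    synonym_map: str | None = None
    simulate: SyntheticConfig | None = None

    proximity_km: float = 2500.0
    cutoff_year: int = 1492
    integration_threshold_woody_km2: float = 2.7e5
    integration_threshold_nonwoody_km2: float = 1.1e6
    region_grid_side: int = 100
    cell_area_km2: float = 2500.0
    reference_year: int = 2025

    bootstrap_reps: int = 0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = SyntheticConfig(**sim)
        return cfg

    def validate(self) -> None:
        if self.simulate is None:
            required = ["interactions", "plants", "occurrences", "region_centroids"]
            missing = [k for k in required if getattr(self, k) is None]
            if missing:
                raise ValueError(f"missing input path(s) {missing} and no simulate block")

    @property
    def integration_thresholds(self) -> dict[str, float]:
        return {
            "woody": self.integration_threshold_woody_km2,
            "non-woody": self.integration_threshold_nonwoody_km2,
        }


@dataclass
class PipelineResult:
    """Bundle of tables, fitted models and the run manifest."""

    plants: pd.DataFrame | None = None
    interactions: pd.DataFrame | None = None
    profiles: pd.DataFrame | None = None
    composition: pd.DataFrame | None = None
    origin_fit: models.RichnessMixedLMResults | None = None
    drivers_fit: models.RichnessMixedLMResults | None = None
    breadth_fit: models.RichnessMixedLMResults | None = None
    r2: models.R2Decomposition | None = None
    group_summary: dict | None = None
    report: dict | None = None
    manifest: dict = field(default_factory=dict)


def _stage_error(stage: str, exc: Exception) -> RuntimeError:
    return RuntimeError(f"pipeline stage {stage!r} failed: {exc}")


def _ledger(manifest: dict, stage: str, rows_in: int, rows_dropped: int) -> None:
    manifest.setdefault("filters", []).append(
        {"stage": stage, "rows_in": rows_in, "rows_dropped": rows_dropped,
         "rows_out": rows_in - rows_dropped}
    )


def run_pipeline(config: PipelineConfig, upto: str = "report") -> PipelineResult:
    """Run the pipeline through stage ``upto`` and write outputs.

    Stage order: simulate, build (ingest + covariates), specialisation,
    models, report.  Any stage error aborts with the stage name.
    """
    config.validate()
    if upto not in STAGES:
        raise ValueError(f"unknown stage {upto!r}")
    last = STAGES.index(upto)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult()
    manifest = result.manifest
    manifest["seed"] = config.seed

    # --- simulate -----------------------------------------------------------
    if config.simulate is not None:
        try:
            paths = write_dataset(outdir / "inputs", config.simulate)
        except Exception as exc:  # noqa: BLE001
            raise _stage_error("simulate", exc) from exc
        for key in ("interactions", "plants", "occurrences", "region_centroids", "synonym_map"):
            setattr(config, key, str(paths[key]))
        manifest["simulated"] = True
    if last == 0:
        _write_manifest(outdir, manifest)
        return result

    # --- build: ingest + covariates ----------------------------------------
    try:
        synonyms = (
            pd.read_csv(config.synonym_map) if config.synonym_map else None
        )
        inter = ingest.read_interactions(config.interactions, synonyms)
        plants = ingest.read_plants(config.plants)
        richness = ingest.richness_per_plant(inter)
    except FileNotFoundError as exc:
        raise _stage_error("build", exc) from exc
    except ValueError as exc:
        raise _stage_error("build", exc) from exc
    manifest["n_interactions"] = len(inter)
    manifest["n_genus_only_dropped"] = inter.attrs.get("n_genus_only_dropped", 0)
    manifest["n_duplicates_collapsed"] = inter.attrs.get("n_duplicates_collapsed", 0)

    try:
        plants = plants.merge(richness, left_on="accepted_name", right_index=True, how="left")
        n_no_inter = int(plants["richness"].isna().sum())
        _ledger(manifest, "plants_without_interactions", len(plants), n_no_inter)
        plants = plants.dropna(subset=["richness"])
        plants["richness"] = plants["richness"].astype(int)

        plants, imp = cov.fill_woodiness(plants)
        manifest["woodiness_imputed"] = imp.n_imputed
        manifest["woodiness_unresolved"] = imp.n_unresolved

        # AOO from gridded occurrences, cropped to the focal region
        occ = pd.read_csv(config.occurrences)
        side = config.region_grid_side
        region_cells = {(i, j) for i in range(side) for j in range(side)}
        aoo = cov.aoo_from_occurrences(occ, region_cells, config.cell_area_km2)
        plants = plants.merge(aoo, left_on="accepted_name", right_index=True, how="left")

        # earliest introduction with the post-1492 rule
        nn = plants["origin"].eq("non-native")
        intro = plants.loc[nn & plants["intro_year"].notna(), ["accepted_name", "intro_year"]]
        kept_years, n_pre = cov.earliest_introduction(
            intro.rename(columns={"accepted_name": "species", "intro_year": "year"}),
            cutoff_year=config.cutoff_year,
        )
        _ledger(manifest, "pre_columbian_introductions", len(intro), n_pre)
        plants["intro_year"] = plants["accepted_name"].map(kept_years)

        # native-range centroid distance + proximity exclusion
        centroids = pd.read_csv(config.region_centroids).set_index("region_code")
        dist = pd.Series(np.nan, index=plants.index)
        has_regions = nn & plants["native_regions"].fillna("").str.len().gt(0)
        for idx in plants.index[has_regions]:
            codes = plants.at[idx, "native_regions"].split(";")
            lat, lon = cov.native_centroid(codes, centroids)
            dist.at[idx] = cov.great_circle_km(lat, lon, *cov.EUROPE_CENTROID)
        plants["centroid_dist_km"] = dist
        n_dist = int(dist.notna().sum())
        close = dist < config.proximity_km
        _ledger(manifest, "proximity_exclusion", n_dist, int(close.sum()))
        plants.loc[close, "centroid_dist_km"] = np.nan

        # relatedness to the native flora
        natives = plants.loc[plants["origin"].eq("native")]
        rel = cov.classify_relatedness(
            plants.loc[nn], set(natives["genus"]), set(natives["family"])
        )
        plants["relatedness"] = rel
    except (KeyError, ValueError) as exc:
        raise _stage_error("build", exc) from exc

    result.plants = plants
    result.interactions = inter
    manifest["n_plants"] = len(plants)
    plants.to_csv(outdir / "plants_covariates.csv", index=False)
    richness.to_csv(outdir / "richness.csv")
    if last == 1:
        _write_manifest(outdir, manifest)
        return result

    # --- specialisation -----------------------------------------------------
    try:
        profiles = specialisation.build_profiles(inter, plants)
        breadth = specialisation.host_breadth(inter)
        mean_breadth = specialisation.per_plant_mean_breadth(inter, breadth)
        plants["mean_host_breadth"] = plants["accepted_name"].map(mean_breadth)
        composition = specialisation.per_plant_composition(inter, profiles)
        comp_groups = specialisation.composition_summary(plants, composition)
    except (KeyError, ValueError) as exc:
        raise _stage_error("specialisation", exc) from exc
    result.profiles = profiles
    result.composition = comp_groups
    manifest["n_herbivores"] = len(profiles)
    manifest["phagy_counts"] = profiles["phagy"].value_counts().to_dict()
    profiles.to_csv(outdir / "herbivore_profiles.csv")
    comp_groups.to_csv(outdir / "composition_by_group.csv")
    if last == 2:
        _write_manifest(outdir, manifest)
        return result

    # --- models -------------------------------------------------------------
    try:
        known_wood = plants[plants["woodiness"].isin(["woody", "non-woody"])].copy()
        _ledger(manifest, "unknown_woodiness_for_models", len(plants), len(plants) - len(known_wood))

        origin_fit = models.RichnessMixedLM.origin_model(known_wood).fit()
        gs = models.group_summary(known_wood)

        nn_frame = known_wood[known_wood["origin"].eq("non-native")].copy()
        nn_frame["log10_aoo"] = np.log10(nn_frame["aoo_km2"].where(nn_frame["aoo_km2"] > 0))
        drivers = models.RichnessMixedLM.drivers_model(nn_frame)
        _ledger(manifest, "drivers_complete_case", len(nn_frame), drivers.n_dropped)
        drivers_fit = drivers.fit()
        r2 = drivers_fit.r2_decomposition(n_boot=config.bootstrap_reps, seed=config.seed)

        integrated = specialisation.integration_filter(
            known_wood, config.integration_thresholds
        )
        manifest["n_well_integrated"] = int(
            (integrated["origin"] == "non-native").sum()
        )
        breadth_fit = models.RichnessMixedLM.origin_model(
            integrated, response="mean_host_breadth"
        ).fit()
    except (KeyError, ValueError) as exc:
        raise _stage_error("models", exc) from exc

    result.origin_fit = origin_fit
    result.drivers_fit = drivers_fit
    result.breadth_fit = breadth_fit
    result.r2 = r2
    result.group_summary = gs
    manifest["n_origin_model"] = origin_fit.n_obs
    manifest["n_drivers_model"] = drivers_fit.n_obs
    (outdir / "fit_origin.txt").write_text(origin_fit.summary() + "\n")
    (outdir / "fit_drivers.txt").write_text(drivers_fit.summary() + "\n")
    (outdir / "fit_breadth.txt").write_text(breadth_fit.summary() + "\n")
    r2.to_frame().to_csv(outdir / "r2_decomposition.csv")
    if last == 3:
        _write_manifest(outdir, manifest)
        return result

    # --- report -------------------------------------------------------------
    try:
        result.report = _build_report(config, result)
    except (KeyError, ValueError) as exc:
        raise _stage_error("report", exc) from exc
    (outdir / "report.json").write_text(json.dumps(result.report, indent=1, sort_keys=True))
    _write_manifest(outdir, manifest)
    return result


def _slope(fit: models.RichnessMixedLMResults, fragment: str, level: str) -> float:
    names = [n for n in fit.fe_params.index if fragment in n and f"[{level}]" in n]
    if len(names) != 1:
        raise KeyError(f"no unique coefficient matching {fragment!r} at level {level!r}")
    return float(fit.fe_params[names[0]])


def _build_report(config: PipelineConfig, result: PipelineResult) -> dict:
    """Back-transformed slopes, group contrasts and integration thresholds."""
    fit = result.drivers_fit
    gs = result.group_summary
    mean = gs["table"]["mean_richness"]
    report: dict = {
        "marginal_r2": fit.marginal_r2,
        "conditional_r2": fit.conditional_r2,
        "semipartial_r2": result.r2.semipartial,
        "group_means": {f"{o}|{w}": m for (o, w), m in mean.items()},
        "folds": gs["folds"],
        "percent": gs["percent"],
    }
    for level in ("non-woody", "woody"):
        b_range = _slope(fit, "log10_aoo", level)
        b_year = _slope(fit, "intro_year", level)
        b_dist = _slope(fit, "centroid_dist_km", level)
        report[f"fold_per_decade[{level}]"] = models.backtransform_per_decade(b_range)
        report[f"percent_per_century[{level}]"] = models.backtransform_per_century(b_year)
        span = result.plants["centroid_dist_km"].max() - result.plants["centroid_dist_km"].min()
        report[f"distance_effect_percent[{level}]"] = models.distance_effect_percent(
            b_dist, -span
        )
        target = mean[("native", level)]
        aoo_thr = fit.crossover_threshold(
            target, "log10_aoo", {"woodiness": level}, scale="log10"
        )
        year_thr = fit.crossover_threshold(target, "intro_year", {"woodiness": level})
        report[f"crossover_aoo_km2[{level}]"] = aoo_thr
        report[f"crossover_year[{level}]"] = year_thr
        report[f"residence_years[{level}]"] = models.residence_years(
            min(year_thr, config.reference_year), config.reference_year
        )
    return report


def _write_manifest(outdir: Path, manifest: dict) -> None:
    manifest["package"] = "microherbivory"
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
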