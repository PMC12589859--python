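import numpy as np
import pandas as pd
import pytest

from microherbivory.covariates import classify_relatedness
from microherbivory.ingest import richness_per_plant
from microherbivory.synthetic import (
    SyntheticConfig,
    generate_flora,
    generate_interactions,
)


def small_config(**overrides) -> SyntheticConfig:
    base = dict(
        n_native_nonwoody=300,
        n_native_woody=80,
        n_nonnative_nonwoody=400,
        n_nonnative_woody=200,
        n_families=30,
        genera_per_family=5,
        seed=3,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


def recovery_config(seed: int) -> SyntheticConfig:
    """Drivers-model recovery conditions: 1000 non-natives, 30 families,
    realistic slope magnitudes, baseline richness high enough that the
    integer floor of the response does not censor the latent model."""
    return SyntheticConfig(
        n_native_nonwoody=300,
        n_native_woody=100,
        n_nonnative_nonwoody=600,
        n_nonnative_woody=400,
        n_families=30,
        genera_per_family=8,
        intercept_nonnative_nonwoody=1.9010,
        intercept_nonnative_woody=2.2695,
        intercept_native_nonwoody=1.4583,
        intercept_native_woody=1.6327,
        missing_woodiness_fraction=0.0,
        seed=seed,
    )


def drivers_frame(config: SyntheticConfig) -> pd.DataFrame:
    """Non-native analysis frame (richness + covariates) for the drivers model."""
    plants = generate_flora(config)
    inter, _ = generate_interactions(plants, config)
    plants = plants.merge(
        richness_per_plant(inter), left_on="accepted_name", right_index=True
    )
    natives = plants[plants["origin"].eq("native")]
    nn = plants[plants["origin"].eq("non-native")].copy()
    nn["relatedness"] = classify_relatedness(
        nn, set(natives["genus"]), set(natives["family"])
    )
    nn["log10_aoo"] = np.log10(nn["aoo_km2"])
    return nn


@pytest.fixture(scope="session")
def small_dataset():
    cfg = small_config()
    plants = generate_flora(cfg)
    interactions, truth = generate_interactions(plants, cfg)
    return cfg, plants, interactions, truth


@pytest.fixture(scope="session")
def default_dataset():
    """One realisation at the full default scale (~10,000 plants)."""
    cfg = SyntheticConfig(seed=42)
    plants = generate_flora(cfg)
    interactions, truth = generate_interactions(plants, cfg)
    return cfg, plants, interactions, truth
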