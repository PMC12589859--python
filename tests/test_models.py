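"""Mixed-model estimation, variance partitioning and derived thresholds."""

import numpy as np
import pandas as pd
import pytest

from microherbivory.models import (
    RichnessMixedLM,
    backtransform_per_century,
    backtransform_per_decade,
    distance_effect_percent,
    group_summary,
    residence_years,
)
from microherbivory.synthetic import SyntheticConfig, generate_flora, generate_interactions

from conftest import drivers_frame, recovery_config


def noiseless_frame(seed=11):
    """Drivers-model frame whose response is the exact latent value."""
    cfg = SyntheticConfig(
        n_native_nonwoody=0, n_native_woody=0,
        n_nonnative_nonwoody=300, n_nonnative_woody=200,
        n_families=20, genera_per_family=5,
        sd_family=0.0, sd_resid=0.0, missing_woodiness_fraction=0.0, seed=seed,
    )
    plants = generate_flora(cfg)
    _, truth = generate_interactions(plants, cfg)
    df = plants.copy()
    df["resp"] = 10.0 ** truth.latent_log10_richness.loc[df["accepted_name"]].to_numpy()
    df["log10_aoo"] = np.log10(df["aoo_km2"])
    df["relatedness"] = "congeneric"
    return cfg, df


@pytest.fixture(scope="module")
def noiseless_fit():
    cfg, df = noiseless_frame()
    return cfg, RichnessMixedLM.drivers_model(df, response="resp").fit()


@pytest.fixture(scope="module")
def noisy_fit():
    cfg = recovery_config(0)
    frame = drivers_frame(cfg)
    return cfg, frame, RichnessMixedLM.drivers_model(frame).fit()


def test_noiseless_fit_recovers_generating_values_exactly(noiseless_fit):
    cfg, fit = noiseless_fit
    expect = {
        "C(woodiness)[non-woody]:log10_aoo": cfg.beta_range_nonwoody,
        "C(woodiness)[woody]:log10_aoo": cfg.beta_range_woody,
        "C(woodiness)[non-woody]:intro_year": cfg.beta_year_nonwoody,
        "C(woodiness)[woody]:intro_year": cfg.beta_year_woody,
        "C(woodiness)[non-woody]:centroid_dist_km": cfg.beta_dist,
        "C(woodiness)[woody]:centroid_dist_km": cfg.beta_dist,
        "Intercept": cfg.intercept_nonnative_nonwoody,
    }
    for name, value in expect.items():
        assert fit.fe_params[name] == pytest.approx(value, abs=1e-7)
    assert fit.var_family == 0.0 and fit.var_resid == 0.0


def test_constant_response_gives_zero_slopes_and_zero_residual_variance():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({
        "richness": 5,
        "origin": rng.choice(["native", "non-native"], 200),
        "woodiness": rng.choice(["woody", "non-woody"], 200),
        "family": rng.choice([f"F{i}" for i in range(10)], 200),
    })
    fit = RichnessMixedLM.origin_model(df).fit()
    slopes = fit.fe_params.drop("Intercept")
    assert np.allclose(slopes, 0.0, atol=1e-12)
    assert fit.var_resid == 0.0
    assert fit.fe_params["Intercept"] == pytest.approx(np.log10(5))


def test_origin_model_recovers_group_contrasts_within_2_se():
    # covariate slopes zeroed so the latent group contrast is exactly the
    # intercept difference
    cfg = recovery_config(1)
    cfg.beta_range_nonwoody = cfg.beta_range_woody = 0.0
    cfg.beta_year_nonwoody = cfg.beta_year_woody = cfg.beta_dist = 0.0
    plants = generate_flora(cfg)
    inter, _ = generate_interactions(plants, cfg)
    from microherbivory.ingest import richness_per_plant
    plants = plants.merge(richness_per_plant(inter), left_on="accepted_name", right_index=True)
    fit = RichnessMixedLM.origin_model(plants).fit()
    origin_contrast = cfg.intercept_nonnative_nonwoody - cfg.intercept_native_nonwoody
    est = fit.fe_params["C(origin)[T.non-native]"]
    se = fit.bse["C(origin)[T.non-native]"]
    assert abs(est - origin_contrast) < 2 * se
    inter_truth = (cfg.intercept_nonnative_woody - cfg.intercept_native_woody) - origin_contrast
    name = "C(origin)[T.non-native]:C(woodiness)[T.woody]"
    assert abs(fit.fe_params[name] - inter_truth) < 2 * fit.bse[name]


def test_marginal_equals_conditional_without_family_variance(noiseless_fit):
    # exact equality when the family variance is exactly zero
    _, clean_fit = noiseless_fit
    assert clean_fit.marginal_r2 == clean_fit.conditional_r2
    # near equality when the generating process has no family component
    _, df = noiseless_frame()
    rng = np.random.default_rng(1)
    df["resp"] = df["resp"] * 10 ** rng.normal(0, 0.2, len(df))  # residual noise only
    fit = RichnessMixedLM.drivers_model(df, response="resp").fit()
    assert fit.marginal_r2 == pytest.approx(fit.conditional_r2, abs=5e-3)
    assert 0.0 <= fit.marginal_r2 <= fit.conditional_r2 <= 1.0


def test_removing_all_fixed_effects_gives_semipartial_equal_to_marginal(noisy_fit):
    _, frame, _ = noisy_fit
    model = RichnessMixedLM(
        frame, response="richness",
        fixed_terms=RichnessMixedLM.drivers_model(frame).fixed_terms,
        term_groups={"everything": RichnessMixedLM.drivers_model(frame).fixed_terms},
    )
    fit = model.fit()
    dec = fit.r2_decomposition(n_boot=0)
    assert dec.semipartial["everything"] == pytest.approx(fit.marginal_r2, abs=1e-6)


def test_marginal_r2_invariant_to_affine_covariate_rescaling(noisy_fit):
    _, frame, fit = noisy_fit
    rescaled = frame.copy()
    rescaled["intro_year"] = (rescaled["intro_year"] - 1700.0) / 10.0
    fit2 = RichnessMixedLM.drivers_model(rescaled).fit()
    assert fit2.marginal_r2 == pytest.approx(fit.marginal_r2, abs=1e-4)


def test_semipartials_invariant_to_group_ordering(noisy_fit):
    _, frame, fit = noisy_fit
    forward = fit.r2_decomposition(n_boot=0).semipartial
    model = RichnessMixedLM.drivers_model(frame)
    model.term_groups = dict(reversed(list(model.term_groups.items())))
    backward = model.fit().r2_decomposition(n_boot=0).semipartial
    for key, value in forward.items():
        assert backward[key] == pytest.approx(value, abs=1e-8)


def test_bootstrap_ci_brackets_point_estimates(noisy_fit):
    _, _, fit = noisy_fit
    dec = fit.r2_decomposition(n_boot=8, seed=1)
    assert dec.ci is not None
    for name, (low, high) in dec.ci.items():
        assert 0.0 <= low <= high <= 1.0
    none = fit.r2_decomposition(n_boot=0)
    assert none.ci is None


def test_crossover_matches_closed_form_inversion(noiseless_fit):
    cfg, fit = noiseless_fit
    frame = fit.model.frame
    target = 6.0
    thr = fit.crossover_threshold(target, "log10_aoo", {"woodiness": "non-woody"}, scale="log10")
    # independent closed-form inversion from the generating coefficients
    a = (
        cfg.intercept_nonnative_nonwoody
        + cfg.beta_year_nonwoody * frame["intro_year"].mean()
        + cfg.beta_dist * frame["centroid_dist_km"].mean()
    )
    expected = (np.log10(target) - a) / cfg.beta_range_nonwoody
    assert np.log10(thr) == pytest.approx(expected, abs=1e-6)
    # predicted richness at the threshold equals the target on the log scale
    ref = {c: frame[c].mean() if np.issubdtype(frame[c].dtype, np.number) else frame[c].mode()[0]
           for c in ["intro_year", "centroid_dist_km", "relatedness"]}
    ref.update({"woodiness": "non-woody", "log10_aoo": np.log10(thr)})
    pred = fit.predict_fixed(pd.DataFrame([ref]))[0]
    assert pred == pytest.approx(np.log10(target), abs=1e-6)


def test_crossover_fixed_point(noiseless_fit):
    _, fit = noiseless_fit
    frame = fit.model.frame
    ref_year = frame["intro_year"].mean()
    ref = {c: frame[c].mean() if np.issubdtype(frame[c].dtype, np.number) else frame[c].mode()[0]
           for c in ["log10_aoo", "centroid_dist_km", "relatedness"]}
    ref["woodiness"] = "non-woody"
    ref["intro_year"] = ref_year
    target = 10.0 ** fit.predict_fixed(pd.DataFrame([ref]))[0]
    assert fit.crossover_threshold(target, "intro_year", {"woodiness": "non-woody"}) == pytest.approx(
        ref_year, abs=1e-6
    )


def test_zero_slope_has_no_crossover(noiseless_fit):
    _, fit = noiseless_fit
    fit.fe_params["C(woodiness)[non-woody]:intro_year"] = 0.0
    fit.fe_params["C(woodiness)[woody]:intro_year"] = 0.0
    with pytest.raises(ValueError, match="no crossover"):
        fit.crossover_threshold(5.0, "intro_year", {"woodiness": "non-woody"})


def test_backtransform_identities():
    assert backtransform_per_decade(0.0) == pytest.approx(1.0)
    assert backtransform_per_century(0.0) == pytest.approx(0.0)
    assert distance_effect_percent(0.0, -14868.0) == pytest.approx(0.0)


def test_distance_effect_multiplicative_symmetry():
    p_close = distance_effect_percent(-2.31e-5, -14868.0)
    p_far = distance_effect_percent(-2.31e-5, 14868.0)
    assert (1 + p_close / 100.0) * (1 + p_far / 100.0) == pytest.approx(1.0)


def test_group_summary_equal_means_give_unit_fold():
    plants = pd.DataFrame({
        "origin": ["native", "native", "non-native", "non-native"] * 2,
        "woodiness": ["woody"] * 4 + ["non-woody"] * 4,
        "richness": [3, 5, 4, 4, 2, 2, 1, 3],
    })
    gs = group_summary(plants)
    assert gs["folds"]["native_vs_nonnative[woody]"] == pytest.approx(1.0)
    assert gs["percent"]["native_vs_nonnative[woody]"] == pytest.approx(0.0)
    assert gs["table"].loc[("native", "woody"), "mean_richness"] == 4.0


def test_residence_years_arithmetic():
    assert residence_years(1719, 2025) == 306
    assert residence_years(2000, 2000) == 0
    with pytest.raises(ValueError):
        residence_years(2030, 2025)


def _normality_frame(noise):
    rng = np.random.default_rng(2)
    n = len(noise)
    return pd.DataFrame({
        "richness": 10.0 ** (1.0 + noise),
        "origin": rng.choice(["native", "non-native"], n),
        "woodiness": rng.choice(["woody", "non-woody"], n),
        "family": rng.choice([f"F{i}" for i in range(25)], n),
    })


def test_normal_residuals_have_small_skew():
    rng = np.random.default_rng(3)
    fit = RichnessMixedLM.origin_model(_normality_frame(rng.normal(0, 0.3, 5000))).fit()
    summary = fit.residual_normality()
    assert abs(summary.skewness) < 0.1
    assert summary.ks_distance < 0.02
    assert not summary.degenerate


def test_exponential_noise_flagged_as_skewed():
    rng = np.random.default_rng(4)
    fit = RichnessMixedLM.origin_model(_normality_frame(rng.exponential(0.3, 3000))).fit()
    assert fit.residual_normality().skewness > 0.5


def test_constant_residuals_warn_degenerate():
    fit = RichnessMixedLM.origin_model(_normality_frame(np.zeros(400))).fit()
    with pytest.warns(UserWarning, match="degenerate"):
        summary = fit.residual_normality()
    assert summary.degenerate
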