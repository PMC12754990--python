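"""Expected counts, the nested-Laplace fit, DIC/WAIC and diagnostics."""

import types

import numpy as np
import pandas as pd
import pytest

from arealrisk import (
    AreaData,
    CovariateSpec,
    ModelSpec,
    PcPriors,
    SimulationConfig,
    aggregate_posterior_counts,
    confounding_check,
    expected_counts,
    fit_glm,
    fit_model,
    format_percent_change,
    residuals,
    simulate_counts,
)

FLAT = PcPriors(beta_precision=1e-6, intercept_precision=1e-6)


# ---------------------------------------------------------------------------
# expected counts
# ---------------------------------------------------------------------------


def test_equal_populations_give_mean_count():
    y = np.array([3.0, 7.0, 5.0])
    E = expected_counts(y, np.full(3, 100.0))
    assert np.allclose(E, 5.0)


def test_proportional_counts_give_unit_smr():
    E = expected_counts(np.array([10.0, 30.0]), np.array([100.0, 300.0]))
    assert np.allclose(E, [10.0, 30.0])


def test_hand_arithmetic_split():
    E = expected_counts(np.array([8.0, 2.0]), np.array([50.0, 50.0]))
    assert np.allclose(E, [5.0, 5.0])


def test_expected_counts_preserve_total():
    rng = np.random.default_rng(0)
    y = rng.poisson(9.0, 40)
    pop = rng.uniform(50, 500, 40)
    assert np.isclose(expected_counts(y, pop).sum(), y.sum())


def test_zero_population_rejected():
    with pytest.raises(ValueError, match="population"):
        expected_counts(np.array([1.0]), np.array([0.0]))


# ---------------------------------------------------------------------------
# fitting: GLM limit and structure recovery
# ---------------------------------------------------------------------------


def _dataset(seed=0, rows=10, cols=10, sigma=0.0, phi=0.5, beta=(0.1, 0.3), ncov=1):
    covs = tuple(CovariateSpec(f"x{i}") for i in range(ncov))
    cfg = SimulationConfig(
        n_rows=rows, n_cols=cols, beta=beta, sigma=sigma, phi=phi, covariates=covs, seed=seed
    )
    return simulate_counts(cfg)


def test_flat_prior_glm_limit_matches_irls():
    """No random effects + near-flat priors reproduce the ML Poisson fit."""
    ds = _dataset(seed=2)
    d = ds.table
    glm = fit_glm(d.y, d.X, np.log(d.E))
    fit = fit_model(d, ds.graph, ModelSpec(random_effect="none", priors=FLAT, seed=1))
    assert np.max(np.abs(fit.fixed_effects["mean"].to_numpy() - glm.coefficients)) < 1e-4
    assert np.max(np.abs(fit.fixed_effects["sd"].to_numpy() / glm.se - 1.0)) < 0.02


def test_glm_variant_dic_matches_aic():
    ds = _dataset(seed=4)
    d = ds.table
    glm = fit_glm(d.y, d.X, np.log(d.E))
    fit = fit_model(d, ds.graph, ModelSpec(random_effect="none", priors=FLAT, seed=1))
    aic = -2.0 * glm.log_likelihood + 2 * len(glm.coefficients)
    assert abs(fit.dic - aic) < 2 * max(fit.mc_se_dic, 0.05)


def test_grid_weights_sum_to_one_and_mode_heaviest():
    ds = _dataset(seed=5, sigma=0.5, phi=0.8)
    fit = fit_model(ds.table, ds.graph, ModelSpec(random_effect="bym", grid_points=5, seed=1))
    w = fit.grid["weight"].to_numpy()
    assert np.isclose(w.sum(), 1.0)
    # the heaviest grid point sits in the interior of the grid (near the mode)
    heavy = fit.grid.iloc[np.argmax(w)]
    for dim in ("log_sigma", "logit_phi"):
        lo, hi = fit.grid[dim].min(), fit.grid[dim].max()
        assert lo < heavy[dim] < hi


def test_structured_field_sums_to_zero():
    ds = _dataset(seed=6, sigma=0.6, phi=0.9)
    fit = fit_model(ds.table, ds.graph, ModelSpec(random_effect="bym", grid_points=5, seed=1))
    assert abs(fit.area_effects["structured_mean"].sum()) < 1e-6


def test_rr_intervals_ordered_and_positive():
    ds = _dataset(seed=7, sigma=0.4, phi=0.5)
    fit = fit_model(ds.table, ds.graph, ModelSpec(random_effect="bym", grid_points=5, seed=1))
    rr = fit.rr
    assert (rr["lower"] > 0).all()
    assert (rr["lower"] <= rr["median"]).all()
    assert (rr["median"] <= rr["upper"]).all()


def test_missing_covariates_rejected():
    ds = _dataset(seed=8)
    X = ds.table.X.copy()
    X.iloc[0, 0] = np.nan
    bad = AreaData(
        area_ids=ds.table.area_ids,
        y=ds.table.y,
        population=ds.table.population,
        X=X,
        E=ds.table.E,
    )
    with pytest.raises(ValueError, match="missing"):
        fit_model(bad, ds.graph, ModelSpec(random_effect="none"))


def test_e_zero_with_positive_count_rejected():
    ds = _dataset(seed=9)
    E = ds.table.E.copy()
    E[0] = 0.0
    bad = AreaData(
        area_ids=ds.table.area_ids,
        y=np.maximum(ds.table.y, 1),
        population=ds.table.population,
        X=ds.table.X,
        E=E,
    )
    with pytest.raises(ValueError, match="non-finite"):
        fit_model(bad, ds.graph, ModelSpec(random_effect="none"))


def test_dic_waic_deterministic_given_seed():
    ds = _dataset(seed=10, sigma=0.3)
    spec = ModelSpec(random_effect="iid", grid_points=5, seed=11)
    f1 = fit_model(ds.table, ds.graph, spec)
    f2 = fit_model(ds.table, ds.graph, spec)
    assert f1.dic == f2.dic
    assert f1.waic == f2.waic


def test_scale_invariance_of_rr():
    """Doubling every population (hence E) with counts regenerated at the same
    relative risks leaves the fixed-effect RR posteriors statistically unchanged."""
    base = _dataset(seed=12, sigma=0.3, phi=0.5, beta=(0.0, 0.3))
    d1 = base.table
    rng = np.random.default_rng(1)
    mu2 = 2.0 * d1.E * np.exp(base.truth["eta"])
    d2 = AreaData(
        area_ids=d1.area_ids,
        y=rng.poisson(mu2),
        population=2.0 * d1.population,
        X=d1.X,
        E=2.0 * d1.E,
    )
    spec = ModelSpec(random_effect="bym", grid_points=5, seed=3)
    f1 = fit_model(d1, base.graph, spec)
    f2 = fit_model(d2, base.graph, spec)
    b1 = f1.fixed_effects.loc["x0"]
    b2 = f2.fixed_effects.loc["x0"]
    pooled_sd = np.hypot(b1["sd"], b2["sd"])
    assert abs(b1["mean"] - b2["mean"]) < 4 * pooled_sd


def test_nb_likelihood_fits_and_reports_dispersion():
    ds = _dataset(seed=13, sigma=0.2)
    spec = ModelSpec(
        likelihood="negative_binomial",
        random_effect="iid",
        grid_points=4,
        nb_grid_points=4,
        seed=1,
    )
    fit = fit_model(ds.table, ds.graph, spec)
    assert "dispersion_mean" in fit.hyper
    assert fit.hyper["dispersion_mean"] > 0
    assert np.isfinite(fit.dic) and np.isfinite(fit.waic)


# ---------------------------------------------------------------------------
# residuals
# ---------------------------------------------------------------------------


def _stub_fit(y, mu, likelihood="poisson"):
    return types.SimpleNamespace(
        y=np.asarray(y, float),
        fitted_means=np.asarray(mu, float),
        spec=types.SimpleNamespace(likelihood=likelihood),
        hyper={},
    )


def test_residuals_zero_when_exact():
    fit = _stub_fit([4.0, 9.0], [4.0, 9.0])
    assert np.allclose(residuals(fit), 0.0)


def test_pearson_residual_arithmetic():
    fit = _stub_fit([8.0], [4.0])
    assert np.isclose(residuals(fit)[0], 2.0)


# ---------------------------------------------------------------------------
# confounding check
# ---------------------------------------------------------------------------


def test_confounding_same_fit_gives_zero_deltas():
    ds = _dataset(seed=14, sigma=0.4, phi=0.7)
    fit = fit_model(ds.table, ds.graph, ModelSpec(random_effect="bym", grid_points=4, seed=1))
    table = confounding_check(ds.table, ds.graph, fit_bym=fit, fit_iid=fit)
    assert np.allclose(table["percent_change"], 0.0)


def test_percent_change_formatting_matches_convention():
    assert format_percent_change(1.081, 1.083) == "+0.2%"
    assert format_percent_change(1.010, 0.990) == "-2.0%"


# ---------------------------------------------------------------------------
# posterior count aggregation
# ---------------------------------------------------------------------------


def test_aggregation_single_group_equals_total():
    ds = _dataset(seed=15, sigma=0.3)
    fit = fit_model(ds.table, ds.graph, ModelSpec(random_effect="iid", grid_points=4, seed=1))
    table = aggregate_posterior_counts(fit, {a: "all" for a in fit.area_ids})
    assert np.isclose(table.loc["all", "mean"], table.loc["__total__", "mean"])


def test_aggregation_group_means_additive():
    ds = _dataset(seed=16, sigma=0.3)
    fit = fit_model(ds.table, ds.graph, ModelSpec(random_effect="iid", grid_points=4, seed=1))
    half = {a: ("left" if i < 50 else "right") for i, a in enumerate(fit.area_ids)}
    table = aggregate_posterior_counts(fit, half)
    assert np.isclose(
        table.loc["left", "mean"] + table.loc["right", "mean"], table.loc["__total__", "mean"]
    )
    width_l = table.loc["left", "upper"] - table.loc["left", "lower"]
    width_r = table.loc["right", "upper"] - table.loc["right", "lower"]
    assert 0.5 < width_l / width_r < 2.0  # exchangeable halves: comparable widths


def test_aggregation_unmapped_area_rejected():
    ds = _dataset(seed=17)
    fit = fit_model(ds.table, ds.graph, ModelSpec(random_effect="none", seed=1))
    with pytest.raises(ValueError, match="missing from grouping"):
        aggregate_posterior_counts(fit, {fit.area_ids[0]: "only"})


def test_interval_width_scales_with_sqrt_total():
    """Poisson-limit check: multiplying E by 4 with matched counts roughly
    doubles the absolute interval width of the total."""
    ds = _dataset(seed=18, sigma=0.0, beta=(0.0, 0.0))
    d1 = ds.table
    spec = ModelSpec(random_effect="none", priors=FLAT, seed=2)
    f1 = fit_model(d1, ds.graph, spec)
    rng = np.random.default_rng(3)
    d4 = AreaData(
        area_ids=d1.area_ids,
        y=rng.poisson(4.0 * d1.E),
        population=4.0 * d1.population,
        X=d1.X,
        E=4.0 * d1.E,
    )
    f4 = fit_model(d4, ds.graph, spec)
    g = {a: "all" for a in f1.area_ids}
    w1 = aggregate_posterior_counts(f1, g).loc["all"]
    w4 = aggregate_posterior_counts(f4, g).loc["all"]
    ratio = (w4["upper"] - w4["lower"]) / (w1["upper"] - w1["lower"])
    assert 1.4 < ratio < 2.9  # ~2 expected under sqrt scaling


def test_standardized_fit_reports_raw_scale_slopes():
    """Fitting on z-scored covariates and back-transforming reproduces the
    raw-scale slope posteriors."""
    ds = _dataset(seed=19, sigma=0.3, phi=0.6, beta=(0.0, 0.3))
    raw = fit_model(ds.table, ds.graph, ModelSpec(random_effect="bym", grid_points=4, seed=2))
    std = fit_model(
        ds.table, ds.graph, ModelSpec(random_effect="bym", grid_points=4, seed=2, standardize=True)
    )
    b_raw = raw.fixed_effects.loc["x0"]
    b_std = std.fixed_effects.loc["x0"]
    assert abs(b_raw["mean"] - b_std["mean"]) < 0.02
    assert abs(b_raw["sd"] / b_std["sd"] - 1.0) < 0.2
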