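"""GLM fits, overdispersion, the screening funnel and chained imputation."""

import numpy as np
import pandas as pd
import pytest

from arealrisk import (
    correlation_filter,
    fit_glm,
    forward_bic,
    impute_chained,
    interaction_scan,
    overdispersion_stat,
    run_screening,
    vif_filter,
)
from arealrisk.screening import GlmFit


# ---------------------------------------------------------------------------
# GLM fitting
# ---------------------------------------------------------------------------


def test_intercept_only_poisson_recovers_sample_mean(rng):
    y = rng.poisson(7.0, 500)
    fit = fit_glm(y, np.ones((500, 1)))
    assert np.isclose(np.exp(fit.coefficients[0]), y.mean(), rtol=1e-8)


def test_two_group_coefficient_is_log_rate_ratio(rng):
    g = np.repeat([0, 1], 400)
    y = rng.poisson(np.where(g == 1, 12.0, 4.0))
    X = np.column_stack([np.ones(800), g])
    fit = fit_glm(y, X)
    m0, m1 = y[g == 0].mean(), y[g == 1].mean()
    assert np.isclose(fit.coefficients[1], np.log(m1 / m0), rtol=1e-8)


def test_nb_on_poisson_data_matches_poisson_fit(rng):
    n = 2000
    x = rng.standard_normal(n)
    y = rng.poisson(np.exp(1.0 + 0.4 * x))
    X = pd.DataFrame({"x": x})
    pois = fit_glm(y, X, family="poisson")
    nb = fit_glm(y, X, family="negative_binomial")
    assert np.max(np.abs(nb.coefficients - pois.coefficients)) < 0.01
    # dispersion near zero => variance/mean close to 1
    mu_bar = nb.fitted_means.mean()
    assert 1.0 + nb.dispersion * mu_bar < 1.1


def test_rank_deficient_design_rejected(rng):
    x = rng.standard_normal(100)
    X = pd.DataFrame({"a": x, "b": 2 * x})
    with pytest.raises(ValueError, match="rank deficient"):
        fit_glm(rng.poisson(5.0, 100), X)


def test_poisson_score_equations_satisfied(rng):
    """IRLS stationarity: X'(y - mu) ~ 0 at convergence."""
    n = 400
    X = pd.DataFrame({"x1": rng.standard_normal(n), "x2": rng.standard_normal(n)})
    y = rng.poisson(np.exp(0.5 + 0.3 * X["x1"] - 0.2 * X["x2"]))
    fit = fit_glm(y, X)
    design = np.column_stack([np.ones(n), X.to_numpy()])
    score = design.T @ (y - fit.fitted_means)
    assert np.max(np.abs(score)) / max(1.0, y.sum()) < 1e-6


# ---------------------------------------------------------------------------
# overdispersion statistic
# ---------------------------------------------------------------------------


def test_overdispersion_near_one_for_poisson_data(rng):
    y = rng.poisson(6.0, 5000)
    fit = fit_glm(y, np.ones((5000, 1)))
    assert 0.9 < overdispersion_stat(fit, y) < 1.1


def test_overdispersion_large_for_nb_data_under_poisson_fit(rng):
    # NB with size theta=2: variance = mu + mu^2/2
    theta = 2.0
    mu = 6.0
    lam = rng.gamma(theta, mu / theta, 20000)
    y = rng.poisson(lam)
    fit = fit_glm(y, np.ones((len(y), 1)))
    assert overdispersion_stat(fit, y) > 1.3


def test_overdispersion_zero_when_fit_is_exact():
    y = np.array([3.0, 5.0, 7.0])
    fit = GlmFit(
        family="poisson",
        names=["(intercept)"],
        coefficients=np.array([0.0]),
        covariance=np.eye(1),
        log_likelihood=0.0,
        fitted_means=y.copy(),
    )
    assert overdispersion_stat(fit, y) == 0.0


# ---------------------------------------------------------------------------
# correlation filter
# ---------------------------------------------------------------------------


def test_duplicated_column_dropped_once(rng):
    x = rng.standard_normal(200)
    X = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.standard_normal(200)})
    reduced, dropped = correlation_filter(X)
    assert len(dropped) == 1
    assert set(reduced.columns) | {dropped[0][0]} == {"a", "b", "c"}
    assert np.isclose(abs(dropped[0][2]), 1.0)


def test_orthogonal_columns_all_kept(rng):
    X = pd.DataFrame(np.linalg.qr(rng.standard_normal((300, 4)))[0], columns=list("abcd"))
    reduced, dropped = correlation_filter(X)
    assert dropped == []
    assert list(reduced.columns) == list("abcd")


def test_exact_boundary_pair_kept():
    """r = 0.6 exactly: strict inequality keeps both."""
    rng = np.random.default_rng(3)
    basis = np.linalg.qr(rng.standard_normal((500, 2)))[0]
    e1, e2 = basis[:, 0], basis[:, 1]
    e1 = (e1 - e1.mean()) / e1.std()
    e2 = (e2 - e2.mean()) / e2.std()
    # orthogonalize after centering so the sample correlation is exactly 0.6
    e2 = e2 - e1 * (e1 @ e2) / (e1 @ e1)
    e2 = (e2 - e2.mean()) / e2.std()
    X = pd.DataFrame({"a": e1, "b": 0.6 * e1 + 0.8 * e2})
    assert abs(X["a"].corr(X["b"]) - 0.6) < 1e-12
    reduced, dropped = correlation_filter(X, 0.6)
    assert dropped == []
    assert list(reduced.columns) == ["a", "b"]


def test_constant_column_rejected():
    X = pd.DataFrame({"a": np.ones(50), "b": np.arange(50.0)})
    with pytest.raises(ValueError, match="constant"):
        correlation_filter(X)


# ---------------------------------------------------------------------------
# forward BIC selection
# ---------------------------------------------------------------------------


def test_forward_bic_finds_true_predictor():
    hits = 0
    n_seeds = 50
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        n = 500
        X = pd.DataFrame(
            rng.standard_normal((n, 6)), columns=["true"] + [f"noise{i}" for i in range(5)]
        )
        y = rng.poisson(np.exp(1.0 + 0.5 * X["true"]))
        _, selected = forward_bic(y, X)
        if "true" in selected:
            hits += 1
    assert hits >= 0.9 * n_seeds


def test_forward_bic_all_noise_selects_nothing():
    sizes = []
    for seed in range(50):
        rng = np.random.default_rng(1000 + seed)
        n = 500
        X = pd.DataFrame(rng.standard_normal((n, 5)), columns=[f"n{i}" for i in range(5)])
        y = rng.poisson(np.exp(1.0), n)
        _, selected = forward_bic(y, X)
        sizes.append(len(selected))
    assert np.median(sizes) == 0


def test_forward_bic_duplicate_never_chosen(rng):
    n = 400
    x = rng.standard_normal(n)
    X = pd.DataFrame({"x": x, "x_copy": x.copy()})
    y = rng.poisson(np.exp(1.0 + 0.5 * x))
    path, selected = forward_bic(y, X)
    assert selected in (["x"], ["x_copy"])  # one of the twins, never both
    bics = [b for _, b in path]
    assert all(b2 < b1 for b1, b2 in zip(bics, bics[1:]))  # strictly decreasing


# ---------------------------------------------------------------------------
# VIF filter
# ---------------------------------------------------------------------------


def test_vif_orthonormal_design_all_one(rng):
    Q = np.linalg.qr(rng.standard_normal((300, 3)))[0]
    vifs, reduced = vif_filter(pd.DataFrame(Q, columns=list("abc")))
    assert all(abs(v - 1.0) < 0.05 for v in vifs.values())
    assert reduced.shape[1] == 3


def test_vif_perfect_collinearity_removed_first(rng):
    x1, x2 = rng.standard_normal(200), rng.standard_normal(200)
    X = pd.DataFrame({"x1": x1, "x2": x2, "x3": x1 + x2})
    vifs, reduced = vif_filter(X)
    removed = set(X.columns) - set(reduced.columns)
    assert len(removed) == 1
    assert np.isinf(vifs[removed.pop()])


def test_vif_closed_form_for_correlated_pair():
    rng = np.random.default_rng(11)
    n = 5000
    a = rng.standard_normal(n)
    b = 0.9 * a + np.sqrt(1 - 0.81) * rng.standard_normal(n)
    X = pd.DataFrame({"a": a, "b": b, "c": rng.standard_normal(n)})
    vifs, _ = vif_filter(X)
    assert abs(vifs["a"] - 1 / (1 - 0.81)) < 0.5
    assert abs(vifs["b"] - 1 / (1 - 0.81)) < 0.5


# ---------------------------------------------------------------------------
# interaction scan
# ---------------------------------------------------------------------------


def test_bh_adjustment_step_up_arithmetic():
    from statsmodels.stats.multitest import multipletests

    adj = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
    assert np.allclose(adj, [0.03, 0.03, 0.03])


def test_interaction_scan_detects_injected_product():
    hits = 0
    n_seeds = 20
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        n = 1000
        X = pd.DataFrame(rng.standard_normal((n, 3)), columns=["a", "b", "c"])
        eta = 1.0 + 0.2 * X["a"] + 0.2 * X["b"] + 0.3 * X["a"] * X["b"]
        y = rng.poisson(np.exp(eta))
        res = interaction_scan(y, X)
        kept = res.loc[res["kept"], "pair"].tolist()
        if ("a", "b") in kept:
            hits += 1
    assert hits >= 0.9 * n_seeds


def test_interaction_scan_order_invariance(rng):
    n = 400
    X = pd.DataFrame(rng.standard_normal((n, 3)), columns=["a", "b", "c"])
    y = rng.poisson(np.exp(1.0 + 0.1 * X["a"]))
    r1 = interaction_scan(y, X)
    r2 = interaction_scan(y, X[["c", "b", "a"]])
    kept1 = {frozenset(p) for p in r1.loc[r1["kept"], "pair"]}
    kept2 = {frozenset(p) for p in r2.loc[r2["kept"], "pair"]}
    assert kept1 == kept2


# ---------------------------------------------------------------------------
# chained-equation imputation
# ---------------------------------------------------------------------------


def test_impute_identity_when_complete(rng):
    X = pd.DataFrame(rng.standard_normal((100, 3)), columns=list("abc"))
    assert impute_chained(X, seed=0).equals(X)


def test_impute_beats_mean_imputation():
    wins = 0
    n_seeds = 100
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        n = 300
        x = rng.standard_normal(n)
        y = 0.8 * x + np.sqrt(1 - 0.64) * rng.standard_normal(n)
        X = pd.DataFrame({"x": x, "y": y})
        mask = rng.random(n) < 0.2
        Xm = X.copy()
        Xm.loc[mask, "y"] = np.nan
        completed = impute_chained(Xm, regressor="linear", seed=seed)
        rmse = np.sqrt(np.mean((completed.loc[mask, "y"] - y[mask]) ** 2))
        rmse_mean = np.sqrt(np.mean((Xm["y"].mean() - y[mask]) ** 2))
        if rmse < rmse_mean:
            wins += 1
    assert wins >= 0.95 * n_seeds


def test_impute_seeded_determinism(rng):
    X = pd.DataFrame(rng.standard_normal((150, 3)), columns=list("abc"))
    Xm = X.copy()
    Xm.iloc[::7, 1] = np.nan
    c1 = impute_chained(Xm, n_iterations=3, regressor="random_forest", seed=5)
    c2 = impute_chained(Xm, n_iterations=3, regressor="random_forest", seed=5)
    assert c1.equals(c2)


def test_impute_all_missing_column_rejected():
    X = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
    with pytest.raises(ValueError, match="no observed"):
        impute_chained(X)


# ---------------------------------------------------------------------------
# the full funnel on a constructed toy
# ---------------------------------------------------------------------------


def test_funnel_retains_designed_survivor_set():
    """Duplicates fall to the correlation filter, the collinear triple to the
    rank/VIF guards, and only informative predictors survive forward-BIC."""
    rng = np.random.default_rng(21)
    n = 800
    inf1, inf2 = rng.standard_normal(n), rng.standard_normal(n)
    noise = rng.standard_normal((n, 2))
    X = pd.DataFrame(
        {
            "inf1": inf1,
            "inf1_dup": inf1 + 1e-3 * rng.standard_normal(n),
            "inf2": inf2,
            "inf2_dup": inf2 + 1e-3 * rng.standard_normal(n),
            "n1": noise[:, 0],
            "n1_dup": noise[:, 0] + 1e-3 * rng.standard_normal(n),
            "tri_a": rng.standard_normal(n),
            "tri_b": rng.standard_normal(n),
            "n2": noise[:, 1],
        }
    )
    X["tri_c"] = X["tri_a"] + X["tri_b"]  # perfectly collinear triple
    y = rng.poisson(np.exp(1.0 + 0.5 * inf1 - 0.4 * inf2))
    retained, report = run_screening(y, X, seed=0)
    assert {"inf1", "inf2"} <= {c.split("_")[0] for c in retained.columns} or {
        "inf1",
        "inf2",
    } <= set(retained.columns)
    # exactly one member of each duplicated pair survived the funnel inputs
    assert len([c for c in report.retained if c.startswith("inf1")]) <= 1
    assert len([c for c in report.retained if c.startswith("inf2")]) <= 1
    bics = [b for _, b in report.bic_path]
    assert all(b2 < b1 for b1, b2 in zip(bics, bics[1:]))
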