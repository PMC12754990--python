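"""Covariate screening funnel, GLM machinery and chained-equation imputation.

Before any spatial model is fitted, candidate predictors pass through the
classical parsimony funnel used in county-level risk-factor studies:

1. pairwise Pearson correlation filter (|r| > 0.6 drops one of the pair),
2. stepwise-forward selection under BIC with a Poisson count GLM,
3. variance-inflation-factor filter (VIF > 10, removed iteratively),
4. a negative-binomial scan of all pairwise interactions among the survivors
   with Benjamini-Hochberg false-discovery-rate adjustment.

Missing covariate cells are completed beforehand by chained-equation
imputation (column-by-column regression sweeps, linear or random-forest).

The GLM fits are delegated to statsmodels (IRLS for Poisson; full MLE with
estimated dispersion for the negative binomial) behind a small ``GlmFit``
container so the rest of the package never touches statsmodels objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from statsmodels.discrete.discrete_model import NegativeBinomial
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GlmFit",
    "ScreeningReport",
    "fit_glm",
    "overdispersion_stat",
    "correlation_filter",
    "forward_bic",
    "vif_filter",
    "interaction_scan",
    "impute_chained",
    "run_screening",
]


# ---------------------------------------------------------------------------
# GLM fitting
# ---------------------------------------------------------------------------


@dataclass
class GlmFit:
    """Maximum-likelihood GLM fit for count data.

    ``dispersion`` is the negative-binomial overdispersion parameter alpha in
    Var(Y) = mu + alpha * mu^2 (None for Poisson); equivalently the NB size
    is theta = 1/alpha.
    """

    family: str
    names: list[str]
    coefficients: np.ndarray
    covariance: np.ndarray
    log_likelihood: float
    fitted_means: np.ndarray
    dispersion: float | None = None

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    @property
    def k_params(self) -> int:
        return len(self.coefficients) + (1 if self.family == "negative_binomial" else 0)

    def bic(self, n: int) -> float:
        return -2.0 * self.log_likelihood + self.k_params * np.log(n)

    def wald_pvalues(self) -> np.ndarray:
        from scipy.stats import norm

        z = self.coefficients / self.se
        return 2.0 * norm.sf(np.abs(z))


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns involved in the deficiency via the QR diagonal
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[i] for i in range(len(names)) if i < len(diag) and diag[i] < tol]
        raise ValueError(f"design matrix is rank deficient (suspect columns: {bad or names})")


def fit_glm(
    y: np.ndarray,
    X: pd.DataFrame | np.ndarray,
    offset_log: np.ndarray | None = None,
    family: str = "poisson",
) -> GlmFit:
    """Fit a Poisson or negative-binomial GLM with a log link and log offset.

    ``X`` is the full design matrix (include the intercept column yourself,
    or pass a DataFrame and it is prepended automatically when absent).
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("counts must be nonnegative")
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xm = X.to_numpy(dtype=float)
        if not any(np.allclose(Xm[:, j], Xm[0, j]) for j in range(Xm.shape[1])):
            Xm = np.column_stack([np.ones(len(y)), Xm])
            names = ["(intercept)"] + names
    else:
        Xm = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(Xm.shape[1])]
    _check_rank(Xm, names)
    offset = np.zeros(len(y)) if offset_log is None else np.asarray(offset_log, dtype=float)

    if family == "poisson":
        model = sm.GLM(y, Xm, family=sm.families.Poisson(), offset=offset)
        res = model.fit(maxiter=100, tol=1e-10)
        if not res.converged:
            raise RuntimeError("Poisson IRLS did not converge in 100 iterations")
        return GlmFit(
            family="poisson",
            names=names,
            coefficients=np.asarray(res.params),
            covariance=np.asarray(res.cov_params()),
            log_likelihood=float(res.llf),
            fitted_means=np.asarray(res.mu),
        )
    if family == "negative_binomial":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            start = sm.GLM(y, Xm, family=sm.families.Poisson(), offset=offset).fit().params
            model = NegativeBinomial(y, Xm, offset=offset)
            res = model.fit(
                start_params=np.append(start, 0.1),
                method="bfgs",
                maxiter=200,
                disp=0,
            )
        params = np.asarray(res.params)
        alpha = max(float(params[-1]), 1e-10)
        coefs = params[:-1]
        try:
            cov = np.asarray(res.cov_params())[: len(coefs), : len(coefs)]
        except (ValueError, np.linalg.LinAlgError):
            # alpha on the zero boundary makes the joint Hessian singular;
            # in that limit the NB is a Poisson, whose covariance applies
            pois = sm.GLM(y, Xm, family=sm.families.Poisson(), offset=offset).fit()
            cov = np.asarray(pois.cov_params())
        eta = Xm @ coefs + offset
        return GlmFit(
            family="negative_binomial",
            names=names,
            coefficients=coefs,
            covariance=cov,
            log_likelihood=float(res.llf),
            fitted_means=np.exp(eta),
            dispersion=alpha,
        )
    raise ValueError(f"unknown family {family!r}")


def overdispersion_stat(fit: GlmFit, y: np.ndarray) -> float:
    """Pearson chi-square over residual degrees of freedom.

    Values near 1 indicate the family's variance function matches the data;
    > 1 signals overdispersion relative to the assumed family.
    """
    y = np.asarray(y, dtype=float)
    mu = fit.fitted_means
    if fit.family == "poisson":
        var = mu
    else:
        var = mu * (1.0 + fit.dispersion * mu)
    chi2 = float(np.sum((y - mu) ** 2 / var))
    dof = len(y) - len(fit.coefficients)
    return chi2 / dof


# ---------------------------------------------------------------------------
# correlation filter
# ---------------------------------------------------------------------------


def correlation_filter(
    X: pd.DataFrame, threshold: float = 0.6
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Drop one member of every covariate pair with |Pearson r| > threshold.

    Survivor rule: within the worst offending pair, the variable with the
    larger mean absolute correlation against all remaining variables is
    dropped (ties: the later column goes).  The boundary is strict, so a
    pair at exactly r = threshold survives.
    """
    if X.shape[1] < 2:
        raise ValueError("need at least two columns")
    for c in X.columns:
        if np.isclose(X[c].std(ddof=0), 0.0):
            raise ValueError(f"column {c!r} is constant; correlation undefined")
    work = X.copy()
    dropped: list[tuple[str, str, float]] = []
    while work.shape[1] >= 2:
        corr = work.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = float(corr.to_numpy().max())
        if worst <= threshold:
            break
        i, j = np.unravel_index(np.argmax(corr.to_numpy()), corr.shape)
        a, b = corr.columns[i], corr.columns[j]
        mean_a = corr[a].drop([a, b]).mean() if work.shape[1] > 2 else 0.0
        mean_b = corr[b].drop([a, b]).mean() if work.shape[1] > 2 else 0.0
        if mean_a > mean_b:
            victim, partner = a, b
        elif mean_b > mean_a:
            victim, partner = b, a
        else:  # tie: drop the later column
            order = list(work.columns)
            victim, partner = (a, b) if order.index(a) > order.index(b) else (b, a)
        r_signed = float(X[victim].corr(X[partner]))
        dropped.append((victim, partner, r_signed))
        work = work.drop(columns=[victim])
    return work, dropped


# ---------------------------------------------------------------------------
# forward selection under BIC
# ---------------------------------------------------------------------------


def forward_bic(
    y: np.ndarray,
    candidates: pd.DataFrame,
    offset_log: np.ndarray | None = None,
    family: str = "poisson",
) -> tuple[list[tuple[str, float]], list[str]]:
    """Stepwise-forward variable selection minimizing BIC.

    Starts from the intercept-only model; at each step adds the candidate
    giving the largest BIC decrease and stops when no addition decreases BIC.
    Returns the path [(variable, BIC after adding)] — the first entry is the
    intercept-only baseline — and the selected variable list.
    """
    n = len(y)
    selected: list[str] = []
    base = fit_glm(y, pd.DataFrame(np.ones((n, 0))), offset_log, family)
    current_bic = base.bic(n)
    path: list[tuple[str, float]] = [("(intercept)", current_bic)]
    remaining = list(candidates.columns)
    while remaining:
        best_var, best_bic = None, current_bic
        for var in remaining:
            cols = selected + [var]
            try:
                fit = fit_glm(y, candidates[cols], offset_log, family)
            except (ValueError, RuntimeError):
                continue  # rank guard or non-convergence: candidate unusable
            b = fit.bic(n)
            if b < best_bic - 1e-9:
                best_var, best_bic = var, b
        if best_var is None:
            break
        selected.append(best_var)
        remaining.remove(best_var)
        current_bic = best_bic
        path.append((best_var, best_bic))
    return path, selected


# ---------------------------------------------------------------------------
# VIF filter
# ---------------------------------------------------------------------------


def vif_filter(
    X: pd.DataFrame, threshold: float = 10.0
) -> tuple[dict[str, float], pd.DataFrame]:
    """Iteratively remove columns with variance inflation factor > threshold.

    VIF_j = 1 / (1 - R^2_j) from the OLS regression of column j on the
    others (with intercept).  Perfectly collinear columns get VIF = +inf and
    leave first; the table records each column's VIF at its moment of removal
    and the final VIFs of the survivors.
    """
    if X.shape[1] < 2:
        raise ValueError("need at least two columns")
    work = X.copy()
    table: dict[str, float] = {}

    def _vifs(df: pd.DataFrame) -> dict[str, float]:
        out = {}
        M = df.to_numpy(dtype=float)
        for j, c in enumerate(df.columns):
            others = np.column_stack([np.ones(len(df)), np.delete(M, j, axis=1)])
            yj = M[:, j]
            coef, _, _, _ = np.linalg.lstsq(others, yj, rcond=None)
            resid = yj - others @ coef
            ss_tot = float(np.sum((yj - yj.mean()) ** 2))
            ss_res = float(np.sum(resid**2))
            if ss_tot <= 0:
                out[c] = np.inf
                continue
            r2 = 1.0 - ss_res / ss_tot
            out[c] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        return out

    while work.shape[1] >= 2:
        vifs = _vifs(work)
        worst = max(vifs, key=lambda c: vifs[c])
        if vifs[worst] <= threshold:
            table.update(vifs)
            break
        table[worst] = vifs[worst]
        work = work.drop(columns=[worst])
    else:
        if work.shape[1] == 1:
            table[work.columns[0]] = 1.0
    return table, work


# ---------------------------------------------------------------------------
# interaction scan
# ---------------------------------------------------------------------------


def interaction_scan(
    y: np.ndarray,
    X_retained: pd.DataFrame,
    offset_log: np.ndarray | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise-interaction scan with a negative-binomial model and BH-FDR.

    For every unordered covariate pair a model with intercept, both main
    effects and the product term is fitted; the Wald p-value of the product
    term enters a Benjamini-Hochberg adjustment across all pairs.  Pairs with
    adjusted p < alpha are flagged for inclusion in the spatial model.  Fit
    failures are recorded with NaN p-values and excluded from the FDR family.
    """
    cols = list(X_retained.columns)
    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            a, b = cols[i], cols[j]
            design = X_retained[[a, b]].copy()
            design[f"{a}:{b}"] = X_retained[a] * X_retained[b]
            try:
                fit = fit_glm(y, design, offset_log, family="negative_binomial")
                coef = float(fit.coefficients[-1])
                p = float(fit.wald_pvalues()[-1])
            except (ValueError, RuntimeError, np.linalg.LinAlgError) as exc:
                warnings.warn(f"interaction fit failed for ({a}, {b}): {exc}")
                coef, p = np.nan, np.nan
            rows.append({"pair": (a, b), "coefficient": coef, "p_raw": p})
    out = pd.DataFrame(rows)
    ok = out["p_raw"].notna()
    out["p_adjusted"] = np.nan
    if ok.any():
        out.loc[ok, "p_adjusted"] = multipletests(out.loc[ok, "p_raw"], method="fdr_bh")[1]
    out["kept"] = out["p_adjusted"] < alpha
    return out


# ---------------------------------------------------------------------------
# chained-equation imputation
# ---------------------------------------------------------------------------


def impute_chained(
    X_with_missing: pd.DataFrame,
    n_iterations: int = 10,
    regressor: str = "random_forest",
    seed: int = 0,
) -> pd.DataFrame:
    """Complete missing covariate cells by chained-equation sweeps.

    Missing cells start at their column means; then each column with missing
    values is regressed on all other (current) columns using its observed
    rows, and its missing cells are replaced by the predictions, cycling for
    ``n_iterations`` sweeps.  A single completed dataset is returned (the
    completed values feed the spatial model directly; no multiple-imputation
    pooling).  Deterministic given the seed.
    """
    if regressor not in ("linear", "random_forest"):
        raise ValueError(f"unknown regressor {regressor!r}")
    X = X_with_missing.copy()
    mask = X.isna()
    if not mask.to_numpy().any():
        return X
    for c in X.columns:
        if mask[c].all():
            raise ValueError(f"column {c!r} has no observed values")
    filled = X.fillna(X.mean())
    targets = [c for c in X.columns if mask[c].any()]
    if X.shape[1] == 1:
        return filled  # nothing to regress on; mean imputation is the best available
    for sweep in range(n_iterations):
        for ci, c in enumerate(targets):
            others = [o for o in X.columns if o != c]
            obs = ~mask[c]
            if regressor == "linear":
                model = LinearRegression()
            else:
                model = RandomForestRegressor(
                    n_estimators=100,
                    random_state=(seed * 1009 + ci) % (2**31 - 1),
                )
            model.fit(filled.loc[obs, others], filled.loc[obs, c])
            filled.loc[mask[c], c] = model.predict(filled.loc[mask[c], others])
    return filled


# ---------------------------------------------------------------------------
# the full funnel
# ---------------------------------------------------------------------------


@dataclass
class ScreeningReport:
    """Record of every screening stage's decisions."""

    correlation_dropped: list[tuple[str, str, float]]
    bic_path: list[tuple[str, float]]
    vif_table: dict[str, float]
    retained: list[str]
    interactions: pd.DataFrame
    imputation: dict = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "correlation_dropped": [
                {"variable": v, "partner": p, "r": r} for v, p, r in self.correlation_dropped
            ],
            "bic_path": [{"variable": v, "bic": b} for v, b in self.bic_path],
            "vif_table": {k: (None if np.isinf(v) else v) for k, v in self.vif_table.items()},
            "retained": self.retained,
            "interactions": [
                {
                    "pair": list(row["pair"]),
                    "coefficient": None if pd.isna(row["coefficient"]) else row["coefficient"],
                    "p_raw": None if pd.isna(row["p_raw"]) else row["p_raw"],
                    "p_adjusted": None if pd.isna(row["p_adjusted"]) else row["p_adjusted"],
                    "kept": bool(row["kept"]),
                }
                for _, row in self.interactions.iterrows()
            ],
            "imputation": self.imputation,
        }


def run_screening(
    y: np.ndarray,
    X: pd.DataFrame,
    offset_log: np.ndarray | None = None,
    corr_threshold: float = 0.6,
    vif_threshold: float = 10.0,
    fdr_alpha: float = 0.05,
    imputer: str = "random_forest",
    impute_sweeps: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, ScreeningReport]:
    """Impute, then run the correlation -> forward-BIC -> VIF -> FDR funnel.

    Returns the retained covariate table and the full report.
    """
    imput_info: dict = {}
    if X.isna().to_numpy().any():
        n_missing_rows = int(X.isna().any(axis=1).sum())
        imput_info = {
            "affected_rows": n_missing_rows,
            "percent": round(100.0 * n_missing_rows / len(X), 2),
            "regressor": imputer,
            "sweeps": impute_sweeps,
        }
        X = impute_chained(X, n_iterations=impute_sweeps, regressor=imputer, seed=seed)
    X1, dropped = correlation_filter(X, corr_threshold) if X.shape[1] >= 2 else (X, [])
    path, selected = forward_bic(y, X1, offset_log, family="poisson")
    X2 = X1[selected] if selected else X1.iloc[:, :0]
    if X2.shape[1] >= 2:
        vifs, X3 = vif_filter(X2, vif_threshold)
    else:
        vifs, X3 = ({c: 1.0 for c in X2.columns}, X2)
    if X3.shape[1] >= 2:
        inter = interaction_scan(y, X3, offset_log, alpha=fdr_alpha)
    else:
        inter = pd.DataFrame(columns=["pair", "coefficient", "p_raw", "p_adjusted", "kept"])
    report = ScreeningReport(
        correlation_dropped=dropped,
        bic_path=path,
        vif_table=vifs,
        retained=list(X3.columns),
        interactions=inter,
        imputation=imput_info,
    )
    return X3, report
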