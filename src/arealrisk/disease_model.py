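"""Hierarchical Bayesian disease mapping fitted by nested Laplace approximation.

The observation model is the classical small-area count model

    Y_i ~ Poisson(E_i * theta_i),     log(theta_i) = b0 + x_i' beta + b_i

where ``E_i`` are expected counts (internally standardized so that the total
observed and expected counts agree), ``theta_i`` is the area relative risk and
``b_i`` is a spatial random effect.  Four random-effect variants are
supported: none (a plain GLM), IID Gaussian noise, the intrinsic CAR field,
and the BYM convolution in its modern scaled (BYM2) form

    b = sigma * ( sqrt(phi) * u  +  sqrt(1 - phi) * v ),

with ``u`` a variance-scaled ICAR field (sum-to-zero per graph component),
``v`` standard Gaussian noise, ``sigma`` the marginal SD of the combined
effect and ``phi`` in [0, 1] the fraction of that variance which is spatially
structured.  A negative-binomial likelihood is available for overdispersion
checks; it adds the log dispersion as a third hyperparameter dimension.

Inference mirrors the INLA recipe for latent Gaussian models: for each
hyperparameter configuration the latent field (intercept, slopes, spatial
modes) is maximized by Newton iterations, a Gaussian approximation is formed
at the mode, and the resulting Laplace evidence — likelihood times latent
prior over the Gaussian approximation's density, times the hyperprior — is
evaluated on a regular grid centred at the numerically located hyperparameter
mode.  Latent marginals are weight-mixed Gaussians across the grid; the
``kld`` column reports how far each fixed-effect mixture is from a single
moment-matched Gaussian.  All spatial algebra is done in the eigenbasis of
the scaled ICAR precision, which diagonalizes every prior variant and turns
the sum-to-zero constraints into dropped null modes.

Priors follow penalized-complexity practice: an exponential tail prior
P(sigma > U) = alpha on the marginal SD and a one-parameter Beta prior on phi
calibrated by a tail probability; fixed effects get weak Gaussian priors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.special import gammaln, logsumexp, ndtr

from .spatial_weights import AreaGraph, icar_precision

__all__ = [
    "AreaData",
    "PcPriors",
    "ModelSpec",
    "PosteriorFit",
    "expected_counts",
    "fit_model",
    "dic",
    "waic",
    "compare_models",
    "confounding_check",
    "format_percent_change",
    "residuals",
    "aggregate_posterior_counts",
]

_EIG_TOL_FACTOR = 1e-8
_ETA_CLIP = 40.0  # linear-predictor clip; exp(40) already dwarfs any count


# ---------------------------------------------------------------------------
# data container and expected counts
# ---------------------------------------------------------------------------


@dataclass
class AreaData:
    """Per-area counts, population, expected counts and covariates.

    ``X`` is a named covariate table aligned to ``area_ids``;
    ``missing_mask`` (same shape, boolean) marks covariate cells that were
    observed as missing before imputation.
    """

    area_ids: list[str]
    y: np.ndarray
    population: np.ndarray
    X: pd.DataFrame
    E: np.ndarray | None = None
    missing_mask: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        self.population = np.asarray(self.population, dtype=float)
        n = len(self.area_ids)
        if len(self.y) != n or len(self.population) != n or len(self.X) != n:
            raise ValueError("AreaData fields must share the number of areas")
        if np.any(self.y < 0):
            raise ValueError("counts must be nonnegative")
        if np.any(self.population <= 0):
            raise ValueError("populations must be positive")

    @property
    def n(self) -> int:
        return len(self.area_ids)

    def with_expected_counts(self) -> "AreaData":
        out = replace(self)
        out.E = expected_counts(self.y, self.population)
        return out

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"area_id": self.area_ids, "y": self.y, "population": self.population})
        if self.E is not None:
            df["E"] = self.E
        for c in self.X.columns:
            df[c] = self.X[c].to_numpy()
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "AreaData":
        df = pd.read_csv(path, dtype={"area_id": str})
        reserved = {"area_id", "y", "population", "E"}
        covs = [c for c in df.columns if c not in reserved]
        X = df[covs].copy()
        mask = X.isna()
        return cls(
            area_ids=df["area_id"].tolist(),
            y=df["y"].to_numpy(),
            population=df["population"].to_numpy(float),
            X=X,
            E=df["E"].to_numpy(float) if "E" in df.columns else None,
            missing_mask=mask if mask.to_numpy().any() else None,
        )


def expected_counts(y: np.ndarray, population: np.ndarray) -> np.ndarray:
    """Internally standardized expected counts: E_i = pop_i * (sum y / sum pop).

    The overall rate is applied to each area's population, so the expected
    counts reproduce the observed total exactly and the implied SMR y/E
    averages (count-weighted) to one.
    """
    y = np.asarray(y, dtype=float)
    population = np.asarray(population, dtype=float)
    total_pop = population.sum()
    if total_pop <= 0:
        raise ValueError("total population must be positive")
    return population * (y.sum() / total_pop)


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PcPriors:
    """Prior settings: PC-style tail priors on (sigma, phi), Gaussian betas.

    ``P(sigma > sd_u) = sd_alpha`` (exponential on sigma);
    ``P(phi < phi_u) = phi_alpha`` via a Beta(a, 1) shape solved from the
    tail condition.  Fixed effects are Gaussian with the given precisions.
    """

    sd_u: float = 1.0
    sd_alpha: float = 0.01
    phi_u: float = 0.5
    phi_alpha: float = 2.0 / 3.0
    beta_precision: float = 0.001
    intercept_precision: float = 1e-6

    def __post_init__(self) -> None:
        if not (0 < self.sd_alpha < 1) or not (0 < self.phi_alpha < 1):
            raise ValueError("prior tail probabilities must lie in (0, 1)")

    @property
    def sd_rate(self) -> float:
        return -math.log(self.sd_alpha) / self.sd_u

    @property
    def phi_beta_a(self) -> float:
        # Beta(a, 1): P(phi < u) = u^a  =>  a = log(alpha) / log(u)
        return math.log(self.phi_alpha) / math.log(self.phi_u)


_FAMILIES = ("poisson", "negative_binomial")
_EFFECTS = ("none", "iid", "icar", "bym")


@dataclass(frozen=True)
class ModelSpec:
    """Likelihood family, random-effect structure, priors and grid settings."""

    likelihood: str = "poisson"
    random_effect: str = "bym"
    priors: PcPriors = field(default_factory=PcPriors)
    grid_points: int = 9
    grid_span: float = 3.0
    nb_grid_points: int = 7
    car_rho: float | None = None
    n_draws: int = 1000
    seed: int = 0
    # fit on z-scored covariates for conditioning, report slopes per raw unit;
    # the intercept is then the log-risk at the covariate means
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.likelihood not in _FAMILIES:
            raise ValueError(f"unknown likelihood {self.likelihood!r}")
        if self.random_effect not in _EFFECTS:
            raise ValueError(f"unknown random effect {self.random_effect!r}")
        if self.grid_points < 3 or self.nb_grid_points < 3:
            raise ValueError("grid resolution must be at least 3 per dimension")


# ---------------------------------------------------------------------------
# likelihood pieces
# ---------------------------------------------------------------------------


def _poisson_loglik(y, mu):
    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))


def _poisson_grad_hess(y, mu):
    return y - mu, mu


def _nb_loglik(y, mu, th):
    return float(
        np.sum(
            gammaln(y + th)
            - gammaln(th)
            - gammaln(y + 1.0)
            + th * np.log(th / (th + mu))
            + y * np.log(mu / (th + mu))
        )
    )


def _nb_grad_hess(y, mu, th):
    grad = (y - mu) * th / (th + mu)
    hess = mu * th * (th + y) / (th + mu) ** 2
    return grad, hess


# ---------------------------------------------------------------------------
# latent basis in the ICAR eigenbasis
# ---------------------------------------------------------------------------


@dataclass
class _Basis:
    """Design pieces for one model variant.

    ``A`` is the full dense design [1 | X | V] mapping the latent vector
    z = (intercept, beta, w) to the linear predictor; ``lam`` holds the
    eigenvalues of the scaled ICAR precision aligned to the field modes
    (empty when there is no field; ones are irrelevant for the IID variant).
    """

    A: np.ndarray
    p1: int  # number of fixed-effect columns incl. intercept
    m: int  # number of field modes
    V: np.ndarray | None
    lam: np.ndarray
    kind: str


def _build_basis(data: AreaData, graph: AreaGraph | None, spec: ModelSpec) -> _Basis:
    n = data.n
    Xc = data.X.to_numpy(dtype=float) if data.X.shape[1] else np.empty((n, 0))
    fixed = np.column_stack([np.ones(n), Xc]) if Xc.size else np.ones((n, 1))
    kind = spec.random_effect
    if kind == "none":
        return _Basis(A=fixed, p1=fixed.shape[1], m=0, V=None, lam=np.empty(0), kind=kind)
    if kind == "iid":
        V = np.eye(n)
        A = np.column_stack([fixed, V])
        return _Basis(A=A, p1=fixed.shape[1], m=n, V=V, lam=np.ones(n), kind=kind)
    if graph is None:
        raise ValueError("structured random effects require an AreaGraph")
    if list(graph.area_ids) != list(data.area_ids):
        raise ValueError("data and graph area ids are not aligned")
    if kind == "icar" and spec.car_rho is not None:
        # proper CAR with fixed propriety parameter: precision D - rho*A
        Aadj = graph.adjacency().toarray()
        D = np.diag(Aadj.sum(axis=1))
        Q = D - spec.car_rho * Aadj
        lam, V = np.linalg.eigh(Q)
        keep = lam > _EIG_TOL_FACTOR * max(lam.max(), 1.0)
        lam, V = lam[keep], V[:, keep]
    else:
        prec = icar_precision(graph, scaled=True)
        Qs = prec.Q_scaled.toarray()
        lam, V = np.linalg.eigh(Qs)
        lam = np.maximum(lam, 0.0)
        if kind == "icar":
            keep = lam > _EIG_TOL_FACTOR * max(lam.max(), 1.0)
            lam, V = lam[keep], V[:, keep]
    A = np.column_stack([fixed, V])
    return _Basis(A=A, p1=fixed.shape[1], m=V.shape[1], V=V, lam=lam, kind=kind)


def _mode_variances(basis: _Basis, sigma: float, phi: float) -> np.ndarray:
    """Prior variance of each field mode under the variant's parameterization."""
    if basis.m == 0:
        return np.empty(0)
    if basis.kind == "iid":
        return np.full(basis.m, sigma**2)
    if basis.kind == "icar":
        return sigma**2 / basis.lam
    tol = _EIG_TOL_FACTOR * max(basis.lam.max(), 1.0)
    lam_inv = np.where(basis.lam > tol, 1.0 / np.maximum(basis.lam, tol), 0.0)
    return sigma**2 * (phi * lam_inv + (1.0 - phi))


def _structured_shrinkage(basis: _Basis, sigma: float, phi: float):
    """Per-mode share of the BYM mode that is structured, plus its residual var."""
    tol = _EIG_TOL_FACTOR * max(basis.lam.max(), 1.0)
    lam_inv = np.where(basis.lam > tol, 1.0 / np.maximum(basis.lam, tol), 0.0)
    num = phi * lam_inv
    den = num + (1.0 - phi)
    s = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    cond = sigma**2 * num * (1.0 - s)
    return s, cond


# ---------------------------------------------------------------------------
# inner Newton optimization of the latent field
# ---------------------------------------------------------------------------


def _newton_mode(y, offset, A, prior_prec, family, th, z0=None, max_iter=100, tol=1e-6):
    """Maximize loglik(eta) - 0.5 z'Pz for the latent vector z; eta = A z."""
    n, q = A.shape
    z = np.zeros(q) if z0 is None else z0.copy()
    eta = A @ z

    def _ll(eta_v):
        mu = np.exp(np.clip(offset + eta_v, -_ETA_CLIP, _ETA_CLIP))
        if family == "poisson":
            return _poisson_loglik(y, mu), mu
        return _nb_loglik(y, mu, th), mu

    f, mu = _ll(eta)
    f -= 0.5 * float(prior_prec @ (z * z))
    for it in range(max_iter):
        if family == "poisson":
            g_eta, w = _poisson_grad_hess(y, mu)
        else:
            g_eta, w = _nb_grad_hess(y, mu, th)
        grad = A.T @ g_eta - prior_prec * z
        if np.max(np.abs(grad)) < tol:
            break
        H = (A.T * w) @ A
        H[np.diag_indices_from(H)] += prior_prec
        try:
            L = sla.cholesky(H, lower=True)
        except sla.LinAlgError:
            H[np.diag_indices_from(H)] += 1e-8 * np.trace(H) / q
            L = sla.cholesky(H, lower=True)
        step = sla.cho_solve((L, True), grad)
        # step halving to guarantee ascent
        t = 1.0
        for _ in range(30):
            z_new = z + t * step
            eta_new = A @ z_new
            f_new, mu_new = _ll(eta_new)
            f_new -= 0.5 * float(prior_prec @ (z_new * z_new))
            if f_new >= f - 1e-9 * (1.0 + abs(f)):
                break
            t *= 0.5
        else:
            raise RuntimeError("Newton step failed to improve the log joint")
        z, eta, mu, f = z_new, eta_new, mu_new, f_new
    else:
        raise RuntimeError(f"latent Newton did not converge in {max_iter} iterations")
    if family == "poisson":
        g_eta, w = _poisson_grad_hess(y, mu)
    else:
        g_eta, w = _nb_grad_hess(y, mu, th)
    H = (A.T * w) @ A
    H[np.diag_indices_from(H)] += prior_prec
    L = sla.cholesky(H, lower=True)
    ll = f + 0.5 * float(prior_prec @ (z * z))
    return z, L, ll, f


# ---------------------------------------------------------------------------
# hyperparameter handling
# ---------------------------------------------------------------------------


def _theta_dims(spec: ModelSpec) -> list[str]:
    dims: list[str] = []
    if spec.random_effect in ("iid", "icar"):
        dims.append("log_sigma")
    elif spec.random_effect == "bym":
        dims += ["log_sigma", "logit_phi"]
    if spec.likelihood == "negative_binomial":
        dims.append("log_dispersion")
    return dims


_THETA_BOUNDS = {"log_sigma": (-10.0, 5.0), "logit_phi": (-12.0, 12.0), "log_dispersion": (-10.0, 10.0)}


def _clamp_theta(theta: np.ndarray, dims: Sequence[str]) -> np.ndarray:
    out = np.array(theta, dtype=float)
    for i, d in enumerate(dims):
        lo, hi = _THETA_BOUNDS[d]
        out[i] = min(max(out[i], lo), hi)
    return out


def _unpack_theta(theta: np.ndarray, dims: Sequence[str]) -> dict[str, float]:
    vals = dict(zip(dims, theta))
    out = {"sigma": 1.0, "phi": 1.0, "dispersion": 1.0}
    if "log_sigma" in vals:
        out["sigma"] = math.exp(vals["log_sigma"])
    if "logit_phi" in vals:
        out["phi"] = 1.0 / (1.0 + math.exp(-vals["logit_phi"]))
    if "log_dispersion" in vals:
        out["dispersion"] = math.exp(vals["log_dispersion"])
    if "log_sigma" in vals and "logit_phi" not in vals:
        out["phi"] = 1.0
    return out


def _log_hyperprior(theta: np.ndarray, dims: Sequence[str], priors: PcPriors) -> float:
    """Log prior density of theta in its transformed coordinates."""
    vals = dict(zip(dims, theta))
    lp = 0.0
    if "log_sigma" in vals:
        sigma = math.exp(vals["log_sigma"])
        rate = priors.sd_rate
        lp += math.log(rate) - rate * sigma + vals["log_sigma"]  # + Jacobian d sigma/d log sigma
    if "logit_phi" in vals:
        phi = 1.0 / (1.0 + math.exp(-vals["logit_phi"]))
        a = priors.phi_beta_a
        lp += math.log(a) + (a - 1.0) * math.log(phi) + math.log(phi) + math.log(1.0 - phi)
    if "log_dispersion" in vals:
        # weakly informative lognormal on the NB size parameter
        lp += -0.5 * (vals["log_dispersion"] / 3.0) ** 2 - math.log(3.0) - 0.5 * math.log(2 * math.pi)
    return lp


# ---------------------------------------------------------------------------
# posterior container
# ---------------------------------------------------------------------------


@dataclass
class PosteriorFit:
    """Grid-mixed Gaussian approximation to the posterior of one model."""

    spec: ModelSpec
    area_ids: list[str]
    covariate_names: list[str]
    grid: pd.DataFrame  # theta columns + log_posterior + weight
    fixed_effects: pd.DataFrame  # mean, sd, q025, q50, q975, kld, rr columns
    area_effects: pd.DataFrame  # structured/unstructured mean and sd
    rr: pd.DataFrame  # mean, lower, upper, median
    hyper: dict
    dic: float
    waic: float
    p_eff_dic: float
    p_eff_waic: float
    mc_se_dic: float
    mc_se_waic: float
    fitted_means: np.ndarray
    linpred_mean: np.ndarray
    offset: np.ndarray
    y: np.ndarray
    mu_draws: np.ndarray  # n_draws x n posterior draws of the fitted count
    deviance_draws: np.ndarray

    def summary_json(self) -> dict:
        return {
            "model": {
                "likelihood": self.spec.likelihood,
                "random_effect": self.spec.random_effect,
            },
            "fixed_effects": self.fixed_effects.round(6).reset_index().to_dict(orient="records"),
            "hyperparameters": self.hyper,
            "dic": self.dic,
            "waic": self.waic,
            "p_eff_dic": self.p_eff_dic,
            "p_eff_waic": self.p_eff_waic,
        }


# ---------------------------------------------------------------------------
# mixture helpers
# ---------------------------------------------------------------------------


def _mixture_mean_var(weights, means, variances):
    mean = weights @ means
    second = weights @ (variances + means**2)
    return mean, np.maximum(second - mean**2, 0.0)


def _mixture_quantiles(weights, means, sds, probs, iters=70):
    """Quantiles of a K-component Gaussian mixture, vectorized over scalars.

    ``means``/``sds`` are (K, d); returns (len(probs), d).
    """
    lo = np.min(means - 9.0 * sds, axis=0)
    hi = np.max(means + 9.0 * sds, axis=0)
    out = np.empty((len(probs), means.shape[1]))
    w = weights[:, None]
    for ip, prob in enumerate(probs):
        a, b = lo.copy(), hi.copy()
        for _ in range(iters):
            mid = 0.5 * (a + b)
            cdf = np.sum(w * ndtr((mid[None, :] - means) / sds), axis=0)
            below = cdf < prob
            a = np.where(below, mid, a)
            b = np.where(below, b, mid)
        out[ip] = 0.5 * (a + b)
    return out


def _mixture_kld(weights, means, sds, npts=1001):
    """KL(mixture || moment-matched Gaussian) per scalar, by quadrature."""
    K, d = means.shape
    mean, var = _mixture_mean_var(weights, means, sds**2)
    sd = np.sqrt(np.maximum(var, 1e-300))
    klds = np.empty(d)
    for j in range(d):
        xs = np.linspace(mean[j] - 8 * sd[j], mean[j] + 8 * sd[j], npts)
        comp = np.exp(-0.5 * ((xs[None, :] - means[:, j, None]) / sds[:, j, None]) ** 2) / (
            np.sqrt(2 * np.pi) * sds[:, j, None]
        )
        mix = weights @ comp
        gauss = np.exp(-0.5 * ((xs - mean[j]) / sd[j]) ** 2) / (np.sqrt(2 * np.pi) * sd[j])
        good = mix > 1e-300
        integrand = np.zeros_like(xs)
        integrand[good] = mix[good] * (np.log(mix[good]) - np.log(np.maximum(gauss[good], 1e-300)))
        klds[j] = max(float(np.trapezoid(integrand, xs)), 0.0)
    return klds


# ---------------------------------------------------------------------------
# the fit
# ---------------------------------------------------------------------------


def fit_model(data: AreaData, graph: AreaGraph | None, spec: ModelSpec) -> PosteriorFit:
    """Fit one model variant and return its grid-mixed posterior approximation."""
    if data.E is None:
        raise ValueError("expected counts E must be set before fitting (see expected_counts)")
    if np.any((data.E <= 0) & (data.y > 0)):
        raise ValueError("E = 0 with y > 0 gives a non-finite posterior")
    if data.X.isna().to_numpy().any():
        raise ValueError("covariates contain missing values; impute first")
    y = np.asarray(data.y, dtype=float)
    offset = np.log(np.asarray(data.E, dtype=float))
    col_scale = None
    if spec.standardize and data.X.shape[1]:
        scales = data.X.std(ddof=0).replace(0.0, 1.0)
        Xz = (data.X - data.X.mean()) / scales
        data = replace(data, X=Xz)
        col_scale = scales.to_numpy(dtype=float)
    basis = _build_basis(data, graph, spec)
    A, p1, m = basis.A, basis.p1, basis.m
    q = A.shape[1]
    priors = spec.priors
    prior_fixed = np.concatenate(
        [[priors.intercept_precision], np.full(p1 - 1, priors.beta_precision)]
    )
    dims = _theta_dims(spec)
    warm = {"z": None}

    def _prior_prec(theta_vals) -> np.ndarray:
        if m == 0:
            return prior_fixed
        mv = _mode_variances(basis, theta_vals["sigma"], theta_vals["phi"])
        return np.concatenate([prior_fixed, 1.0 / mv])

    def _log_posterior(theta: np.ndarray, keep=False):
        theta = _clamp_theta(theta, dims)
        vals = _unpack_theta(theta, dims)
        P = _prior_prec(vals)
        try:
            z, L, ll, _ = _newton_mode(
                y, offset, A, P, spec.likelihood, vals["dispersion"], z0=warm["z"]
            )
        except RuntimeError:
            # warm start from a distant grid point can stall; retry cold
            z, L, ll, _ = _newton_mode(y, offset, A, P, spec.likelihood, vals["dispersion"])
        warm["z"] = z
        logdet_post = 2.0 * float(np.sum(np.log(np.diag(L))))
        lp = (
            ll
            + 0.5 * float(np.sum(np.log(P)))
            - 0.5 * float(P @ (z * z))
            - 0.5 * logdet_post
            + _log_hyperprior(theta, dims, priors)
        )
        if keep:
            return lp, z, L, vals
        return lp

    # --- hyperparameter mode and grid -------------------------------------
    if dims:
        x0 = []
        for d in dims:
            x0.append({"log_sigma": math.log(0.5), "logit_phi": 0.0, "log_dispersion": math.log(5.0)}[d])
        x0 = np.array(x0)
        from scipy.optimize import minimize

        res = minimize(
            lambda t: -_log_posterior(t),
            x0,
            method="Nelder-Mead",
            options={"xatol": 0.02, "fatol": 0.005, "maxiter": 200},
        )
        mode = res.x
        # finite-difference Hessian -> grid standard deviations
        h = 0.25
        nd = len(dims)
        H = np.zeros((nd, nd))
        f0 = -_log_posterior(mode)
        for i in range(nd):
            ei = np.zeros(nd)
            ei[i] = h
            fp = -_log_posterior(mode + ei)
            fm = -_log_posterior(mode - ei)
            H[i, i] = (fp - 2 * f0 + fm) / h**2
            for j in range(i + 1, nd):
                ej = np.zeros(nd)
                ej[j] = h
                fpp = -_log_posterior(mode + ei + ej)
                fpm = -_log_posterior(mode + ei - ej)
                fmp = -_log_posterior(mode - ei + ej)
                fmm = -_log_posterior(mode - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h**2)
        sds = np.full(nd, 0.5)
        try:
            cov = np.linalg.inv(H)
            dg = np.diag(cov)
            if np.all(dg > 0):
                sds = np.sqrt(dg)
        except np.linalg.LinAlgError:
            pass
        sds = np.clip(sds, 0.05, 2.0)
        axes = []
        for i, dname in enumerate(dims):
            g = spec.nb_grid_points if dname == "log_dispersion" else spec.grid_points
            axes.append(mode[i] + np.linspace(-spec.grid_span, spec.grid_span, g) * sds[i])
        mesh = np.meshgrid(*axes, indexing="ij")
        thetas = np.column_stack([mm.ravel() for mm in mesh])
    else:
        thetas = np.zeros((1, 0))

    K = thetas.shape[0]
    logposts = np.empty(K)
    node_z = np.empty((K, q))
    node_L: list[np.ndarray] = []
    fixed_mean = np.empty((K, p1))
    fixed_sd = np.empty((K, p1))
    eta_mean = np.empty((K, data.n))
    eta_sd = np.empty((K, data.n))
    b_mean = np.zeros((K, data.n))
    b_var = np.zeros((K, data.n))
    u_mean = np.zeros((K, data.n))
    u_var = np.zeros((K, data.n))
    theta_vals_list = []

    for k in range(K):
        try:
            lp, z, L, vals = _log_posterior(thetas[k], keep=True)
        except RuntimeError as exc:
            raise RuntimeError(
                f"latent optimization failed at grid point {dict(zip(dims, thetas[k]))}: {exc}"
            ) from exc
        logposts[k] = lp
        node_z[k] = z
        node_L.append(L)
        theta_vals_list.append(vals)
        # marginal variances of linear functionals via triangular solves
        S_eta = sla.solve_triangular(L, A.T, lower=True)  # q x n
        eta_mean[k] = A @ z
        eta_sd[k] = np.sqrt(np.sum(S_eta**2, axis=0))
        Iq = np.eye(q)[:, :p1]
        S_fix = sla.solve_triangular(L, Iq, lower=True)
        fixed_mean[k] = z[:p1]
        fixed_sd[k] = np.sqrt(np.sum(S_fix**2, axis=0))
        if m:
            V = basis.V
            Bf = np.zeros((q, data.n))
            Bf[p1:, :] = V.T
            S_b = sla.solve_triangular(L, Bf, lower=True)
            b_mean[k] = V @ z[p1:]
            b_var[k] = np.sum(S_b**2, axis=0)
            if basis.kind == "icar":
                u_mean[k], u_var[k] = b_mean[k], b_var[k]
            elif basis.kind == "bym":
                s, cond = _structured_shrinkage(basis, vals["sigma"], vals["phi"])
                Bu = np.zeros((q, data.n))
                Bu[p1:, :] = (s[:, None] * V.T)
                S_u = sla.solve_triangular(L, Bu, lower=True)
                u_mean[k] = V @ (s * z[p1:])
                u_var[k] = np.sum(S_u**2, axis=0) + (V**2) @ cond

    weights = np.exp(logposts - logsumexp(logposts))
    weights /= weights.sum()

    if col_scale is not None:
        # slopes back to the raw covariate scale (linear reparameterization)
        fixed_mean[:, 1:] /= col_scale[None, :]
        fixed_sd[:, 1:] /= col_scale[None, :]

    # --- mixture summaries --------------------------------------------------
    fe_mean, fe_var = _mixture_mean_var(weights, fixed_mean, fixed_sd**2)
    fe_q = _mixture_quantiles(weights, fixed_mean, fixed_sd, [0.025, 0.5, 0.975])
    fe_kld = _mixture_kld(weights, fixed_mean, fixed_sd)
    coef_names = ["(intercept)"] + list(data.X.columns)
    fixed_effects = pd.DataFrame(
        {
            "mean": fe_mean,
            "sd": np.sqrt(fe_var),
            "q025": fe_q[0],
            "q50": fe_q[1],
            "q975": fe_q[2],
            "kld": fe_kld,
            "rr": np.exp(fe_q[1]),
            "rr_mean": weights @ np.exp(fixed_mean + 0.5 * fixed_sd**2),
            "rr_lower": np.exp(fe_q[0]),
            "rr_upper": np.exp(fe_q[2]),
        },
        index=coef_names,
    )

    eta_q = _mixture_quantiles(weights, eta_mean, eta_sd, [0.025, 0.5, 0.975])
    rr_mean_post = weights @ np.exp(eta_mean + 0.5 * eta_sd**2)
    rr = pd.DataFrame(
        {
            "mean": rr_mean_post,
            "lower": np.exp(eta_q[0]),
            "median": np.exp(eta_q[1]),
            "upper": np.exp(eta_q[2]),
        },
        index=pd.Index(data.area_ids, name="area_id"),
    )

    um, uv = _mixture_mean_var(weights, u_mean, u_var)
    bm, bv = _mixture_mean_var(weights, b_mean, b_var)
    vm = bm - um
    # unstructured variance: var(b - u); the cross term is approximated via
    # the per-node decomposition var(v) = var(b) - var(u) + 2*cond; keep the
    # simple nonnegative bound instead of tracking covariances exactly.
    vv = np.maximum(bv - uv, 0.0)
    if basis.kind == "iid":
        um, uv = np.zeros(data.n), np.zeros(data.n)
        vm, vv = bm, bv
    area_effects = pd.DataFrame(
        {
            "structured_mean": um,
            "structured_sd": np.sqrt(uv),
            "unstructured_mean": vm,
            "unstructured_sd": np.sqrt(vv),
        },
        index=pd.Index(data.area_ids, name="area_id"),
    )

    lin_mean = weights @ eta_mean
    fitted = data.E * (weights @ np.exp(eta_mean + 0.5 * eta_sd**2))

    # --- hyperparameter posterior summaries --------------------------------
    hyper: dict = {}
    if dims:
        theta_mat = thetas
        grid_df = pd.DataFrame(theta_mat, columns=dims)
        if "log_sigma" in dims:
            sig = np.exp(grid_df["log_sigma"].to_numpy())
            hyper["sigma_mean"] = float(weights @ sig)
        if "logit_phi" in dims:
            phi = 1.0 / (1.0 + np.exp(-grid_df["logit_phi"].to_numpy()))
            hyper["phi_mean"] = float(weights @ phi)
            order = np.argsort(phi)
            cw = np.cumsum(weights[order])
            hyper["phi_q025"] = float(phi[order][np.searchsorted(cw, 0.025)])
            hyper["phi_q975"] = float(phi[order][min(np.searchsorted(cw, 0.975), len(phi) - 1)])
        if "log_dispersion" in dims:
            disp = np.exp(grid_df["log_dispersion"].to_numpy())
            hyper["dispersion_mean"] = float(weights @ disp)
    else:
        grid_df = pd.DataFrame(index=[0])
    grid_df["log_posterior"] = logposts
    grid_df["weight"] = weights

    # --- posterior draws, DIC and WAIC --------------------------------------
    rng = np.random.default_rng(spec.seed)
    S = spec.n_draws
    counts = rng.multinomial(S, weights)
    mu_draws = np.empty((S, data.n))
    th_draws = np.empty(S)
    pos = 0
    for k in range(K):
        c = counts[k]
        if c == 0:
            continue
        xi = rng.standard_normal((q, c))
        zd = node_z[k][:, None] + sla.solve_triangular(node_L[k].T, xi, lower=False)
        eta_d = (A @ zd).T + offset[None, :]
        mu_draws[pos : pos + c] = np.exp(np.clip(eta_d, -700.0, 700.0))
        th_draws[pos : pos + c] = theta_vals_list[k]["dispersion"]
        pos += c

    if spec.likelihood == "poisson":
        pointwise = y[None, :] * np.log(mu_draws) - mu_draws - gammaln(y + 1.0)[None, :]
    else:
        th = th_draws[:, None]
        pointwise = (
            gammaln(y[None, :] + th)
            - gammaln(th)
            - gammaln(y + 1.0)[None, :]
            + th * np.log(th / (th + mu_draws))
            + y[None, :] * np.log(mu_draws / (th + mu_draws))
        )
    dev_draws = -2.0 * pointwise.sum(axis=1)
    mean_dev = float(dev_draws.mean())
    mu_at_mean = data.E * np.exp(np.clip(lin_mean, -_ETA_CLIP, _ETA_CLIP))
    if spec.likelihood == "poisson":
        dev_at_mean = -2.0 * _poisson_loglik(y, mu_at_mean)
    else:
        th_mean = hyper.get("dispersion_mean", 1.0)
        dev_at_mean = -2.0 * _nb_loglik(y, mu_at_mean, th_mean)
    dic_val = 2.0 * mean_dev - dev_at_mean
    p_dic = mean_dev - dev_at_mean
    mc_se_dic = 2.0 * float(dev_draws.std(ddof=1)) / math.sqrt(S)

    lppd_i = logsumexp(pointwise, axis=0) - math.log(S)
    p_waic_i = pointwise.var(axis=0, ddof=1)
    waic_val = float(-2.0 * np.sum(lppd_i - p_waic_i))
    half = S // 2
    w1 = float(
        -2.0
        * np.sum(
            (logsumexp(pointwise[:half], axis=0) - math.log(half))
            - pointwise[:half].var(axis=0, ddof=1)
        )
    )
    w2 = float(
        -2.0
        * np.sum(
            (logsumexp(pointwise[half:], axis=0) - math.log(S - half))
            - pointwise[half:].var(axis=0, ddof=1)
        )
    )
    mc_se_waic = abs(w1 - w2) / 2.0

    return PosteriorFit(
        spec=spec,
        area_ids=list(data.area_ids),
        covariate_names=list(data.X.columns),
        grid=grid_df,
        fixed_effects=fixed_effects,
        area_effects=area_effects,
        rr=rr,
        hyper=hyper,
        dic=dic_val,
        waic=waic_val,
        p_eff_dic=p_dic,
        p_eff_waic=float(np.sum(p_waic_i)),
        mc_se_dic=mc_se_dic,
        mc_se_waic=mc_se_waic,
        fitted_means=fitted,
        linpred_mean=lin_mean,
        offset=offset,
        y=y,
        mu_draws=mu_draws,
        deviance_draws=dev_draws,
    )


def dic(fit: PosteriorFit) -> float:
    """Deviance information criterion of a fitted model."""
    return fit.dic


def waic(fit: PosteriorFit) -> float:
    """Watanabe-Akaike information criterion of a fitted model."""
    return fit.waic


# ---------------------------------------------------------------------------
# model comparison and diagnostics
# ---------------------------------------------------------------------------


def compare_models(
    data: AreaData, graph: AreaGraph | None, specs: Sequence[ModelSpec]
) -> pd.DataFrame:
    """Fit each spec on shared data and tabulate DIC/WAIC side by side.

    Failed fits yield a row of NaNs with the error message; the remaining
    rows are still ranked.  Returns the table with boolean ``dic_best`` /
    ``waic_best`` flags.
    """
    rows = []
    fits = []
    for spec in specs:
        row = {
            "likelihood": spec.likelihood,
            "random_effect": spec.random_effect,
            "dic": np.nan,
            "waic": np.nan,
            "p_eff_dic": np.nan,
            "p_eff_waic": np.nan,
            "phi_mean": np.nan,
            "phi_q025": np.nan,
            "phi_q975": np.nan,
            "error": "",
        }
        try:
            f = fit_model(data, graph, spec)
            row.update(
                dic=f.dic,
                waic=f.waic,
                p_eff_dic=f.p_eff_dic,
                p_eff_waic=f.p_eff_waic,
                phi_mean=f.hyper.get("phi_mean", np.nan),
                phi_q025=f.hyper.get("phi_q025", np.nan),
                phi_q975=f.hyper.get("phi_q975", np.nan),
            )
            fits.append(f)
        except (RuntimeError, ValueError) as exc:
            row["error"] = str(exc)
            fits.append(None)
        rows.append(row)
    table = pd.DataFrame(rows)
    table["dic_best"] = table["dic"] == table["dic"].min()
    table["waic_best"] = table["waic"] == table["waic"].min()
    table.attrs["fits"] = fits
    return table


def format_percent_change(rr_from: float, rr_to: float) -> str:
    """Render an RR shift as a signed percent change, e.g. 1.081->1.083 => '+0.2%'."""
    pct = 100.0 * (rr_to - rr_from) / rr_from
    return f"{pct:+.1f}%"


def confounding_check(
    data: AreaData,
    graph: AreaGraph,
    spec_bym: ModelSpec | None = None,
    spec_iid: ModelSpec | None = None,
    fit_bym: PosteriorFit | None = None,
    fit_iid: PosteriorFit | None = None,
) -> pd.DataFrame:
    """Spatial-confounding diagnostic: fixed effects with vs without structure.

    Compares each covariate's posterior-median RR under the IID-only model
    against the BYM model sharing the same offset and covariates, reporting
    the percent change, and correlates the BYM posterior-mean structured
    field with each covariate.  Small shifts and modest correlations indicate
    the structured effect is not proxying the covariates.
    """
    if fit_bym is None:
        fit_bym = fit_model(data, graph, spec_bym or ModelSpec(random_effect="bym"))
    if fit_iid is None:
        fit_iid = fit_model(data, graph, spec_iid or ModelSpec(random_effect="iid"))
    if fit_bym.covariate_names != fit_iid.covariate_names:
        raise ValueError("covariate sets differ between the two fits")
    covs = fit_bym.covariate_names
    u = fit_bym.area_effects["structured_mean"].to_numpy()
    rows = []
    for c in covs:
        rr_iid = float(fit_iid.fixed_effects.loc[c, "rr"])
        rr_bym = float(fit_bym.fixed_effects.loc[c, "rr"])
        x = data.X[c].to_numpy(dtype=float)
        if np.std(u) > 0 and np.std(x) > 0:
            corr = float(np.corrcoef(x, u)[0, 1])
        else:
            corr = np.nan
        rows.append(
            {
                "covariate": c,
                "rr_iid": rr_iid,
                "rr_bym": rr_bym,
                "percent_change": 100.0 * (rr_bym - rr_iid) / rr_iid,
                "formatted": format_percent_change(rr_iid, rr_bym),
                "corr_structured": corr,
            }
        )
    return pd.DataFrame(rows).set_index("covariate")


def residuals(fit: PosteriorFit, kind: str = "pearson") -> np.ndarray:
    """Pearson residuals (y - mu_hat) / sqrt(V(mu_hat)) at the posterior mean fit."""
    if kind != "pearson":
        raise ValueError("only pearson residuals are implemented")
    mu = fit.fitted_means
    if fit.spec.likelihood == "poisson":
        var = mu
    else:
        th = fit.hyper.get("dispersion_mean", 1.0)
        var = mu * (1.0 + mu / th)
    return (fit.y - mu) / np.sqrt(var)


def aggregate_posterior_counts(
    fit: PosteriorFit, grouping: Mapping[str, str]
) -> pd.DataFrame:
    """Posterior predicted counts summed within groups of areas.

    ``grouping`` maps every area id to a group label (e.g. county -> state).
    Sums are taken per posterior draw of the fitted count, so group means add
    up exactly to the overall mean; 95% intervals come from the draw quantiles.
    """
    unmapped = [a for a in fit.area_ids if a not in grouping]
    if unmapped:
        raise ValueError(f"areas missing from grouping: {unmapped[:10]}")
    labels = np.array([grouping[a] for a in fit.area_ids])
    rows = []
    for g in sorted(set(labels)):
        cols = labels == g
        draws = fit.mu_draws[:, cols].sum(axis=1)
        rows.append(
            {
                "group": g,
                "mean": float(draws.mean()),
                "lower": float(np.quantile(draws, 0.025)),
                "upper": float(np.quantile(draws, 0.975)),
            }
        )
    total = fit.mu_draws.sum(axis=1)
    rows.append(
        {
            "group": "__total__",
            "mean": float(total.mean()),
            "lower": float(np.quantile(total, 0.025)),
            "upper": float(np.quantile(total, 0.975)),
        }
    )
    return pd.DataFrame(rows).set_index("group")
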