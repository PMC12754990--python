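"""Synthetic areal datasets with known ground truth.

Real county-level disease data (survey counts joined to county polygons)
cannot be redistributed, so every downstream stage of this package is
exercised on simulated lattices that carry the exact generative structure the
models assume:

    Y_i ~ Poisson(E_i * theta_i),
    log theta_i = x_i' beta + sigma * ( sqrt(phi) u_i + sqrt(1 - phi) v_i ),

with ``u`` a variance-scaled intrinsic CAR field on the contiguity graph
(sum-to-zero within each connected component), ``v`` IID standard normal,
``sigma`` the marginal SD of the combined random effect and ``phi`` its
structured fraction (the BYM2 parameterization).  Covariates are Gaussian
with controllable mutual correlation and controllable correlation with the
structured field — the latter is what makes the spatial-confounding
diagnostic testable.  A small completely-at-random share of covariate cells
can be masked to emulate survey gaps.

Default parameter values imitate the shape of US county data: percent-scale
behavioral covariates (smoking, alcohol use, obesity), environmental
exposures (PM2.5, NO2, maximum temperature) and a 0-1 vulnerability index,
with an adult-population baseline rate of one diagnosed case per ten people
at risk and 1.62% missingness.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import box

from .disease_model import AreaData
from .spatial_weights import AreaGraph, icar_precision, write_geojson

__all__ = [
    "CovariateSpec",
    "SimulationConfig",
    "SyntheticDataset",
    "MissingnessReport",
    "make_lattice",
    "sample_icar",
    "simulate_counts",
    "inject_missing",
    "default_config",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CovariateSpec:
    """One simulated covariate.

    ``pairwise_correlation`` is the target Pearson correlation with the other
    covariates (achieved exactly when all covariates request the same value),
    ``corr_structured`` the target correlation with the standardized
    structured field.  Both enter through a shared-factor construction; the
    requested combination must leave a nonnegative idiosyncratic variance,
    otherwise the implied correlation matrix is not positive definite.
    """

    name: str
    mean: float = 0.0
    sd: float = 1.0
    pairwise_correlation: float = 0.0
    corr_structured: float = 0.0


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters for one synthetic dataset."""

    n_rows: int = 20
    n_cols: int = 20
    beta: tuple[float, ...] = (0.0,)  # intercept first, then one slope per covariate
    sigma: float = 0.5
    phi: float = 0.57
    covariates: tuple[CovariateSpec, ...] = ()
    population_range: tuple[float, float] = (5_000.0, 200_000.0)
    baseline_rate: float = 0.1
    missing_fraction: float = 0.0
    contiguity: str = "queen"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1 or self.n_rows * self.n_cols < 2:
            raise ValueError("lattice must contain at least 2 areas")
        if not (0.0 <= self.phi <= 1.0):
            raise ValueError("phi must lie in [0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if not (0.0 <= self.missing_fraction < 1.0):
            raise ValueError("missing_fraction must lie in [0, 1)")
        lo, hi = self.population_range
        if lo <= 0 or hi < lo:
            raise ValueError("population_range must be a positive interval")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if len(self.beta) != 1 + len(self.covariates):
            raise ValueError(
                "beta must have one entry per covariate plus the intercept "
                f"(got {len(self.beta)} for {len(self.covariates)} covariates)"
            )


def default_config(seed: int = 0) -> SimulationConfig:
    """Study-shaped defaults: seven county-style covariates, 20x20 lattice.

    Slopes are log relative risks per raw covariate unit; smoking and obesity
    carry small positive effects, the rest are null.  The intercept offsets
    the covariate means so the national-average relative risk is near one.
    """
    covs = (
        CovariateSpec("pct_smokers", 20.1, 3.0, 0.3, 0.0),
        CovariateSpec("pct_alcohol", 19.0, 2.0, 0.3, 0.0),
        CovariateSpec("pct_obese", 33.0, 4.0, 0.3, 0.0),
        CovariateSpec("pm25", 7.2, 1.5, 0.3, 0.0),
        CovariateSpec("no2", 8.8, 3.5, 0.3, 0.0),
        CovariateSpec("max_temp", 30.4, 3.0, 0.3, 0.0),
        CovariateSpec("svi", 0.5, 0.25, 0.3, 0.0),
    )
    slopes = (math.log(1.08), 0.0, math.log(1.007), 0.0, 0.0, 0.0, 0.0)
    intercept = -sum(b * c.mean for b, c in zip(slopes, covs))
    return SimulationConfig(
        beta=(intercept, *slopes),
        covariates=covs,
        missing_fraction=0.0162,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# lattice graphs
# ---------------------------------------------------------------------------


def make_lattice(n_rows: int, n_cols: int, contiguity: str = "queen") -> AreaGraph:
    """Regular grid of unit squares with queen or rook adjacency.

    Area ids are row-major ``A0000, A0001, ...``; each area carries its unit
    square polygon so the lattice round-trips through the GeoJSON reader and
    the polygon-based contiguity builder.
    """
    if n_rows * n_cols < 2:
        raise ValueError("lattice must contain at least 2 areas")
    if contiguity not in ("queen", "rook"):
        raise ValueError(f"unknown contiguity {contiguity!r}")
    ids = [f"A{r * n_cols + c:04d}" for r in range(n_rows) for c in range(n_cols)]
    neighbors: dict[str, set[str]] = {a: set() for a in ids}
    if contiguity == "queen":
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    for r in range(n_rows):
        for c in range(n_cols):
            a = ids[r * n_cols + c]
            for dr, dc in steps:
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols:
                    neighbors[a].add(ids[rr * n_cols + cc])
    polygons = {
        ids[r * n_cols + c]: box(c, r, c + 1, r + 1)
        for r in range(n_rows)
        for c in range(n_cols)
    }
    return AreaGraph(area_ids=ids, neighbors=neighbors, polygons=polygons)


# ---------------------------------------------------------------------------
# ICAR sampling
# ---------------------------------------------------------------------------


def sample_icar(
    graph: AreaGraph,
    tau: float = 1.0,
    seed: int | np.random.Generator = 0,
    scaled: bool = False,
) -> np.ndarray:
    """Exact draw from the intrinsic CAR distribution on a graph.

    The field has precision ``tau * (D - A)`` (or the variance-scaled BYM2
    precision when ``scaled=True``) under a sum-to-zero constraint per
    connected component.  Sampling uses the eigendecomposition of the
    precision: independent Gaussians on the positive eigenmodes, zero on the
    null modes, which is equivalent to projecting a pseudo-inverse draw onto
    the constraint subspace.  Isolated areas get value 0.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    prec = icar_precision(graph, scaled=scaled)
    Q = (prec.Q_scaled if scaled else prec.Q).toarray()
    lam, V = np.linalg.eigh(Q)
    tol = max(len(lam), 1) * np.finfo(float).eps * max(lam.max(), 1.0)
    pos = lam > tol
    z = rng.standard_normal(int(pos.sum()))
    return V[:, pos] @ (z / np.sqrt(tau * lam[pos]))


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    """Generated graph + table + the ground truth that produced them."""

    graph: AreaGraph
    table: AreaData
    truth: dict

    def write(self, outdir: str | Path, id_property: str = "area_id") -> None:
        """Serialize as GeoJSON (polygons) + CSV (attributes) + JSON (truth)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if self.graph.polygons is not None:
            write_geojson(self.graph.polygons, outdir / "areas.geojson", id_property)
        self.table.to_csv(outdir / "attributes.csv")
        truth = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in self.truth.items()
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1))


def _draw_covariates(
    rng: np.random.Generator,
    specs: Sequence[CovariateSpec],
    u_std: np.ndarray,
) -> pd.DataFrame:
    """Shared-factor covariate construction.

    Each covariate is rho * u_std + s * g + t * e with a common factor g and
    idiosyncratic noise e, where s = sqrt(r - rho^2) reproduces the requested
    pairwise correlation r exactly when all covariates request the same r,
    and t mops up the remaining unit variance.
    """
    n = len(u_std)
    g = rng.standard_normal(n)
    cols = {}
    for cs in specs:
        rho, r = cs.corr_structured, cs.pairwise_correlation
        s2 = r - rho**2
        t2 = 1.0 - rho**2 - max(s2, 0.0)
        if s2 < -1e-12 or t2 < -1e-12 or abs(rho) > 1.0:
            raise ValueError(
                f"covariate {cs.name!r}: correlation targets (pairwise={r}, "
                f"structured={rho}) imply a non-positive-definite covariance"
            )
        z = rho * u_std + math.sqrt(max(s2, 0.0)) * g + math.sqrt(max(t2, 0.0)) * rng.standard_normal(n)
        cols[cs.name] = cs.mean + cs.sd * z
    return pd.DataFrame(cols)


def simulate_counts(config: SimulationConfig) -> SyntheticDataset:
    """Generate one synthetic areal dataset with full ground truth.

    Deterministic given the config (including its seed): equal configs give
    bit-identical datasets.
    """
    rng = np.random.default_rng(config.seed)
    graph = make_lattice(config.n_rows, config.n_cols, config.contiguity)
    n = graph.n

    u = sample_icar(graph, tau=1.0, seed=rng, scaled=True)
    v = rng.standard_normal(n)
    b = config.sigma * (math.sqrt(config.phi) * u + math.sqrt(1.0 - config.phi) * v)

    if config.covariates:
        u_sd = float(np.std(u))
        u_std = u / u_sd if u_sd > 0 else np.zeros(n)
        X = _draw_covariates(rng, config.covariates, u_std)
    else:
        X = pd.DataFrame(index=range(n))

    lo, hi = config.population_range
    population = rng.uniform(lo, hi, size=n)
    E = population * config.baseline_rate

    beta = np.asarray(config.beta, dtype=float)
    eta = beta[0] + (X.to_numpy(dtype=float) @ beta[1:] if len(beta) > 1 else 0.0) + b
    mu = E * np.exp(np.clip(eta, -700, 700))
    y = rng.poisson(mu)

    table = AreaData(
        area_ids=list(graph.area_ids),
        y=y,
        population=population,
        X=X,
        E=E,
    )
    report = None
    if config.missing_fraction > 0 and config.covariates:
        table, report = inject_missing(table, config.missing_fraction, seed=rng)
    truth = {
        "beta": beta,
        "sigma": config.sigma,
        "phi": config.phi,
        "u": u,
        "v": v,
        "combined": b,
        "eta": eta,
        "missingness": None if report is None else report.as_dict(),
    }
    return SyntheticDataset(graph=graph, table=table, truth=truth)


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MissingnessReport:
    """Audit of injected missingness: how many rows were touched."""

    n_rows: int
    n_affected: int

    @property
    def percent(self) -> float:
        return round(100.0 * self.n_affected / self.n_rows, 2)

    @property
    def percent_text(self) -> str:
        return f"{self.percent:.2f}%"

    def as_dict(self) -> dict:
        return {
            "rows": self.n_rows,
            "affected_rows": self.n_affected,
            "percent": self.percent,
            "text": self.percent_text,
        }


def inject_missing(
    table: AreaData,
    fraction: float,
    seed: int | np.random.Generator = 0,
) -> tuple[AreaData, MissingnessReport]:
    """Mask covariate cells completely at random.

    ``round(fraction * n)`` rows are chosen without replacement and one
    randomly chosen covariate cell in each is set missing; counts and
    populations are never masked.  The report gives the affected-row count
    and percentage (two decimals).
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must lie in [0, 1)")
    if table.X.shape[1] == 0:
        raise ValueError("table has no covariates to mask")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = table.n
    n_mask = int(round(fraction * n))
    X = table.X.copy()
    mask = pd.DataFrame(False, index=X.index, columns=X.columns)
    if n_mask > 0:
        rows = rng.choice(n, size=n_mask, replace=False)
        cols = rng.integers(0, X.shape[1], size=n_mask)
        for r, c in zip(rows, cols):
            X.iat[int(r), int(c)] = np.nan
            mask.iat[int(r), int(c)] = True
    out = replace(table, X=X, missing_mask=mask)
    return out, MissingnessReport(n_rows=n, n_affected=n_mask)
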