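"""End-to-end orchestration of the disease-mapping workflow.

One call runs the full analysis in the order a county-level mapping study
proceeds: impute missing covariates -> screening funnel -> expected counts ->
model comparison (GLM / IID / CAR / BYM random effects; Poisson vs negative
binomial with an overdispersion report) -> final fit -> spatial-confounding
check -> residual diagnostics (global Moran, Gi*) -> LISA hotspots on the
relative risks -> SD-band tiers -> report bundle.  Inputs are either a
(geometry, attributes) file pair or a synthetic-data configuration; one
global seed drives every stochastic stage, so repeated runs are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import cluster_stats, screening, spatial_weights, synthetic_data, tiering
from .disease_model import (
    AreaData,
    ModelSpec,
    compare_models,
    confounding_check,
    expected_counts,
    fit_model,
    aggregate_posterior_counts,
    residuals,
)

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("arealrisk")


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; exactly one input source is set."""

    outdir: str = "arealrisk_output"
    seed: int = 0
    # input: either file paths ...
    geometry_path: str | None = None
    attributes_path: str | None = None
    id_property: str = "area_id"
    # ... or a simulation config
    simulate: synthetic_data.SimulationConfig | None = None
    # stage settings
    corr_threshold: float = 0.6
    vif_threshold: float = 10.0
    fdr_alpha: float = 0.05
    imputer: str = "random_forest"
    run_screening: bool = True
    grid_points: int = 5
    nb_grid_points: int = 5
    n_draws: int = 1000
    compare_negative_binomial: bool = True
    permutations: int = 999
    alpha: float = 0.05
    fdr_lisa: bool = False
    tier_center: str = "reference_1"
    grouping_column: str | None = None

    def __post_init__(self) -> None:
        has_files = self.geometry_path is not None and self.attributes_path is not None
        if has_files == (self.simulate is not None):
            raise ValueError(
                "exactly one of (geometry_path + attributes_path) or simulate must be set"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        if sim is not None:
            covs = tuple(
                synthetic_data.CovariateSpec(**c) for c in sim.pop("covariates", [])
            )
            if "beta" in sim:
                sim["beta"] = tuple(sim["beta"])
            if "population_range" in sim:
                sim["population_range"] = tuple(sim["population_range"])
            sim = synthetic_data.SimulationConfig(covariates=covs, **sim)
        return cls(simulate=sim, **raw)


def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        dataset = synthetic_data.simulate_counts(sim)
        return dataset.graph, dataset.table, dataset.truth
    polygons = spatial_weights.read_geojson(config.geometry_path, config.id_property)
    graph = spatial_weights.queen_contiguity(polygons)
    table = AreaData.from_csv(config.attributes_path)
    if list(table.area_ids) != list(graph.area_ids):
        order = {a: i for i, a in enumerate(graph.area_ids)}
        missing = [a for a in table.area_ids if a not in order]
        if missing:
            raise ValueError(f"attribute areas not in geometry: {missing[:10]}")
        perm = np.argsort([order[a] for a in table.area_ids])
        table = AreaData(
            area_ids=[table.area_ids[i] for i in perm],
            y=table.y[perm],
            population=table.population[perm],
            X=table.X.iloc[perm].reset_index(drop=True),
            E=None if table.E is None else table.E[perm],
        )
    return graph, table, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle to ``config.outdir``."""
    t0 = time.perf_counter()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start: seed=%d outdir=%s", config.seed, outdir)

    graph, table, truth = _load_inputs(config)
    log.info("inputs: %d areas, %d covariates", table.n, table.X.shape[1])

    # --- imputation + screening -------------------------------------------
    E = expected_counts(table.y, table.population)
    offset_log = np.log(E)
    screen_report = None
    X = table.X
    if X.shape[1] and config.run_screening:
        X, screen_report = screening.run_screening(
            table.y,
            X,
            offset_log,
            corr_threshold=config.corr_threshold,
            vif_threshold=config.vif_threshold,
            fdr_alpha=config.fdr_alpha,
            imputer=config.imputer,
            seed=config.seed,
        )
        log.info("screening retained %s", list(X.columns))
    elif X.isna().to_numpy().any():
        X = screening.impute_chained(X, regressor=config.imputer, seed=config.seed)
    data = AreaData(
        area_ids=list(table.area_ids),
        y=table.y,
        population=table.population,
        X=X.reset_index(drop=True),
        E=E,
    )

    # --- family check: Poisson vs negative binomial at the GLM level -------
    design = data.X if data.X.shape[1] else pd.DataFrame(np.ones((data.n, 0)))
    glm_pois = screening.fit_glm(data.y, design, offset_log, "poisson")
    overdispersion = {"poisson": screening.overdispersion_stat(glm_pois, data.y)}
    try:
        glm_nb = screening.fit_glm(data.y, design, offset_log, "negative_binomial")
        overdispersion["negative_binomial"] = screening.overdispersion_stat(glm_nb, data.y)
    except (RuntimeError, ValueError) as exc:
        log.warning("negative-binomial GLM failed: %s", exc)
    log.info("overdispersion: %s", overdispersion)

    # --- model comparison over random-effect variants ----------------------
    def _spec(re: str, family: str = "poisson") -> ModelSpec:
        return ModelSpec(
            likelihood=family,
            random_effect=re,
            grid_points=config.grid_points,
            nb_grid_points=config.nb_grid_points,
            n_draws=config.n_draws,
            seed=config.seed,
        )

    variants = ["none", "iid", "icar", "bym"]
    comparison = compare_models(data, graph, [_spec(v) for v in variants])
    fits = dict(zip(variants, comparison.attrs["fits"]))
    best_idx = int(comparison["dic"].idxmin())
    best_variant = comparison.loc[best_idx, "random_effect"]
    log.info("DIC-best random effect: %s", best_variant)

    fit = fits[best_variant]
    family = "poisson"
    if config.compare_negative_binomial:
        try:
            fit_nb = fit_model(data, graph, _spec(best_variant, "negative_binomial"))
            if fit_nb.dic < fit.dic:
                fit, family = fit_nb, "negative_binomial"
            log.info(
                "family comparison by DIC: poisson=%.2f nb=%.2f -> %s",
                fits[best_variant].dic,
                fit_nb.dic,
                family,
            )
        except (RuntimeError, ValueError) as exc:
            log.warning("negative-binomial spatial fit failed: %s", exc)

    # --- spatial-confounding check -----------------------------------------
    confounding = None
    if data.X.shape[1] and fits.get("bym") is not None and fits.get("iid") is not None:
        confounding = confounding_check(data, graph, fit_bym=fits["bym"], fit_iid=fits["iid"])
        log.info("max |RR percent change| = %.2f%%", confounding["percent_change"].abs().max())

    # --- residual diagnostics ----------------------------------------------
    resid = residuals(fit)
    w_row = spatial_weights.to_weights(graph, "row_standardized")
    w_self = spatial_weights.to_weights(graph, "self_included_binary")
    resid_moran = cluster_stats.global_moran(
        resid, w_row, permutations=config.permutations, seed=config.seed
    )
    resid_gistar = cluster_stats.getis_ord_gistar(resid, w_self)
    log.info("residual Moran I = %.5f (p = %.4f)", resid_moran.I, resid_moran.p_sim)

    # --- LISA on posterior-mean RR ------------------------------------------
    lisa = cluster_stats.local_moran(
        fit.rr["mean"].to_numpy(),
        w_row,
        permutations=config.permutations,
        alpha=config.alpha,
        fdr=config.fdr_lisa,
        seed=config.seed,
    )

    # --- tiers ----------------------------------------------------------------
    tiers = tiering.classify_sd_bands(
        fit.rr["mean"], center=config.tier_center, area_ids=list(fit.area_ids)
    )

    # --- state-level (grouped) posterior counts ------------------------------
    if config.grouping_column and config.grouping_column in table.X.columns:
        grouping = dict(zip(table.area_ids, table.X[config.grouping_column].astype(str)))
    else:
        grouping = {a: "all" for a in table.area_ids}
    aggregated = aggregate_posterior_counts(fit, grouping)

    extra: dict = {
        "seed": config.seed,
        "overdispersion": overdispersion,
        "selected_model": {"random_effect": str(best_variant), "likelihood": family},
        "aggregated_counts": aggregated.reset_index().to_dict(orient="records"),
    }
    if screen_report is not None:
        extra["screening"] = screen_report.to_json()
    if confounding is not None:
        extra["confounding"] = confounding.reset_index().round(6).to_dict(orient="records")
    if truth is not None:
        extra["simulation_truth"] = {
            "beta": list(truth["beta"]),
            "sigma": truth["sigma"],
            "phi": truth["phi"],
        }

    bundle = tiering.build_report(
        fit,
        lisa,
        tiers,
        outdir,
        residual_clusters=resid_gistar,
        residual_moran=resid_moran,
        comparison=comparison,
        polygons=graph.polygons,
        extra=extra,
    )
    bundle["fit"] = fit
    bundle["comparison"] = comparison
    bundle["confounding"] = confounding
    bundle["aggregated"] = aggregated
    log.info("pipeline done in %.1f s", time.perf_counter() - t0)
    return bundle
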