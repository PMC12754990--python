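"""SD-band relative-risk classification, intervention tiers and report assembly.

Posterior-mean relative risks are expressed in standard-deviation units from
a center — by default the reference risk RR = 1 (the national expectation),
optionally the sample mean — and cut into seven bands at +/-0.5, +/-1.5 and
+/-2.5 SD.  The bands drive a three-tier intervention framework: areas more
than 1.5 SD above the center are tier 1 (intensive programs), 0.5-1.5 SD
tier 2 (outreach), -0.5-0.5 SD tier 3 (regular surveillance), and anything
at or below -0.5 SD is below the reference and untargeted.

``build_report`` joins the model fit, cluster labels and tiers into one
per-area table plus a JSON summary (fixed-effect table, model comparison,
residual autocorrelation, tier counts) ready for external mapping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .cluster_stats import ClusterResult, GlobalMoran
from .disease_model import PosteriorFit, residuals
from .spatial_weights import write_geojson

__all__ = ["TierTable", "classify_sd_bands", "build_report"]

_BAND_CUTS = (-2.5, -1.5, -0.5, 0.5, 1.5, 2.5)
_BAND_LABELS = (
    "<-2.5",
    "-2.5..-1.5",
    "-1.5..-0.5",
    "-0.5..0.5",
    "0.5..1.5",
    "1.5..2.5",
    ">=2.5",
)


@dataclass
class TierTable:
    """Per-area SD units, band label and intervention tier."""

    table: pd.DataFrame  # columns: rr, sd_units, band, tier
    center: float
    scale: float

    def tier_counts(self) -> dict[str, int]:
        counts = self.table["tier"].value_counts().to_dict()
        return {str(k): int(v) for k, v in counts.items()}

    def band_counts(self) -> dict[str, int]:
        return {b: int((self.table["band"] == b).sum()) for b in _BAND_LABELS}


def classify_sd_bands(
    rr: np.ndarray | pd.Series,
    center: str = "reference_1",
    area_ids: list[str] | None = None,
) -> TierTable:
    """Classify relative risks into SD bands and intervention tiers.

    ``center`` is ``reference_1`` (deviations from the null risk RR = 1) or
    ``sample_mean``; the scale is always the sample SD of the RR vector.
    Bands are left-closed/right-open upward at cuts +/-0.5, +/-1.5, +/-2.5;
    tiers follow the strict upper rule (tier 1 strictly above 1.5 SD).
    """
    if isinstance(rr, pd.Series):
        if area_ids is None:
            area_ids = list(rr.index)
        rr = rr.to_numpy(dtype=float)
    rr = np.asarray(rr, dtype=float)
    if len(rr) < 2:
        raise ValueError("need at least two areas")
    if np.any(rr <= 0):
        raise ValueError("relative risks must be positive")
    scale = float(np.std(rr, ddof=1))
    if scale == 0:
        raise ValueError("zero spread in relative risks; SD bands undefined")
    if center == "reference_1":
        c = 1.0
    elif center == "sample_mean":
        c = float(np.mean(rr))
    else:
        raise ValueError(f"unknown center {center!r}")
    sd_units = (rr - c) / scale
    band_idx = np.digitize(sd_units, _BAND_CUTS, right=False)
    bands = [_BAND_LABELS[i] for i in band_idx]
    tiers = []
    for s in sd_units:
        if s > 1.5:
            tiers.append("1")
        elif s > 0.5:
            tiers.append("2")
        elif s > -0.5:
            tiers.append("3")
        else:
            tiers.append("below-reference")
    index = pd.Index(area_ids, name="area_id") if area_ids is not None else None
    table = pd.DataFrame({"rr": rr, "sd_units": sd_units, "band": bands, "tier": tiers}, index=index)
    return TierTable(table=table, center=c, scale=scale)


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------


def build_report(
    fit: PosteriorFit,
    clusters: ClusterResult,
    tiers: TierTable,
    outdir: str | Path,
    residual_clusters: ClusterResult | None = None,
    residual_moran: GlobalMoran | None = None,
    comparison: pd.DataFrame | None = None,
    polygons=None,
    extra: Mapping[str, object] | None = None,
) -> dict:
    """Join all per-area products and write the report bundle.

    Writes ``areas.csv`` (per-area RR, fields, residuals, cluster label,
    tier), ``summary.json`` and, when polygons are given, ``areas.geojson``
    with the same values appended as feature properties.  All inputs must
    share the fit's area ids; mismatches raise, naming the offenders.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ids = list(fit.area_ids)
    for name, other in (("clusters", clusters.area_ids), ("tiers", list(tiers.table.index))):
        if other and list(other) != ids:
            offenders = sorted(set(other).symmetric_difference(ids))
            raise ValueError(f"area ids of {name} do not match the fit: {offenders[:10]}")

    per_area = pd.DataFrame(index=pd.Index(ids, name="area_id"))
    per_area["rr_mean"] = fit.rr["mean"].to_numpy()
    per_area["rr_lower"] = fit.rr["lower"].to_numpy()
    per_area["rr_upper"] = fit.rr["upper"].to_numpy()
    per_area["structured"] = fit.area_effects["structured_mean"].to_numpy()
    per_area["unstructured"] = fit.area_effects["unstructured_mean"].to_numpy()
    per_area["residual"] = residuals(fit)
    per_area["lisa_statistic"] = clusters.statistic
    per_area["lisa_p"] = clusters.pseudo_p
    per_area["lisa_label"] = clusters.labels
    per_area["sd_units"] = tiers.table["sd_units"].to_numpy()
    per_area["band"] = tiers.table["band"].to_numpy()
    per_area["tier"] = tiers.table["tier"].to_numpy()
    if residual_clusters is not None:
        per_area["gistar_z"] = residual_clusters.statistic
        per_area["gistar_label"] = residual_clusters.labels
    per_area.to_csv(outdir / "areas.csv")

    label_counts = pd.Series(clusters.labels).value_counts().to_dict()
    summary = {
        "model": fit.summary_json(),
        "cluster_label_counts": {str(k): int(v) for k, v in label_counts.items()},
        "tier_counts": tiers.tier_counts(),
        "band_counts": tiers.band_counts(),
    }
    if residual_moran is not None:
        summary["residual_global_moran"] = residual_moran.as_dict()
    if comparison is not None:
        comp = comparison.drop(columns=["error"], errors="ignore")
        summary["model_comparison"] = json.loads(comp.to_json(orient="records"))
    if extra:
        summary.update(extra)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))

    if polygons is not None:
        props = {aid: row.to_dict() for aid, row in per_area.iterrows()}
        # JSON cannot carry NaN; drop undefined numeric entries
        for aid in props:
            props[aid] = {
                k: (None if isinstance(v, float) and np.isnan(v) else v)
                for k, v in props[aid].items()
            }
        write_geojson(polygons, outdir / "areas.geojson", properties=props)
    return {"per_area": per_area, "summary": summary, "outdir": str(outdir)}
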