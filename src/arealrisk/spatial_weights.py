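"""Contiguity structures, spatial weight matrices and ICAR precision matrices.

Areal models and cluster statistics both run on a neighborhood graph over the
study areas.  This module builds that graph from polygon geometries (queen or
rook contiguity), converts it to the weight-matrix styles the different
statistics need (binary for Gi*, row-standardized for Moran/LISA), and
assembles the intrinsic CAR precision matrix ``Q = D - A`` together with the
variance-scaling constant used by the BYM2 parameterization.

File formats: GeoJSON (RFC 7946) for polygons, the GAL text dialect for
adjacency lists, and a sparse (i, j, w) triplet CSV for weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from shapely.geometry import mapping as shapely_mapping
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

__all__ = [
    "AreaGraph",
    "WeightMatrix",
    "queen_contiguity",
    "to_weights",
    "icar_precision",
    "read_gal",
    "write_gal",
    "read_geojson",
    "write_geojson",
    "weights_to_csv",
]


# ---------------------------------------------------------------------------
# graph container
# ---------------------------------------------------------------------------


@dataclass
class AreaGraph:
    """Symmetric, irreflexive contiguity graph over named areas.

    Parameters
    ----------
    area_ids
        Ordered area identifiers; the ordering fixes row/column order of every
        matrix derived from the graph.
    neighbors
        Mapping area id -> set of neighboring ids.  Must be symmetric and
        never contain the area itself.
    polygons
        Optional area geometries (kept so synthetic graphs can round-trip
        through the GeoJSON reader).
    """

    area_ids: list[str]
    neighbors: dict[str, set[str]]
    polygons: dict[str, BaseGeometry] | None = None
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.area_ids)) != len(self.area_ids):
            raise ValueError("duplicate area ids")
        self._index = {a: i for i, a in enumerate(self.area_ids)}
        for a, nbrs in self.neighbors.items():
            if a in nbrs:
                raise ValueError(f"area {a!r} listed as its own neighbor")
            for b in nbrs:
                if a not in self.neighbors.get(b, set()):
                    raise ValueError(f"asymmetric neighbor pair: {a!r} -> {b!r}")

    @property
    def n(self) -> int:
        return len(self.area_ids)

    def index_of(self, area_id: str) -> int:
        return self._index[area_id]

    def degree(self, area_id: str) -> int:
        return len(self.neighbors[area_id])

    def adjacency(self) -> sp.csr_matrix:
        """Binary adjacency matrix in ``area_ids`` order."""
        rows, cols = [], []
        for a, nbrs in self.neighbors.items():
            i = self._index[a]
            for b in nbrs:
                rows.append(i)
                cols.append(self._index[b])
        data = np.ones(len(rows))
        return sp.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))

    @property
    def components(self) -> list[list[str]]:
        """Connected components, each an ordered list of area ids."""
        if self.n == 0:
            return []
        _, labels = connected_components(self.adjacency(), directed=False)
        comps: dict[int, list[str]] = {}
        for a, lab in zip(self.area_ids, labels):
            comps.setdefault(int(lab), []).append(a)
        return [comps[k] for k in sorted(comps)]

    def component_labels(self) -> np.ndarray:
        _, labels = connected_components(self.adjacency(), directed=False)
        return labels


# ---------------------------------------------------------------------------
# contiguity from polygons
# ---------------------------------------------------------------------------


def queen_contiguity(
    polygons: Mapping[str, BaseGeometry],
    contiguity: str = "queen",
    tolerance: float = 0.0,
) -> AreaGraph:
    """Build a contiguity graph from polygons.

    Two areas are neighbors when their boundaries share at least one point
    (queen) or a boundary segment of positive length (rook).  The default
    predicate is exact; ``tolerance > 0`` buffers geometries by that amount
    first, for sloppy real-world boundary files.

    Raises on duplicate ids and on invalid geometries (naming the area).
    """
    ids = list(polygons.keys())
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate area ids in polygon collection")
    if contiguity not in ("queen", "rook"):
        raise ValueError(f"unknown contiguity {contiguity!r}")
    geoms = []
    for a in ids:
        g = polygons[a]
        if not isinstance(g, BaseGeometry):
            raise TypeError(f"area {a!r}: not a shapely geometry")
        if not g.is_valid:
            raise ValueError(f"invalid geometry for area {a!r}")
        geoms.append(g.buffer(tolerance) if tolerance > 0 else g)

    tree = STRtree(geoms)
    neighbors: dict[str, set[str]] = {a: set() for a in ids}
    for i, g in enumerate(geoms):
        for j in tree.query(g, predicate="intersects"):
            j = int(j)
            if j == i:
                continue
            inter = g.intersection(geoms[j])
            if inter.is_empty:
                continue
            if contiguity == "rook" and tolerance == 0.0:
                # require shared boundary of positive length
                if inter.length == 0:
                    continue
            neighbors[ids[i]].add(ids[j])
            neighbors[ids[j]].add(ids[i])
    return AreaGraph(area_ids=ids, neighbors=neighbors, polygons=dict(polygons))


# ---------------------------------------------------------------------------
# weight matrices
# ---------------------------------------------------------------------------

_STYLES = ("binary", "row_standardized", "self_included_binary")


@dataclass
class WeightMatrix:
    """Sparse spatial weights aligned to an :class:`AreaGraph` ordering."""

    style: str
    matrix: sp.csr_matrix
    area_ids: list[str]

    @property
    def n(self) -> int:
        return len(self.area_ids)


def to_weights(graph: AreaGraph, style: str = "row_standardized") -> WeightMatrix:
    """Convert a contiguity graph to a weight matrix.

    ``row_standardized`` rows sum to one (isolated areas keep an all-zero
    row); ``self_included_binary`` is the binary adjacency plus the identity,
    as used by the Getis-Ord Gi* statistic.
    """
    if style not in _STYLES:
        raise ValueError(f"unknown weight style {style!r}; choose from {_STYLES}")
    A = graph.adjacency()
    if style == "binary":
        W = A
    elif style == "self_included_binary":
        W = (A + sp.identity(graph.n, format="csr")).tocsr()
    else:
        deg = np.asarray(A.sum(axis=1)).ravel()
        inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
        W = (sp.diags(inv) @ A).tocsr()
    return WeightMatrix(style=style, matrix=W, area_ids=list(graph.area_ids))


def weights_to_csv(weights: WeightMatrix, path: str | Path) -> None:
    """Export nonzero weights as a triplet CSV with columns i, j, w."""
    coo = weights.matrix.tocoo()
    df = pd.DataFrame(
        {
            "i": [weights.area_ids[r] for r in coo.row],
            "j": [weights.area_ids[c] for c in coo.col],
            "w": coo.data,
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ICAR precision
# ---------------------------------------------------------------------------


def _constrained_marginal_variances(Q_dense: np.ndarray) -> np.ndarray:
    """Marginal variances of an intrinsic GMRF under a sum-to-zero constraint.

    Computed from the eigendecomposition of Q restricted to the non-null
    eigenspace, which equals the pseudo-inverse of Q projected onto the
    sum-to-zero subspace for a connected component.
    """
    w, V = np.linalg.eigh(Q_dense)
    tol = max(Q_dense.shape[0], 1) * np.finfo(float).eps * max(abs(w[-1]), 1.0)
    pos = w > tol
    inv = np.zeros_like(w)
    inv[pos] = 1.0 / w[pos]
    return np.einsum("ij,j,ij->i", V, inv, V)


@dataclass
class IcarPrecision:
    """ICAR precision ``Q = D - A`` with optional BYM2 variance scaling.

    ``scale`` holds, per area, the multiplicative constant applied to Q so
    that the geometric mean of the constrained marginal variances equals one
    within each connected component.  Components with fewer than two areas
    cannot carry a structured effect; they are flagged in
    ``degenerate_areas`` and get scale 1.
    """

    Q: sp.csr_matrix
    area_ids: list[str]
    scale: np.ndarray  # per-area scaling constant (1.0 when unscaled)
    degenerate_areas: list[str]

    @property
    def Q_scaled(self) -> sp.csr_matrix:
        return (sp.diags(np.sqrt(self.scale)) @ self.Q @ sp.diags(np.sqrt(self.scale))).tocsr()


def icar_precision(graph: AreaGraph, scaled: bool = False) -> IcarPrecision:
    """Intrinsic CAR precision matrix for a contiguity graph.

    Returns ``Q = D - A`` at unit conditional precision.  With ``scaled=True``
    the per-component constant ``c`` is computed such that the geometric mean
    of the constrained marginal variances of ``c * Q`` equals one (the BYM2
    convention, making the field's typical marginal SD interpretable).

    Note the scale is a uniform constant within each component, so
    ``Q_scaled = c * Q`` there.
    """
    A = graph.adjacency()
    deg = np.asarray(A.sum(axis=1)).ravel()
    Q = (sp.diags(deg) - A).tocsr()
    labels = graph.component_labels()
    scale = np.ones(graph.n)
    degenerate: list[str] = []
    if scaled:
        for lab in np.unique(labels):
            idx = np.where(labels == lab)[0]
            if idx.size < 2:
                degenerate.extend(graph.area_ids[i] for i in idx)
                continue
            sub = Q[np.ix_(idx, idx)].toarray()
            mvar = _constrained_marginal_variances(sub)
            gmean = float(np.exp(np.mean(np.log(mvar))))
            scale[idx] = gmean
    else:
        for lab in np.unique(labels):
            idx = np.where(labels == lab)[0]
            if idx.size < 2:
                degenerate.extend(graph.area_ids[i] for i in idx)
    return IcarPrecision(Q=Q, area_ids=list(graph.area_ids), scale=scale, degenerate_areas=degenerate)


# ---------------------------------------------------------------------------
# GAL serialization
# ---------------------------------------------------------------------------


def write_gal(graph: AreaGraph, path: str | Path) -> None:
    """Write the adjacency structure in GAL format (header = area count)."""
    lines = [str(graph.n)]
    for a in graph.area_ids:
        nbrs = sorted(graph.neighbors[a])
        lines.append(f"{a} {len(nbrs)}")
        lines.append(" ".join(nbrs))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gal(path: str | Path) -> AreaGraph:
    """Read a GAL adjacency file.

    Accepts both the bare header ``<n>`` and the GeoDa-style header
    ``0 <n> <dataset> <key>``.  Validates symmetry and id references;
    degree-0 areas (blank neighbor line) parse as isolates.
    """
    raw = Path(path).read_text().splitlines()
    if not raw:
        raise ValueError("empty GAL file")
    head = raw[0].split()
    if len(head) == 1:
        n = int(head[0])
    else:
        n = int(head[1])
    area_ids: list[str] = []
    neighbors: dict[str, set[str]] = {}
    pos = 1
    for _ in range(n):
        while pos < len(raw) and not raw[pos].strip():
            pos += 1
        if pos >= len(raw):
            raise ValueError("GAL file truncated: fewer areas than header declares")
        ident, deg_s = raw[pos].split()
        deg = int(deg_s)
        pos += 1
        if deg > 0:
            if pos >= len(raw):
                raise ValueError(f"GAL file truncated in neighbor list of {ident!r}")
            nbrs = set(raw[pos].split())
            pos += 1
            if len(nbrs) != deg:
                raise ValueError(f"area {ident!r}: declared degree {deg}, found {len(nbrs)}")
        else:
            nbrs = set()
            # an isolate may be followed by a blank line in some writers
            if pos < len(raw) and not raw[pos].strip():
                pos += 1
        area_ids.append(ident)
        neighbors[ident] = nbrs
    known = set(area_ids)
    bad_pairs = []
    for a, nbrs in neighbors.items():
        for b in nbrs:
            if b not in known:
                raise ValueError(f"unknown neighbor id {b!r} referenced by {a!r}")
            if a not in neighbors[b]:
                bad_pairs.append((a, b))
    if bad_pairs:
        raise ValueError(f"asymmetric neighbor pairs in GAL file: {bad_pairs}")
    return AreaGraph(area_ids=area_ids, neighbors=neighbors)


# ---------------------------------------------------------------------------
# GeoJSON
# ---------------------------------------------------------------------------


def read_geojson(path: str | Path, id_property: str = "area_id") -> dict[str, BaseGeometry]:
    """Read polygons from a GeoJSON FeatureCollection keyed by an id property."""
    obj = json.loads(Path(path).read_text())
    if obj.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    polygons: dict[str, BaseGeometry] = {}
    for feat in obj.get("features", []):
        props = feat.get("properties") or {}
        if id_property not in props:
            raise ValueError(f"feature missing id property {id_property!r}")
        aid = str(props[id_property])
        if aid in polygons:
            raise ValueError(f"duplicate area id {aid!r} in GeoJSON")
        polygons[aid] = shapely_shape(feat["geometry"])
    return polygons


def write_geojson(
    polygons: Mapping[str, BaseGeometry],
    path: str | Path,
    id_property: str = "area_id",
    properties: Mapping[str, Mapping[str, object]] | None = None,
) -> None:
    """Write polygons (plus optional per-area properties) as GeoJSON."""
    feats = []
    for aid, geom in polygons.items():
        props: dict[str, object] = {id_property: aid}
        if properties is not None and aid in properties:
            props.update(properties[aid])
        feats.append(
            {"type": "Feature", "properties": props, "geometry": shapely_mapping(geom)}
        )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))
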