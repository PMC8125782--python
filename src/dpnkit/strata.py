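"""Demographically stratified network layers and their comparison.

The cohort is split into sex x age strata (default: F/M crossed with
0-21, 22-64, 65+), each stratum yielding its own co-prescription layer
over a shared node universe.  Two layers are compared through their
binary adjacency matrices: entry (i, j) of the distance matrix is the
Euclidean distance between the neighbourhood profile (adjacency row)
of code i in one layer and of code j in the other.  For binary rows
the squared distance is exactly the Hamming distance between the
profiles.  The distance matrix is then summarised by a ward.D2
dendrogram (Lance-Williams recurrence on squared distances with
square-rooted merge heights) and an optional flat clustering, with k
chosen by silhouette when not given.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist, squareform

from .ingest import (
    DEFAULT_AGE_BINS,
    IncidenceMap,
    PrescriptionRecord,
    _age_at,
    _stratum_label,
    build_incidence,
)
from .network import DPN
from .phi import phi_edges

__all__ = [
    "BinaryLayer",
    "LayerDistance",
    "stratify",
    "stratify_incidence",
    "binary_layer",
    "layer_distance",
    "ward_d2",
    "cut_clusters",
    "silhouette_k",
]


def stratify(
    records: list[PrescriptionRecord],
    index_date: _dt.date,
    sex_split: bool = True,
    age_bins=DEFAULT_AGE_BINS,
) -> dict[str, list[PrescriptionRecord]]:
    """Partition records into disjoint sex x age strata.

    Stratum labels look like ``"F_65+"``; with ``sex_split=False`` only
    the age bins are used.  Records whose age falls in no bin are
    dropped (with the default bins that is only a negative age).
    """
    out: dict[str, list[PrescriptionRecord]] = {}
    for rec in records:
        age = _age_at(rec.birth_year, index_date)
        band = _stratum_label(age, age_bins) if age >= 0 else None
        if band is None:
            continue
        label = f"{rec.sex}_{band}" if sex_split else band
        out.setdefault(label, []).append(rec)
    return out


def stratify_incidence(records, index_date, level, sex_split=True,
                       age_bins=DEFAULT_AGE_BINS) -> dict[str, IncidenceMap]:
    """Stratify and aggregate each stratum to an IncidenceMap at ``level``."""
    return {
        label: build_incidence(group, level)
        for label, group in stratify(records, index_date, sex_split, age_bins).items()
    }


@dataclass
class BinaryLayer:
    """Binary adjacency of one stratum layer over a shared node universe."""

    node_universe: tuple[str, ...]
    adjacency: np.ndarray  # symmetric 0/1, zero diagonal
    label: str


@dataclass
class LayerDistance:
    """Cross-layer Euclidean row-profile distances with optional clustering."""

    labels: tuple[str, ...]
    D: np.ndarray
    linkage: np.ndarray | None = None
    clusters: dict[str, int] | None = None


def binary_layer(dpn: DPN, node_universe, phi_star: float | None = None,
                 label: str = "") -> BinaryLayer:
    """0/1 adjacency of a DPN over ``node_universe``.

    Entry is 1 iff the edge exists (Cij >= 1) and, when ``phi_star`` is
    given, its φ passes the threshold.  Codes in the universe but
    absent from the stratum give all-zero rows; a DPN node missing from
    the universe is an error.
    """
    universe = tuple(node_universe)
    index = {v: i for i, v in enumerate(universe)}
    missing = [v for v in dpn.graph.nodes if v not in index]
    if missing:
        raise ValueError(f"node universe is missing DPN nodes: {missing[:5]}")
    adj = np.zeros((len(universe), len(universe)), dtype=np.int8)
    if phi_star is None:
        edges = ((u, v) for u, v in dpn.graph.edges)
    else:
        edges = ((e.i, e.j) for e in phi_edges(dpn) if e.phi >= phi_star)
    for u, v in edges:
        adj[index[u], index[v]] = 1
        adj[index[v], index[u]] = 1
    return BinaryLayer(node_universe=universe, adjacency=adj, label=label)


def layer_distance(layer_a: BinaryLayer, layer_b: BinaryLayer) -> LayerDistance:
    """Euclidean distances between row profiles across two layers.

    ``D[i][j]`` compares the neighbourhood of code i in layer A with
    that of code j in layer B; both layers must share the same ordered
    node universe.
    """
    if layer_a.node_universe != layer_b.node_universe:
        raise ValueError("layers must share an identical ordered node universe")
    D = cdist(layer_a.adjacency.astype(float), layer_b.adjacency.astype(float),
              metric="euclidean")
    return LayerDistance(labels=layer_a.node_universe, D=D)


def as_dissimilarity(D: np.ndarray) -> np.ndarray:
    """Coerce a cross-layer distance matrix into a clustering dissimilarity.

    A female-vs-male matrix is not a dissimilarity over codes: entry
    (i, i) compares code i's two sex-specific profiles and is generally
    positive, and (i, j) need not equal (j, i).  Mirroring how R's
    ``as.dist`` reads such a matrix, this averages the two triangles
    and zeroes the diagonal.
    """
    D = np.asarray(D, dtype=float)
    sym = 0.5 * (D + D.T)
    np.fill_diagonal(sym, 0.0)
    return sym


def ward_d2(distance_matrix: np.ndarray) -> np.ndarray:
    """Agglomerative ward.D2 linkage of a square distance matrix.

    Uses the Lance-Williams recurrence on squared distances with
    square-rooted merge heights, so merge heights are non-decreasing.
    Returns a SciPy linkage matrix.
    """
    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(D < 0):
        raise ValueError("distances must be non-negative")
    return hierarchy.linkage(squareform(D, checks=False), method="ward")


def cut_clusters(linkage: np.ndarray, k: int, labels=None) -> dict:
    """The k-cluster partition from a linkage tree.

    Removes the k-1 highest merges; cluster ids (1..k) are renumbered
    by dendrogram leaf order.
    """
    n = linkage.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    raw = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    order = hierarchy.leaves_list(linkage)
    remap: dict[int, int] = {}
    for leaf in order:
        remap.setdefault(raw[leaf], len(remap) + 1)
    assignments = [remap[c] for c in raw]
    keys = labels if labels is not None else list(range(n))
    return dict(zip(keys, assignments))


def _silhouette(D: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width for a precomputed distance matrix."""
    n = D.shape[0]
    uniq = np.unique(labels)
    scores = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own <= 1:
            scores[i] = 0.0
            continue
        a = D[i, own].sum() / (n_own - 1)
        b = min(D[i, labels == c].mean() for c in uniq if c != labels[i])
        scores[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(scores.mean())


def silhouette_k(linkage: np.ndarray, D: np.ndarray,
                 k_range=None) -> tuple[int, float]:
    """Choose k by maximising the silhouette over k = 2..min(10, n-1)."""
    n = D.shape[0]
    if k_range is None:
        k_range = range(2, min(10, n - 1) + 1)
    best_k, best_s = 2, -np.inf
    for k in k_range:
        labels = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
        if np.unique(labels).size < 2:
            continue
        s = _silhouette(D, labels)
        if s > best_s:
            best_k, best_s = k, s
    return best_k, best_s
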