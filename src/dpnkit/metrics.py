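"""Structural metric panel for Drug Prescription Networks.

Computes, per network: density d = 2E/(N(N-1)); the node degree,
betweenness and closeness centralities with their means and CV%
(population standard deviation / mean x 100); Newman's degree
assortativity r; and the random-graph giant-component heuristics
(a giant component exists when the mean degree exceeds 1, and spans the
network when it exceeds ln N).

Centralities support three edge-length conventions, because the weight
of a co-prescription edge can be read either as a cost or as a
proximity:

- ``unweighted`` — every edge has length 1;
- ``cij`` (default) — length equals the raw co-prescription count Cij,
  the convention of treating the stored weight as a distance;
- ``inverse-cij`` — length 1/Cij, so strongly co-prescribed pairs are
  close.

Betweenness is Freeman's unnormalised count with geodesic ties split
equally; closeness is the unnormalised reciprocal of the sum of
distances to reachable nodes (isolated nodes score 0, and disconnected
graphs are computed per component and flagged).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "WEIGHTINGS",
    "NodeMetrics",
    "MetricsSummary",
    "UndefinedMetricError",
    "density",
    "degrees",
    "betweenness",
    "closeness",
    "assortativity",
    "giant_component_flags",
    "summary",
]

WEIGHTINGS = ("unweighted", "cij", "inverse-cij")


class UndefinedMetricError(ValueError):
    """The metric is not defined on this graph (too small / no edges)."""


@dataclass
class NodeMetrics:
    """Per-node degree (k), betweenness (b) and closeness (cl)."""

    k: dict[str, int]
    b: dict[str, float]
    cl: dict[str, float]


@dataclass
class MetricsSummary:
    """One summary row for a network: sizes, density, centrality means, r."""

    level: int
    N: int
    lnN: float
    E: int
    d: float
    k_mean: float
    k_cv_pct: float
    b_mean: float
    b_cv_pct: float
    cl_mean: float
    cl_cv_pct: float
    r: float | None
    has_giant: bool
    fully_connected_regime: bool
    is_connected: bool
    weighting: str

    def to_dict(self) -> dict:
        out = dict(self.__dict__)
        out["r"] = float("nan") if self.r is None else self.r
        return out


def _edge_length(dpn, weighting: str) -> str | None:
    """Attach a 'length' attribute per the weighting mode; None = unweighted."""
    if weighting not in WEIGHTINGS:
        raise ValueError(f"weighting must be one of {WEIGHTINGS}")
    if weighting == "unweighted":
        return None
    for u, v, d in dpn.graph.edges(data=True):
        cij = d["Cij"]
        if cij <= 0:
            raise ValueError(f"edge {u}-{v} has non-positive weight {cij}")
        d["length"] = float(cij) if weighting == "cij" else 1.0 / cij
    return "length"


def density(dpn) -> float:
    """Graph density 2E / (N(N-1))."""
    n = dpn.N
    if n < 2:
        raise UndefinedMetricError("density undefined for N < 2")
    return 2.0 * dpn.E / (n * (n - 1))


def degrees(dpn) -> dict[str, int]:
    """Unweighted node degrees."""
    return dict(dpn.graph.degree())


def betweenness(dpn, weighting: str = "cij") -> dict[str, float]:
    """Freeman betweenness, unnormalised, ties split among geodesics."""
    attr = _edge_length(dpn, weighting)
    return nx.betweenness_centrality(dpn.graph, normalized=False, weight=attr)


def closeness(dpn, weighting: str = "cij") -> dict[str, float]:
    """Cl_i = 1 / sum of shortest-path distances from i to reachable nodes."""
    attr = _edge_length(dpn, weighting)
    out: dict[str, float] = {}
    for v in dpn.graph.nodes:
        dists = nx.shortest_path_length(dpn.graph, source=v, weight=attr)
        total = sum(d for u, d in dists.items() if u != v)
        out[v] = 1.0 / total if total > 0 else 0.0
    return out


def assortativity(dpn) -> float | None:
    """Newman's degree assortativity.

    The Pearson correlation of the degrees at the two ends of each
    edge, each edge counted in both orientations.  Returns ``None``
    (not-applicable) when the degree variance over edge ends is zero,
    as on regular and complete graphs.
    """
    if dpn.E == 0:
        raise UndefinedMetricError("assortativity undefined with no edges")
    deg = dict(dpn.graph.degree())
    x, y = [], []
    for u, v in dpn.graph.edges:
        x.extend((deg[u], deg[v]))
        y.extend((deg[v], deg[u]))
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0.0 or y.std() == 0.0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def giant_component_flags(dpn) -> tuple[bool, bool, list[int]]:
    """Mean-degree heuristics plus the true component decomposition.

    Returns ``(has_giant, fully_connected_regime, component_sizes)``
    where the flags are the random-graph criteria mean degree > 1 and
    mean degree > ln N, and the sizes are the actual connected
    components in decreasing order — the heuristic and the ground truth
    can disagree and both are reported.
    """
    n = dpn.N
    k_mean = 2.0 * dpn.E / n if n else 0.0
    sizes = sorted((len(c) for c in nx.connected_components(dpn.graph)), reverse=True)
    return k_mean > 1.0, n > 0 and k_mean > math.log(n), sizes


def _mean_cv(values) -> tuple[float, float]:
    a = np.asarray(list(values), dtype=float)
    m = a.mean()
    sd = a.std()  # population SD, ddof=0
    cv = 100.0 * sd / m if m != 0 else float("nan")
    return float(m), float(cv)


def summary(dpn, weighting: str = "cij") -> MetricsSummary:
    """Assemble the full metric row for one network."""
    n = dpn.N
    d = density(dpn)
    k = degrees(dpn)
    b = betweenness(dpn, weighting)
    cl = closeness(dpn, weighting)
    k_mean, k_cv = _mean_cv(k.values())
    b_mean, b_cv = _mean_cv(b.values())
    cl_mean, cl_cv = _mean_cv(cl.values())
    try:
        r = assortativity(dpn)
    except UndefinedMetricError:
        r = None
    has_giant, fully_connected, sizes = giant_component_flags(dpn)
    return MetricsSummary(
        level=dpn.level, N=n, lnN=float(math.log(n)), E=dpn.E, d=d,
        k_mean=k_mean, k_cv_pct=k_cv, b_mean=b_mean, b_cv_pct=b_cv,
        cl_mean=cl_mean, cl_cv_pct=cl_cv, r=r,
        has_giant=has_giant, fully_connected_regime=fully_connected,
        is_connected=len(sizes) == 1, weighting=weighting,
    )


def node_metrics(dpn, weighting: str = "cij") -> NodeMetrics:
    """Degree, betweenness and closeness for every node."""
    return NodeMetrics(k=degrees(dpn), b=betweenness(dpn, weighting),
                       cl=closeness(dpn, weighting))


__all__.append("node_metrics")
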