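"""φ binary-correlation thresholding of co-prescription networks.

For drugs i and j in a cohort of n patients, with Pi and Pj patients
prescribed each and Cij prescribed both, the φ coefficient is the
Pearson correlation of the two binary patient-indicator vectors::

    φij = (n·Cij − Pi·Pj) / sqrt(Pi(n−Pi) · Pj(n−Pj))

Thresholding at φ* keeps edges with φij ≥ φ* and discards the rest,
stripping the "weak" edges whose co-prescription count barely exceeds
the independence expectation.  Scanning φ* over a (log-spaced) grid
yields retention curves — the fraction of connected nodes (degree ≥ 1)
and of edges surviving at each φ* — which are summarised by logistic
fits on the log10 φ* axis.  φmax, the threshold at which the gap
between the node and edge curves peaks, marks the regime where most
weak edges are gone but the network is still broadly connected; it is
the operating point proposed for module-oriented pruning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .network import DPN

__all__ = [
    "PhiEdge",
    "LogisticFit",
    "RetentionCurve",
    "ZeroVarianceError",
    "InconsistencyError",
    "DegenerateFitError",
    "phi",
    "phi_edges",
    "threshold_network",
    "default_grid",
    "retention_curve",
    "fit_logistic",
    "phi_max",
]


class ZeroVarianceError(ValueError):
    """φ undefined: one drug was prescribed to no patient or to all."""


class InconsistencyError(ValueError):
    """Counts violate the Fréchet bounds max(0, Pi+Pj−n) ≤ Cij ≤ min(Pi, Pj)."""


class DegenerateFitError(ValueError):
    """Logistic fit impossible: the retention fractions carry no signal."""


def phi(n: int, Pi: int, Pj: int, Cij: int) -> float:
    """The 2×2 contingency φ coefficient for one drug pair."""
    if not (0 < Pi < n and 0 < Pj < n):
        raise ZeroVarianceError(
            f"phi undefined for Pi={Pi}, Pj={Pj} with n={n} (zero variance)"
        )
    if not (max(0, Pi + Pj - n) <= Cij <= min(Pi, Pj)):
        raise InconsistencyError(
            f"Cij={Cij} outside Fréchet bounds for Pi={Pi}, Pj={Pj}, n={n}"
        )
    num = n * Cij - Pi * Pj
    den = math.sqrt(Pi * (n - Pi)) * math.sqrt(Pj * (n - Pj))
    return num / den


@dataclass(frozen=True)
class PhiEdge:
    """One edge with its φ value and the counts it was computed from."""

    i: str
    j: str
    phi: float
    Pi: int
    Pj: int
    Cij: int
    n: int


def phi_edges(dpn: DPN) -> list[PhiEdge]:
    """φ for every edge; edges with undefined φ are dropped with a warning."""
    out: list[PhiEdge] = []
    n = dpn.n_patients
    for u, v, d in dpn.graph.edges(data=True):
        pi = dpn.graph.nodes[u]["Pi"]
        pj = dpn.graph.nodes[v]["Pi"]
        try:
            val = phi(n, pi, pj, d["Cij"])
        except ZeroVarianceError:
            warnings.warn(f"dropping edge {u}-{v}: phi undefined (Pi={pi}, Pj={pj}, n={n})")
            continue
        out.append(PhiEdge(u, v, val, pi, pj, d["Cij"], n))
    return out


def threshold_network(dpn: DPN, phi_star: float) -> DPN:
    """Copy of the DPN keeping only edges with φij ≥ φ*; all nodes retained."""
    g = dpn.graph.copy()
    g.remove_edges_from(list(g.edges))
    for e in phi_edges(dpn):
        if e.phi >= phi_star:
            g.add_edge(e.i, e.j, Cij=e.Cij)
    return DPN(level=dpn.level, n_patients=dpn.n_patients, graph=g)


def default_grid(n_points: int = 50, lo: float = 1e-5, hi: float = 1.0) -> np.ndarray:
    """Log-spaced φ* grid, 50 points from 1e-5 to 1 by default."""
    return np.logspace(math.log10(lo), math.log10(hi), n_points)


@dataclass
class LogisticFit:
    """Decreasing logistic ``A / (1 + exp((x − x0)/s))`` on x = log10 φ*."""

    asymptote: float
    x0: float
    slope: float
    rss: float
    converged: bool

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.asymptote / (1.0 + np.exp((x - self.x0) / self.slope))


@dataclass
class RetentionCurve:
    """Node / edge survival fractions over a φ* grid, with optional fits."""

    grid: np.ndarray
    node_frac: np.ndarray
    edge_frac: np.ndarray
    node_fit: LogisticFit | None = None
    edge_fit: LogisticFit | None = None
    phi_max: float | None = None


def retention_curve(dpn: DPN, grid=None) -> RetentionCurve:
    """Fractions of connected nodes and edges surviving each φ* in the grid.

    Fractions are relative to the unthresholded connected-node count
    (nodes of degree ≥ 1) and edge count.  Both curves are
    non-increasing in φ* by construction.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty φ* grid")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("φ* grid must be strictly increasing")
    edges = phi_edges(dpn)
    base_edges = len(edges)
    base_nodes = sum(1 for _, deg in dpn.graph.degree() if deg > 0)
    if base_edges == 0 or base_nodes == 0:
        raise ValueError("network has no edges to threshold")
    phis = np.array([e.phi for e in edges])
    node_frac = np.empty(grid.size)
    edge_frac = np.empty(grid.size)
    for idx, t in enumerate(grid):
        keep = phis >= t
        edge_frac[idx] = keep.sum() / base_edges
        connected = {e.i for e, k in zip(edges, keep) if k}
        connected |= {e.j for e, k in zip(edges, keep) if k}
        node_frac[idx] = len(connected) / base_nodes
    return RetentionCurve(grid=grid, node_frac=node_frac, edge_frac=edge_frac)


def fit_logistic(xs, fracs, fix_asymptote: bool = True) -> LogisticFit:
    """Least-squares logistic fit of retention fractions on log10 φ*.

    The asymptote A is fixed to 1 by default (curves start at full
    retention); ``fix_asymptote=False`` frees it within (0, 1].
    Non-convergence is flagged, with the best parameters still
    returned; a flat fraction vector is a degenerate fit.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(fracs, dtype=float)
    if xs.size < 4 or np.unique(xs).size < 4:
        raise ValueError("need at least 4 distinct grid points")
    if np.all(ys == ys[0]):
        raise DegenerateFitError("retention fractions are constant")
    if np.any((ys < 0) | (ys > 1)):
        raise ValueError("fractions must lie in [0, 1]")

    # start at the half-retention crossing with a moderate slope
    x0_init = float(xs[np.argmin(np.abs(ys - 0.5 * ys.max()))])
    if fix_asymptote:
        theta0 = np.array([x0_init, 0.5])
        lb, ub = [xs.min() - 10.0, 1e-4], [xs.max() + 10.0, 20.0]

        def resid(theta):
            x0, s = theta
            return 1.0 / (1.0 + np.exp((xs - x0) / s)) - ys
    else:
        theta0 = np.array([min(max(ys.max(), 1e-3), 1.0), x0_init, 0.5])
        lb, ub = [1e-6, xs.min() - 10.0, 1e-4], [1.0, xs.max() + 10.0, 20.0]

        def resid(theta):
            a, x0, s = theta
            return a / (1.0 + np.exp((xs - x0) / s)) - ys

    res = optimize.least_squares(resid, theta0, bounds=(lb, ub), xtol=1e-12, ftol=1e-12)
    if fix_asymptote:
        a, (x0, s) = 1.0, res.x
    else:
        a, x0, s = res.x
    return LogisticFit(asymptote=float(a), x0=float(x0), slope=float(s),
                       rss=float(2.0 * res.cost), converged=bool(res.success))


def phi_max(node_fit: LogisticFit, edge_fit: LogisticFit,
            search_interval: tuple[float, float] = (1e-5, 1.0)) -> float | None:
    """Threshold maximising node-curve minus edge-curve, on the φ scale.

    Located by dense evaluation on a log10 grid followed by bounded
    local refinement.  Returns ``None`` when the difference is nowhere
    positive (e.g. identical fits).
    """
    lo, hi = math.log10(search_interval[0]), math.log10(search_interval[1])
    xs = np.linspace(lo, hi, 4000)
    diff = node_fit.predict(xs) - edge_fit.predict(xs)
    best = int(np.argmax(diff))
    if diff[best] <= 1e-12:
        return None
    a = xs[max(best - 1, 0)]
    b = xs[min(best + 1, xs.size - 1)]
    res = optimize.minimize_scalar(
        lambda x: -(node_fit.predict(x) - edge_fit.predict(x)),
        bounds=(a, b), method="bounded", options={"xatol": 1e-10},
    )
    return float(10.0 ** res.x)


def analyse(dpn: DPN, grid=None) -> RetentionCurve:
    """Full φ analysis: retention curve, logistic fits and φmax."""
    curve = retention_curve(dpn, grid)
    xs = np.log10(curve.grid)
    curve.node_fit = fit_logistic(xs, curve.node_frac)
    curve.edge_fit = fit_logistic(xs, curve.edge_frac)
    curve.phi_max = phi_max(curve.node_fit, curve.edge_fit,
                            (float(curve.grid[0]), float(curve.grid[-1])))
    return curve


__all__.append("analyse")
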