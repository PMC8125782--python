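"""Drug Prescription Network construction and interchange formats.

A DPN at ATC level L is an undirected graph whose nodes are the ATC
codes observed in the cohort at that level and whose edges join codes
co-prescribed to at least one common patient.  Node weight Pi is the
number of distinct patients prescribed code i; edge weight Cij the
number of distinct patients prescribed both i and j.  Both are patient
counts — repeat prescriptions never inflate them.  Nodes with no
co-prescription partner (degree 0) are kept: real registers contain
codes dispensed to patients who received nothing else.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import networkx as nx
import pandas as pd

from .ingest import IncidenceMap

__all__ = ["DPN", "build_dpn", "node_table", "write_graph", "read_graph"]


@dataclass
class DPN:
    """An undirected co-prescription graph with patient-count weights.

    ``graph`` is a :class:`networkx.Graph` whose nodes are code strings
    with attribute ``Pi`` and whose edges carry attribute ``Cij``.
    """

    level: int
    n_patients: int
    graph: nx.Graph

    @property
    def N(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def E(self) -> int:
        return self.graph.number_of_edges()

    @property
    def node_weight(self) -> dict[str, int]:
        return {v: d["Pi"] for v, d in self.graph.nodes(data=True)}

    @property
    def edge_weight(self) -> dict[frozenset, int]:
        return {frozenset((u, v)): d["Cij"] for u, v, d in self.graph.edges(data=True)}

    def validate(self) -> None:
        """Check the structural invariants; raise ``ValueError`` on violation."""
        for v, d in self.graph.nodes(data=True):
            if not 1 <= d["Pi"] <= self.n_patients:
                raise ValueError(f"node {v}: Pi={d['Pi']} outside [1, n={self.n_patients}]")
        for u, v, d in self.graph.edges(data=True):
            if u == v:
                raise ValueError(f"self-loop at {u}")
            cap = min(self.graph.nodes[u]["Pi"], self.graph.nodes[v]["Pi"])
            if not 1 <= d["Cij"] <= cap:
                raise ValueError(f"edge {u}-{v}: Cij={d['Cij']} outside [1, {cap}]")

    def __eq__(self, other) -> bool:
        if not isinstance(other, DPN):
            return NotImplemented
        return (
            self.level == other.level
            and self.n_patients == other.n_patients
            and self.node_weight == other.node_weight
            and self.edge_weight == other.edge_weight
        )


def build_dpn(incidence: IncidenceMap) -> DPN:
    """Build the DPN from per-patient drug sets.

    Pi and Cij are computed by counting, per code and per unordered
    code pair, the patients whose set contains it; only pairs with
    Cij >= 1 become edges, while every code with Pi >= 1 is a node even
    if isolated.
    """
    if incidence.n_patients == 0:
        raise ValueError("empty incidence map")
    g = nx.Graph()
    pair_counts: dict[tuple[str, str], int] = {}
    node_counts: dict[str, int] = {}
    for codes in incidence.sets.values():
        texts = sorted(c.text for c in codes)
        for t in texts:
            node_counts[t] = node_counts.get(t, 0) + 1
        for pair in combinations(texts, 2):
            pair_counts[pair] = pair_counts.get(pair, 0) + 1
    for t, pi in node_counts.items():
        g.add_node(t, Pi=pi)
    for (u, v), cij in pair_counts.items():
        g.add_edge(u, v, Cij=cij)
    return DPN(level=incidence.level, n_patients=incidence.n_patients, graph=g)


def node_table(dpn: DPN, metrics) -> pd.DataFrame:
    """One row per node: code, Pi, degree, betweenness, closeness.

    ``metrics`` is a :class:`dpnkit.metrics.NodeMetrics` computed on the
    same DPN; a mismatched node set is an error.
    """
    if set(metrics.k) != set(dpn.graph.nodes):
        raise ValueError("metrics were computed on a different node set")
    rows = [
        {"code": v, "Pi": dpn.graph.nodes[v]["Pi"], "ki": metrics.k[v],
         "bi": metrics.b[v], "Cli": metrics.cl[v]}
        for v in sorted(dpn.graph.nodes)
    ]
    return pd.DataFrame(rows)


def write_graph(dpn: DPN, path, format: str = "graphml") -> None:
    """Serialise a DPN as GraphML or as an edge-list CSV + node CSV pair.

    The edge-list format writes ``<path>`` with columns ``i,j,Cij`` and
    a sibling ``<stem>.nodes.csv`` with columns ``i,Pi`` (which also
    carries isolated nodes and the level / cohort-size header).
    """
    path = Path(path)
    if format == "graphml":
        g = dpn.graph.copy()
        g.graph["level"] = dpn.level
        g.graph["n_patients"] = dpn.n_patients
        nx.write_graphml(g, path)
    elif format == "edgelist":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["i", "j", "Cij"])
            for u, v, d in sorted(dpn.graph.edges(data=True)):
                w.writerow([u, v, d["Cij"]])
        with open(_node_csv_path(path), "w", newline="") as fh:
            fh.write(f"# level={dpn.level}\n# n_patients={dpn.n_patients}\n")
            w = csv.writer(fh)
            w.writerow(["i", "Pi"])
            for v, d in sorted(dpn.graph.nodes(data=True)):
                w.writerow([v, d["Pi"]])
    else:
        raise ValueError(f"unknown graph format {format!r}")


def read_graph(path, format: str = "graphml") -> DPN:
    """Read a DPN written by :func:`write_graph` (round-trip identity)."""
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        for v, d in g.nodes(data=True):
            if "Pi" not in d:
                raise ValueError(f"GraphML node {v} lacks the Pi attribute")
            d["Pi"] = int(d["Pi"])
        for u, v, d in g.edges(data=True):
            if "Cij" not in d:
                raise ValueError(f"GraphML edge {u}-{v} lacks the Cij attribute")
            d["Cij"] = int(d["Cij"])
        return DPN(level=int(g.graph["level"]), n_patients=int(g.graph["n_patients"]),
                   graph=nx.Graph(g))
    if format == "edgelist":
        g = nx.Graph()
        level = n_patients = None
        with open(_node_csv_path(path)) as fh:
            header_meta = {}
            lines = []
            for line in fh:
                if line.startswith("#"):
                    key, _, val = line[1:].strip().partition("=")
                    header_meta[key.strip()] = int(val)
                else:
                    lines.append(line)
            level = header_meta["level"]
            n_patients = header_meta["n_patients"]
            for row in csv.DictReader(lines):
                g.add_node(row["i"], Pi=int(row["Pi"]))
        with open(path) as fh:
            for row in csv.DictReader(fh):
                g.add_edge(row["i"], row["j"], Cij=int(row["Cij"]))
        return DPN(level=level, n_patients=n_patients, graph=g)
    raise ValueError(f"unknown graph format {format!r}")


def _node_csv_path(edge_path: Path) -> Path:
    return edge_path.with_suffix(".nodes.csv")
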