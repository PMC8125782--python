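"""Independent brute-force reference implementations used only by tests."""

import itertools
import math

import numpy as np


def enumerate_simple_paths(adj, s, t):
    """All simple s->t paths in an adjacency dict {u: {v: length}}."""
    paths = []

    def dfs(node, visited, path):
        if node == t:
            paths.append(list(path))
            return
        for nxt in adj[node]:
            if nxt not in visited:
                visited.add(nxt)
                path.append(nxt)
                dfs(nxt, visited, path)
                path.pop()
                visited.remove(nxt)

    dfs(s, {s}, [s])
    return paths


def brute_centralities(adj):
    """Freeman betweenness and unnormalised closeness by path enumeration.

    ``adj`` maps node -> {neighbour: edge length}.  Geodesic ties are
    split equally; closeness sums distances to reachable nodes only.
    """
    nodes = sorted(adj)
    bet = {v: 0.0 for v in nodes}
    dist = {v: {} for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = enumerate_simple_paths(adj, s, t)
        if not paths:
            continue
        lengths = [sum(adj[p[i]][p[i + 1]] for i in range(len(p) - 1)) for p in paths]
        d = min(lengths)
        dist[s][t] = dist[t][s] = d
        geodesics = [p for p, l in zip(paths, lengths) if math.isclose(l, d)]
        for p in geodesics:
            for v in p[1:-1]:
                bet[v] += 1.0 / len(geodesics)
    clo = {}
    for v in nodes:
        total = sum(dist[v].values())
        clo[v] = 1.0 / total if total > 0 else 0.0
    return bet, clo


def graph_to_adj(graph, weighting):
    adj = {v: {} for v in graph.nodes}
    for u, v, d in graph.edges(data=True):
        length = {"unweighted": 1.0, "cij": float(d["Cij"]),
                  "inverse-cij": 1.0 / d["Cij"]}[weighting]
        adj[u][v] = adj[v][u] = length
    return adj


def edge_end_pearson(graph):
    """Assortativity as the plain Pearson correlation over oriented edge ends."""
    deg = dict(graph.degree())
    xs, ys = [], []
    for u, v in graph.edges:
        xs += [deg[u], deg[v]]
        ys += [deg[v], deg[u]]
    xs, ys = np.array(xs, float), np.array(ys, float)
    if xs.std() == 0 or ys.std() == 0:
        return None
    return float(np.corrcoef(xs, ys)[0, 1])


def naive_ward_d2(D):
    """O(n^3) agglomerative ward.D2 via the Lance-Williams recurrence.

    Returns (merges, heights) where each merge is the frozenset of leaf
    indices of the newly formed cluster.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    dist = {frozenset((i, j)): D[i, j] for i, j in itertools.combinations(range(n), 2)}
    merges, heights = [], []
    while len(clusters) > 1:
        (a, b), h = min(
            ((pair, dist[frozenset(pair)])
             for pair in itertools.combinations(sorted(clusters), 2)),
            key=lambda kv: kv[1],
        )
        na, nb = len(clusters[a]), len(clusters[b])
        new = clusters.pop(a) | clusters.pop(b)
        merges.append(new)
        heights.append(h)
        new_id = max(list(clusters) + [a, b]) + 1
        for k in list(clusters):
            nk = len(clusters[k])
            dka = dist.pop(frozenset((k, a)))
            dkb = dist.pop(frozenset((k, b)))
            dab = h
            d2 = ((na + nk) * dka**2 + (nb + nk) * dkb**2 - nk * dab**2) / (na + nb + nk)
            dist[frozenset((k, new_id))] = math.sqrt(max(d2, 0.0))
        dist.pop(frozenset((a, b)), None)
        clusters[new_id] = new
    return merges, heights


def scipy_linkage_merges(Z):
    """Leaf compositions of each scipy linkage merge, for topology comparison."""
    n = Z.shape[0] + 1
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    for step, (a, b, _, _) in enumerate(Z):
        new = members[int(a)] | members[int(b)]
        members[n + step] = new
        merges.append(new)
    return merges
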