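"""Brute-force, definition-level centrality oracles for small graphs.

Deliberately naive: breadth-first searches, explicit path enumeration and
dense eigendecompositions, independent of the implementations under test.
"""

from itertools import combinations

import numpy as np


def _adj(graph):
    nodes = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)))
    for u, v in graph.edges:
        a[index[u], index[v]] = a[index[v], index[u]] = 1.0
    return nodes, a


def _bfs_distances(graph, source):
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in graph[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def _all_shortest_paths(graph, s, t):
    """Enumerate every shortest s-t path by depth-first walking the BFS DAG."""
    dist = _bfs_distances(graph, s)
    if t not in dist:
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(list(path))
            return
        for v in graph[u]:
            if dist.get(v) == dist[u] + 1:
                extend(path + [v])

    extend([s])
    return paths


def degree_oracle(graph):
    return {v: float(len(graph[v])) for v in graph}


def betweenness_oracle(graph):
    """Normalized betweenness by explicit enumeration of all shortest paths."""
    n = graph.number_of_nodes()
    bc = {v: 0.0 for v in graph}
    for s, t in combinations(sorted(graph.nodes), 2):
        paths = _all_shortest_paths(graph, s, t)
        if not paths:
            continue
        for v in graph:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / len(paths)
    scale = 2.0 / ((n - 1) * (n - 2)) if n > 2 else 1.0
    return {v: bc[v] * scale for v in bc}


def closeness_oracle(graph):
    """Component-restricted closeness scaled by the component-size fraction."""
    n = graph.number_of_nodes()
    out = {}
    for v in graph:
        dist = _bfs_distances(graph, v)
        reachable = len(dist) - 1
        total = sum(dist.values())
        if reachable == 0 or total == 0:
            out[v] = 0.0
        else:
            out[v] = (reachable / total) * (reachable / (n - 1))
    return out


def eigenvector_oracle(graph):
    """Leading adjacency eigenvector (dense eigh), unit Euclidean norm."""
    nodes, a = _adj(graph)
    vals, vecs = np.linalg.eigh(a)
    lead = np.abs(vecs[:, np.argmax(vals)])
    lead /= np.linalg.norm(lead)
    return dict(zip(nodes, lead))


def subgraph_oracle(graph):
    """Diagonal of expm(A) via the spectral form sum_j v_ij^2 e^{lambda_j}."""
    nodes, a = _adj(graph)
    vals, vecs = np.linalg.eigh(a)
    diag = (vecs**2) @ np.exp(vals)
    return dict(zip(nodes, diag))


def clustering_oracle(graph):
    out = {}
    for v in graph:
        nbrs = list(graph[v])
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(1 for a, b in combinations(nbrs, 2) if graph.has_edge(a, b))
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def soecc_oracle(graph):
    out = {}
    for v in graph:
        total = 0.0
        for u in graph[v]:
            z = sum(1 for w in graph if graph.has_edge(v, w) and graph.has_edge(u, w))
            den = min(len(graph[v]) - 1, len(graph[u]) - 1)
            total += z / den if den > 0 else 0.0
        out[v] = total
    return out


def mnc_oracle(graph):
    out = {}
    for v in graph:
        nbrs = set(graph[v])
        best = 0
        seen = set()
        for start in nbrs:
            if start in seen:
                continue
            comp = {start}
            frontier = [start]
            while frontier:
                u = frontier.pop()
                for w in graph[u]:
                    if w in nbrs and w not in comp:
                        comp.add(w)
                        frontier.append(w)
            seen |= comp
            best = max(best, len(comp))
        out[v] = float(best)
    return out


def lac_oracle(graph):
    out = {}
    for v in graph:
        nbrs = set(graph[v])
        if not nbrs:
            out[v] = 0.0
            continue
        total = 0
        for u in nbrs:
            total += sum(1 for w in graph[u] if w in nbrs)
        out[v] = total / len(nbrs)
    return out


def lid_oracle(graph):
    out = {}
    for v in graph:
        closed = set(graph[v]) | {v}
        if len(closed) == 1:
            out[v] = 0.0
            continue
        edges = sum(
            1 for a, b in combinations(sorted(closed), 2) if graph.has_edge(a, b)
        )
        out[v] = edges / len(graph[v])
    return out


ORACLES = {
    "DC": degree_oracle,
    "BC": betweenness_oracle,
    "CC": closeness_oracle,
    "EC": eigenvector_oracle,
    "SC": subgraph_oracle,
    "ClusterC": clustering_oracle,
    "SoECC": soecc_oracle,
    "MNC": mnc_oracle,
    "LAC": lac_oracle,
    "LID": lid_oracle,
}
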