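"""Independent brute-force twins of every structural measure.

Deliberately different algorithms from the package: Floyd–Warshall instead
of BFS, recursive enumeration of all shortest paths instead of Brandes,
triple-loop triangle census instead of adjacency powers, np.corrcoef instead
of hand-rolled Pearson sums.
"""

from __future__ import annotations

import itertools

import numpy as np


def adjacency(net):
    nodes = sorted(net.nodes)
    pos = {u: i for i, u in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)), dtype=bool)
    for u, v in net.links:
        a[pos[u], pos[v]] = True
    return nodes, a


def undirected(a):
    return a | a.T


def floyd_warshall(u):
    n = u.shape[0]
    d = np.full((n, n), np.inf)
    d[u] = 1.0
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, k, None] + d[None, k, :])
    return d


def largest_component(d):
    n = d.shape[0]
    seen = set()
    best = [0]
    for s in range(n):
        if s in seen:
            continue
        comp = [j for j in range(n) if np.isfinite(d[s, j]) and np.isfinite(d[j, s])]
        seen.update(comp)
        if len(comp) > len(best):
            best = comp
    return np.array(best)


def oracle_density(net):
    n = len(net.nodes)
    return len(net.links) / (n * (n - 1))


def oracle_reciprocity(net):
    links = set(net.links)
    return sum((v, u) in links for u, v in links) / len(links)


def oracle_diameter(net):
    _, a = adjacency(net)
    d = floyd_warshall(undirected(a))
    comp = largest_component(d)
    sub = d[np.ix_(comp, comp)]
    return float(sub.max())


def oracle_path_length(net, include_self=True):
    _, a = adjacency(net)
    d = floyd_warshall(undirected(a))
    comp = largest_component(d)
    sub = d[np.ix_(comp, comp)]
    m = len(comp)
    total = float(sub.sum())
    return total / (m * m if include_self else m * (m - 1))


def oracle_clustering(net):
    _, a = adjacency(net)
    u = undirected(a)
    n = u.shape[0]
    coeffs = []
    for i in range(n):
        nb = np.flatnonzero(u[i])
        if len(nb) < 2:
            coeffs.append(0.0)
            continue
        pairs = closed = 0
        for x, y in itertools.combinations(nb, 2):
            pairs += 1
            closed += bool(u[x, y])
        coeffs.append(closed / pairs)
    return float(np.mean(coeffs))


def oracle_assortativity(net):
    """Pearson correlation on the doubled edge-endpoint degree list, or None."""
    _, a = adjacency(net)
    u = undirected(a)
    deg = u.sum(axis=1).astype(float)
    xs, ys = [], []
    n = u.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            if u[i, j]:
                xs += [deg[i], deg[j]]
                ys += [deg[j], deg[i]]
    if not xs or np.std(xs) < 1e-12:
        return None
    return float(np.corrcoef(xs, ys)[0, 1])


def _freeman(values, denom):
    values = np.asarray(values, dtype=float)
    return float((values.max() - values).sum() / denom)


def oracle_degree_score(net, aggregation="freeman"):
    _, a = adjacency(net)
    deg = undirected(a).sum(axis=1).astype(float)
    n = len(deg)
    if aggregation == "mean":
        return float((deg / (n - 1)).mean())
    return _freeman(deg, (n - 1) * (n - 2))


def oracle_closeness_score(net, aggregation="freeman"):
    _, a = adjacency(net)
    d = floyd_warshall(undirected(a))
    comp = largest_component(d)
    m = len(comp)
    if m < 3:
        return None
    sub = d[np.ix_(comp, comp)]
    c = (m - 1) / sub.sum(axis=1)
    if aggregation == "mean":
        return float(c.mean())
    return _freeman(c, (m - 1) * (m - 2) / (2 * m - 3))


def _all_shortest_paths(u, d, s, t):
    if s == t:
        return [[s]]
    paths = []
    for w in np.flatnonzero(u[s]):
        if d[w, t] == d[s, t] - 1:
            for p in _all_shortest_paths(u, d, w, t):
                paths.append([s] + p)
    return paths


def oracle_betweenness_values(u):
    """Per-node betweenness by enumerating every shortest path (undirected:
    each unordered pair once)."""
    n = u.shape[0]
    d = floyd_warshall(u)
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        if not np.isfinite(d[s, t]) or d[s, t] == 0:
            continue
        paths = _all_shortest_paths(u, d, s, t)
        for p in paths:
            for w in p[1:-1]:
                bc[w] += 1.0 / len(paths)
    return bc


def oracle_betweenness_score(net, aggregation="freeman"):
    _, a = adjacency(net)
    u = undirected(a)
    d = floyd_warshall(u)
    comp = largest_component(d)
    m = len(comp)
    if m < 3:
        return None
    sub = u[np.ix_(comp, comp)]
    b = oracle_betweenness_values(sub) / ((m - 1) * (m - 2) / 2)
    if aggregation == "mean":
        return float(b.mean())
    return _freeman(b, m - 1)
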