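"""Structural measures of per-patient networks, from first principles.

Ten measures per network: node count, density, diameter, path length,
assortativity, clustering coefficient, reciprocity, and degree / closeness /
betweenness scores.  Distance-based measures default to the undirected
projection restricted to its largest connected component; the three
centrality scores default to Freeman centralization (star-normalized to
[0, 1]).  Every convention is a knob on :class:`MetricConfig`.

No graph library is used here; shortest paths are BFS, betweenness is the
Brandes accumulation, clustering is a triangle count via the adjacency
matrix.  (networkx appears only in the test suite, as a cross-check.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .io_model import MetricRecord, PatientNetwork

__all__ = [
    "Aggregation",
    "PathMode",
    "Projection",
    "UnreachablePolicy",
    "MetricConfig",
    "DEFAULT_CONFIG",
    "UndefinedMetricError",
    "density",
    "diameter",
    "path_length",
    "clustering_coefficient",
    "assortativity",
    "reciprocity",
    "degree_score",
    "closeness_score",
    "betweenness_score",
    "compute_all",
]


class Aggregation(Enum):
    FREEMAN_CENTRALIZATION = "freeman_centralization"
    MEAN_NORMALIZED = "mean_normalized"


class PathMode(Enum):
    INCLUDE_SELF_PAIRS = "include_self_pairs"
    EXCLUDE_SELF_PAIRS = "exclude_self_pairs"


class Projection(Enum):
    UNDIRECTED = "undirected"
    DIRECTED = "directed"


class UnreachablePolicy(Enum):
    LARGEST_COMPONENT = "largest_component"
    REACHABLE_PAIRS_ONLY = "reachable_pairs_only"


@dataclass(frozen=True)
class MetricConfig:
    path_mode: PathMode = PathMode.INCLUDE_SELF_PAIRS
    projection: Projection = Projection.UNDIRECTED
    centrality_aggregation: Aggregation = Aggregation.FREEMAN_CENTRALIZATION
    unreachable_policy: UnreachablePolicy = UnreachablePolicy.LARGEST_COMPONENT


DEFAULT_CONFIG = MetricConfig()


class UndefinedMetricError(ValueError):
    """The measure is undefined for this network (too small, no links, ...)."""


# ---------------------------------------------------------------------------
# internal graph machinery


def _index(net: PatientNetwork) -> Tuple[list, np.ndarray]:
    """Sorted node list and boolean directed adjacency matrix."""
    nodes = sorted(net.nodes)
    pos = {u: i for i, u in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)), dtype=bool)
    for u, v in net.links:
        a[pos[u], pos[v]] = True
    return nodes, a


def _project(a: np.ndarray, projection: Projection) -> np.ndarray:
    return a if projection is Projection.DIRECTED else (a | a.T)


def _adj_lists(a: np.ndarray) -> List[np.ndarray]:
    return [np.flatnonzero(a[i]) for i in range(a.shape[0])]


def _distance_matrix(a: np.ndarray) -> np.ndarray:
    """All-pairs hop distances by simultaneous frontier expansion (BFS level
    sets for every source at once, as boolean matrix products)."""
    n = a.shape[0]
    adj = a.astype(np.uint8)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    reached = np.eye(n, dtype=bool)
    frontier = np.eye(n, dtype=np.uint8)
    d = 0
    while frontier.any():
        d += 1
        nxt = ((frontier @ adj) > 0) & ~reached
        dist[nxt] = d
        reached |= nxt
        frontier = nxt.astype(np.uint8)
    return dist


def _largest_component(dist: np.ndarray) -> np.ndarray:
    """Indices of the largest mutually-reachable node set.

    For a symmetric (projected) distance matrix this is the largest connected
    component; for a directed one, the largest strongly connected component.
    Ties broken by smallest member index, for determinism.
    """
    n = dist.shape[0]
    mutual = np.isfinite(dist) & np.isfinite(dist.T)
    seen = np.zeros(n, dtype=bool)
    best: np.ndarray = np.array([0])
    for s in range(n):
        if seen[s]:
            continue
        comp = np.flatnonzero(mutual[s])
        seen[comp] = True
        if comp.size > best.size:
            best = comp
    return best


def _admitted_distances(net: PatientNetwork, cfg: MetricConfig):
    """Projected distance matrix plus the node subset / pair mask admitted
    by the unreachable policy.  Requires at least one link."""
    if net.n_links == 0:
        raise UndefinedMetricError("network has no links")
    _, a = _index(net)
    proj = _project(a, cfg.projection)
    dist = _distance_matrix(proj)
    if cfg.unreachable_policy is UnreachablePolicy.LARGEST_COMPONENT:
        comp = _largest_component(dist)
        sub = dist[np.ix_(comp, comp)]
        mask = np.ones_like(sub, dtype=bool)
        np.fill_diagonal(mask, False)
        return sub, comp, mask
    comp = np.arange(dist.shape[0])
    mask = np.isfinite(dist)
    np.fill_diagonal(mask, False)
    return dist, comp, mask


# ---------------------------------------------------------------------------
# the ten measures


def density(net: PatientNetwork) -> float:
    """Observed links over the n(n-1) possible directed links."""
    n = net.n_nodes
    if n < 2:
        raise UndefinedMetricError("density needs at least 2 nodes")
    return net.n_links / (n * (n - 1))


def diameter(net: PatientNetwork, cfg: MetricConfig = DEFAULT_CONFIG) -> float:
    """Longest shortest-path length over admitted ordered pairs."""
    dist, _, mask = _admitted_distances(net, cfg)
    if not mask.any():
        raise UndefinedMetricError("no admitted node pairs")
    return float(dist[mask].max())


def path_length(net: PatientNetwork, cfg: MetricConfig = DEFAULT_CONFIG) -> float:
    """Mean shortest-path distance over admitted ordered pairs.

    Under INCLUDE_SELF_PAIRS each admitted node contributes a self-pair at
    distance 0 to the denominator.
    """
    dist, comp, mask = _admitted_distances(net, cfg)
    total = float(dist[mask].sum())
    n_pairs = int(mask.sum())
    if cfg.path_mode is PathMode.INCLUDE_SELF_PAIRS:
        n_pairs += comp.size
    if n_pairs == 0:
        raise UndefinedMetricError("no admitted node pairs")
    return total / n_pairs


def clustering_coefficient(net: PatientNetwork) -> float:
    """Average local clustering on the undirected projection.

    Local coefficient of node i: closed neighbour pairs / all neighbour
    pairs; nodes of degree < 2 contribute 0.  Averaged over all n nodes.
    """
    n = net.n_nodes
    if n < 3:
        raise UndefinedMetricError("clustering needs at least 3 nodes")
    _, a = _index(net)
    u = _project(a, Projection.UNDIRECTED).astype(np.int64)
    deg = u.sum(axis=1)
    # (u @ u @ u) diagonal counts 2 * triangles through each node
    tri2 = np.einsum("ij,jk,ki->i", u, u, u)
    coeffs = np.zeros(n)
    ok = deg >= 2
    coeffs[ok] = tri2[ok] / (deg[ok] * (deg[ok] - 1))
    return float(coeffs.mean())


def assortativity(net: PatientNetwork) -> float:
    """Pearson correlation of endpoint total degrees over undirected edges.

    Each undirected edge contributes both orderings of its endpoint degrees.
    Raises UndefinedMetricError when the endpoint-degree variance is zero
    (e.g. regular graphs) or the network has no links.
    """
    if net.n_links == 0:
        raise UndefinedMetricError("network has no links")
    _, a = _index(net)
    u = _project(a, Projection.UNDIRECTED)
    deg = u.sum(axis=1).astype(float)
    ii, jj = np.nonzero(np.triu(u, k=1))
    x = np.concatenate([deg[ii], deg[jj]])
    y = np.concatenate([deg[jj], deg[ii]])
    m = x.size
    sx = x.sum()
    sxx = (x * x).sum()
    sxy = (x * y).sum()
    # x and y are permutations of each other, so shared moments
    var = sxx - sx * sx / m
    if var <= 1e-12:
        raise UndefinedMetricError("zero endpoint-degree variance")
    cov = sxy - sx * sx / m
    return float(cov / var)


def reciprocity(net: PatientNetwork) -> float:
    """Fraction of directed links whose reverse link also exists."""
    if net.n_links == 0:
        raise UndefinedMetricError("network has no links")
    links = net.links
    mutual = sum(1 for (u, v) in links if (v, u) in links)
    return mutual / len(links)


def _freeman(values: np.ndarray, denom: float) -> float:
    if denom <= 0:
        raise UndefinedMetricError("centralization denominator is zero")
    # clamp float noise at the extremes
    return float(min(1.0, max(0.0, (values.max() - values).sum() / denom)))


def degree_score(net: PatientNetwork, cfg: MetricConfig = DEFAULT_CONFIG) -> float:
    """Per-network degree summary on the undirected projection, all n nodes.

    FREEMAN_CENTRALIZATION: sum(c_max - c_i) / ((n-1)(n-2)), the star-
    normalized Freeman index.  MEAN_NORMALIZED: mean of c_i/(n-1).
    """
    n = net.n_nodes
    if n < 3:
        raise UndefinedMetricError("degree score needs at least 3 nodes")
    _, a = _index(net)
    deg = _project(a, Projection.UNDIRECTED).sum(axis=1).astype(float)
    if cfg.centrality_aggregation is Aggregation.MEAN_NORMALIZED:
        return float((deg / (n - 1)).mean())
    return _freeman(deg, (n - 1) * (n - 2))


def closeness_score(net: PatientNetwork, cfg: MetricConfig = DEFAULT_CONFIG) -> float:
    """Freeman centralization (or mean) of normalized closeness.

    Closeness of node i is (m-1)/sum_j d(i, j) within the admitted component
    of m nodes; the Freeman denominator (m-1)(m-2)/(2m-3) is attained by the
    star.
    """
    if net.n_nodes < 3:
        raise UndefinedMetricError("closeness score needs at least 3 nodes")
    dist, comp, mask = _admitted_distances(net, cfg)
    if cfg.unreachable_policy is UnreachablePolicy.LARGEST_COMPONENT:
        m = comp.size
        if m < 3:
            raise UndefinedMetricError("admitted component smaller than 3")
        with np.errstate(invalid="ignore"):
            c = (m - 1) / np.where(mask, dist, 0).sum(axis=1)
        denom_n = m
    else:
        # Wasserman–Faust correction for disconnected graphs
        n = dist.shape[0]
        if not mask.any():
            raise UndefinedMetricError("no admitted pairs")
        reach = mask.sum(axis=1).astype(float)
        sums = np.where(mask, np.where(np.isfinite(dist), dist, 0.0), 0.0).sum(axis=1)
        c = np.zeros(n)
        ok = (reach > 0) & (sums > 0)
        c[ok] = (reach[ok] / (n - 1)) * (reach[ok] / sums[ok])
        denom_n = n
    if cfg.centrality_aggregation is Aggregation.MEAN_NORMALIZED:
        return float(c.mean())
    return _freeman(c, (denom_n - 1) * (denom_n - 2) / (2 * denom_n - 3))


def _brandes(adj: List[np.ndarray], n: int, directed: bool) -> np.ndarray:
    """Shortest-path betweenness via Brandes' accumulation (unweighted)."""
    bc = np.zeros(n)
    for s in range(n):
        stack: List[int] = []
        preds: List[List[int]] = [[] for _ in range(n)]
        sigma = np.zeros(n)
        sigma[s] = 1
        dist = np.full(n, -1)
        dist[s] = 0
        queue = [s]
        qi = 0
        while qi < len(queue):
            u = queue[qi]
            qi += 1
            stack.append(u)
            for v in adj[u]:
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    queue.append(v)
                if dist[v] == dist[u] + 1:
                    sigma[v] += sigma[u]
                    preds[v].append(u)
        delta = np.zeros(n)
        while stack:
            w = stack.pop()
            for u in preds[w]:
                delta[u] += sigma[u] / sigma[w] * (1 + delta[w])
            if w != s:
                bc[w] += delta[w]
    if not directed:
        bc /= 2
    return bc


def betweenness_score(net: PatientNetwork, cfg: MetricConfig = DEFAULT_CONFIG) -> float:
    """Freeman centralization (or mean) of normalized betweenness.

    Betweenness is computed within the admitted component of m nodes and
    normalized by (m-1)(m-2)/2 (undirected) or (m-1)(m-2) (directed); the
    centralization denominator m-1 is attained by the star.
    """
    if net.n_nodes < 3:
        raise UndefinedMetricError("betweenness score needs at least 3 nodes")
    if net.n_links == 0:
        raise UndefinedMetricError("network has no links")
    _, a = _index(net)
    proj = _project(a, cfg.projection)
    dist = _distance_matrix(proj)
    if cfg.unreachable_policy is UnreachablePolicy.LARGEST_COMPONENT:
        comp = _largest_component(dist)
        sub = proj[np.ix_(comp, comp)]
    else:
        comp = np.arange(proj.shape[0])
        sub = proj
    m = comp.size
    if m < 3:
        raise UndefinedMetricError("admitted component smaller than 3")
    directed = cfg.projection is Projection.DIRECTED
    bc = _brandes(_adj_lists(sub), m, directed)
    pairs = (m - 1) * (m - 2) * (1 if directed else 0.5)
    b = bc / pairs
    if cfg.centrality_aggregation is Aggregation.MEAN_NORMALIZED:
        return float(b.mean())
    return _freeman(b, m - 1)


# ---------------------------------------------------------------------------


def compute_all(net: PatientNetwork, cfg: MetricConfig = DEFAULT_CONFIG) -> MetricRecord:
    """All ten measures; individual undefined measures become None + flag."""
    record = MetricRecord(
        group_id=net.group_id,
        year=net.year,
        care_band=net.care_band,
        n_nodes=net.n_nodes,
    )
    computations = {
        "density": lambda: density(net),
        "diameter": lambda: diameter(net, cfg),
        "path_length": lambda: path_length(net, cfg),
        "assortativity": lambda: assortativity(net),
        "clustering": lambda: clustering_coefficient(net),
        "reciprocity": lambda: reciprocity(net),
        "degree_score": lambda: degree_score(net, cfg),
        "closeness_score": lambda: closeness_score(net, cfg),
        "betweenness_score": lambda: betweenness_score(net, cfg),
    }
    undefined = []
    for name, fn in computations.items():
        try:
            setattr(record, name, fn())
        except UndefinedMetricError:
            setattr(record, name, None)
            undefined.append(name)
    record.undefined = tuple(undefined)
    return record
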