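from __future__ import annotations

import numpy as np
import pytest

from carenet.io_model import CareBand, PatientNetwork


def make_network(nodes, links, group_id="g", year=2018, care_band=None):
    return PatientNetwork(
        group_id=group_id,
        year=year,
        care_band=care_band,
        nodes=frozenset(nodes),
        links=frozenset(links),
    )


def random_digraph(rng: np.random.Generator, n: int, p: float, **kw) -> PatientNetwork:
    nodes = [f"v{i:02d}" for i in range(n)]
    links = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(n)
        if i != j and rng.random() < p
    ]
    return make_network(nodes, links, **kw)


def random_linked_digraph(rng, n, p, **kw):
    """Random digraph guaranteed to have at least one link."""
    while True:
        net = random_digraph(rng, n, p, **kw)
        if net.n_links:
            return net


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# small named graphs used across test modules
@pytest.fixture
def path4():
    return make_network("abcd", [("a", "b"), ("b", "c"), ("c", "d")])


@pytest.fixture
def triangle():
    return make_network("abc", [("a", "b"), ("b", "c"), ("c", "a")])


def star(n):
    nodes = [f"v{i}" for i in range(n)]
    return make_network(nodes, [(nodes[0], v) for v in nodes[1:]])


def complete(n):
    nodes = [f"v{i}" for i in range(n)]
    return make_network(nodes, [(u, v) for u in nodes for v in nodes if u != v])
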