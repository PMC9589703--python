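"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library's own code paths (and
networkx): component profiles come from a hand-rolled BFS, and the touch
relationship from its plain-language definition, so that the calculus is
checked against genuinely independent references.
"""

from __future__ import annotations

import itertools
import random
from typing import Dict, FrozenSet, List, Set, Tuple

import pytest

from netintervene import Graph, SocialNetwork
from netintervene import fixture as load_fixture


# --------------------------------------------------------------------------
# Independent oracles

def bfs_component_sizes(vertices, edges) -> List[int]:
    """Connected-component sizes by breadth-first search (weak connectivity).

    Independent oracle: no networkx, no package code.
    """
    adjacency: Dict[str, Set[str]] = {v: set() for v in vertices}
    for u, v in edges:
        adjacency[u].add(v)
        adjacency[v].add(u)
    seen: Set[str] = set()
    sizes: List[int] = []
    for start in vertices:
        if start in seen:
            continue
        queue = [start]
        seen.add(start)
        count = 0
        while queue:
            node = queue.pop()
            count += 1
            for nxt in adjacency[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    queue.append(nxt)
        sizes.append(count)
    return sorted(sizes, reverse=True)


def brute_force_touch(net: SocialNetwork, a: str, b: str) -> bool:
    """Touch by its prose definition: no shared vertex, and at least one
    network edge connecting a member of one community to a member of the
    other."""
    am, bm = net.members(a), net.members(b)
    if am & bm:
        return False
    return any(
        (u in am and v in bm) or (u in bm and v in am)
        for u, v in net.graph.edges
    )


# --------------------------------------------------------------------------
# Random-network generator used by the property suites

def random_social_network(
    rng: random.Random,
    max_vertices: int = 12,
    edge_prob: float = 0.3,
    directed: bool = False,
    labels: Tuple[str, str] = ("blue", "red"),
) -> SocialNetwork:
    """A random simple network with two (possibly overlapping, possibly
    empty) communities; every vertex draws its membership uniformly from
    {∅, {A}, {B}, {A,B}}."""
    n = rng.randint(1, max_vertices)
    vertices = [f"v{i:02d}" for i in range(n)]
    pairs = (
        itertools.permutations(vertices, 2)
        if directed
        else itertools.combinations(vertices, 2)
    )
    edges = [(u, v) for u, v in pairs if rng.random() < edge_prob]
    choices = [frozenset(), frozenset({labels[0]}), frozenset({labels[1]}),
               frozenset(labels)]
    membership = {v: rng.choice(choices) for v in vertices}
    return SocialNetwork.build(
        vertices=vertices, edges=edges, membership=membership,
        labels=labels, directed=directed,
    )


def random_disjoint_communities(
    rng: random.Random,
    max_vertices: int = 30,
    edge_prob: float = 0.2,
    atomized_a: bool = False,
) -> SocialNetwork:
    """Random network whose communities 'red' and 'blue' are vertex-disjoint
    (each non-empty); with ``atomized_a`` the red community additionally has
    no internal edges — the planted preconditions of the infiltration
    algorithms."""
    n = rng.randint(4, max_vertices)
    vertices = [f"v{i:02d}" for i in range(n)]
    shuffled = vertices[:]
    rng.shuffle(shuffled)
    n_red = rng.randint(1, max(1, n // 3))
    n_blue = rng.randint(1, max(1, n // 3))
    red = set(shuffled[:n_red])
    blue = set(shuffled[n_red:n_red + n_blue])
    membership = {}
    for v in vertices:
        if v in red:
            membership[v] = {"red"}
        elif v in blue:
            membership[v] = {"blue"}
        else:
            membership[v] = set()
    edges = []
    for u, v in itertools.combinations(vertices, 2):
        if atomized_a and u in red and v in red:
            continue
        if rng.random() < edge_prob:
            edges.append((u, v))
    return SocialNetwork.build(
        vertices=vertices, edges=edges, membership=membership,
        labels={"blue", "red"},
    )


# --------------------------------------------------------------------------
# Fixtures

@pytest.fixture
def fig1a() -> SocialNetwork:
    return load_fixture("fig1a")


@pytest.fixture
def fig1b() -> SocialNetwork:
    return load_fixture("fig1b")


@pytest.fixture
def fig3a() -> SocialNetwork:
    return load_fixture("fig3a")


@pytest.fixture
def fig4() -> SocialNetwork:
    return load_fixture("fig4")


@pytest.fixture
def fig5a() -> SocialNetwork:
    return load_fixture("fig5a")


@pytest.fixture
def fig5b() -> SocialNetwork:
    return load_fixture("fig5b")


@pytest.fixture
def fig7a() -> SocialNetwork:
    return load_fixture("fig7a")


@pytest.fixture
def empty_graph() -> Graph:
    return Graph()
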