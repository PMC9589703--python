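"""The topological-relationship calculus between communities.

Two communities are compared through three graph-valued binary relations —
intersection ``I``, union ``U`` and subtraction ``S`` — composed with the
component-profile map ``T`` that sends a graph to the multiset of its
connected-component sizes.  Qualitative relationships (disjoint, containment,
equal, partial overlap, touch) are then characterised by necessary and
sufficient conditions on those multisets, e.g. two communities are disjoint
iff ``T∘I(A, B) = {}``, and they touch iff additionally the union has fewer
components than the two communities have separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Tuple

import networkx as nx

from .network import Graph, SocialNetwork, community_subgraph

__all__ = [
    "ComponentProfile",
    "Condition",
    "ConditionSet",
    "intersect",
    "union_graphs",
    "subtract",
    "profile",
    "profile_relation",
    "induced_union",
    "ego",
    "evaluate",
    "classify",
    "most_specific",
    "relationship_conditions",
    "RELATIONSHIPS",
]


# --------------------------------------------------------------------------
# Component profiles (the map T)

@dataclass(frozen=True)
class ComponentProfile:
    """A multiset of connected-component sizes, stored non-increasing.

    Equality is multiset equality; the canonical sorted storage makes the
    profile hashable and order-free.
    """

    sizes: Tuple[int, ...] = ()

    def __post_init__(self) -> None:
        ordered = tuple(sorted((int(s) for s in self.sizes), reverse=True))
        if any(s < 1 for s in ordered):
            raise ValueError("component sizes must be positive")
        object.__setattr__(self, "sizes", ordered)

    def __len__(self) -> int:
        """Multiset cardinality: the number of connected components."""
        return len(self.sizes)

    def __iter__(self):
        return iter(self.sizes)

    def __bool__(self) -> bool:
        return bool(self.sizes)

    @property
    def total(self) -> int:
        """Total vertex count: the sum of component sizes."""
        return sum(self.sizes)

    @property
    def is_empty(self) -> bool:
        return not self.sizes

    def all_singletons(self) -> bool:
        """True iff every component has size one (vacuously true when empty)."""
        return all(s == 1 for s in self.sizes)

    def __repr__(self) -> str:
        return "{" + ", ".join(str(s) for s in self.sizes) + "}"


# --------------------------------------------------------------------------
# Binary relations I, U, S and the map T

def _check_directedness(g: Graph, g2: Graph) -> None:
    if g.directed != g2.directed:
        raise ValueError("cannot relate a directed and an undirected graph")


def intersect(g: Graph, g2: Graph) -> Graph:
    """The binary relation ``I``: intersection of vertex and edge sets."""
    _check_directedness(g, g2)
    return Graph(
        vertices=g.vertices & g2.vertices,
        edges=g.edges & g2.edges,
        directed=g.directed,
    )


def union_graphs(g: Graph, g2: Graph) -> Graph:
    """The binary relation ``U``: union of vertex and edge sets."""
    _check_directedness(g, g2)
    return Graph(
        vertices=g.vertices | g2.vertices,
        edges=g.edges | g2.edges,
        directed=g.directed,
    )


def subtract(g: Graph, g2: Graph) -> Graph:
    """The binary relation ``S``: vertex/edge subtraction.

    Subtracting a vertex removes all its incident edges, so the edge set is
    additionally restricted to pairs whose endpoints both survive.
    """
    _check_directedness(g, g2)
    vertices = g.vertices - g2.vertices
    edges = frozenset(
        e for e in g.edges - g2.edges if e[0] in vertices and e[1] in vertices
    )
    return Graph(vertices=vertices, edges=edges, directed=g.directed)


def profile(g: Graph) -> ComponentProfile:
    """The map ``T``: multiset of connected-component vertex counts.

    Directed graphs use weak connectivity: an influence edge connects its
    endpoints regardless of orientation.
    """
    if not g.vertices:
        return ComponentProfile()
    if g.directed:
        nxg = nx.DiGraph()
        nxg.add_nodes_from(g.vertices)
        nxg.add_edges_from(g.edges)
        comps = nx.weakly_connected_components(nxg)
    else:
        nxg = nx.Graph()
        nxg.add_nodes_from(g.vertices)
        nxg.add_edges_from(g.edges)
        comps = nx.connected_components(nxg)
    return ComponentProfile(tuple(len(c) for c in comps))


_RELATIONS = {
    "I": intersect,
    "U": union_graphs,
    "S": subtract,
}


def profile_relation(
    net: SocialNetwork, relation: str, a: str, b: str
) -> ComponentProfile:
    """``T`` composed with a binary relation of two community subgraphs.

    ``relation`` is one of ``"I"``, ``"U"``, ``"S"``; subtraction uses the
    argument order ``(a, b)``.
    """
    try:
        rel = _RELATIONS[relation]
    except KeyError:
        raise ValueError(f"unknown relation {relation!r}; expected one of I, U, S") from None
    return profile(rel(community_subgraph(net, a), community_subgraph(net, b)))


def induced_union(net: SocialNetwork, a: str, b: str) -> Graph:
    """The network subgraph induced by the union of two communities' members.

    Unlike the plain union of the two community subgraphs, this view retains
    edges that *cross* between the communities.  The touch bound is evaluated
    on it: for vertex-disjoint communities the plain union can never contain
    a connecting edge, so only the induced view lets the component count of
    the union drop below the two communities' combined component count —
    which is precisely what "touching" means.  Whenever the communities
    overlap, the two views have identical component structure.
    """
    members = net.members(a) | net.members(b)
    edges = frozenset(
        e for e in net.graph.edges if e[0] in members and e[1] in members
    )
    return Graph(vertices=members, edges=edges, directed=net.directed)


def ego(net: SocialNetwork, v: str) -> Graph:
    """The ego community ``N(v)``: ``v`` plus its neighbours, with no edges.

    The edge set is deliberately empty, so intersecting an ego community with
    a community subgraph yields only singleton components — the profile's
    cardinality counts shared vertices.  Neighbours are out-neighbours when
    the network is directed.
    """
    if v not in net.graph.vertices:
        raise KeyError(f"unknown vertex {v!r}")
    return Graph(
        vertices=frozenset({v}) | net.graph.neighbors(v),
        edges=frozenset(),
        directed=net.directed,
    )


# --------------------------------------------------------------------------
# Conditions

_KIND_ARITY = {
    "empty-intersection": 2,
    "nonempty-intersection": 2,
    "empty-subtraction": 2,
    "nonempty-subtraction": 2,
    "all-singletons": 1,
    "single-component-union": 2,
    "touch-bound": 2,
    "coverage-all": 1,
}


@dataclass(frozen=True)
class Condition:
    """One necessary-and-sufficient condition on community profiles.

    ``kind`` selects the predicate; ``communities`` carries one or two
    community names.  Subtraction kinds are ordered:
    ``empty-subtraction(A, B)`` asserts ``T∘S(A, B) = {}``, i.e. A ⊆ B.
    ``coverage-all(B)`` asserts every vertex's ego community meets ``C(B)``.
    """

    kind: str
    communities: Tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in _KIND_ARITY:
            raise ValueError(f"unknown condition kind {self.kind!r}")
        object.__setattr__(self, "communities", tuple(self.communities))
        if len(self.communities) != _KIND_ARITY[self.kind]:
            raise ValueError(
                f"condition {self.kind!r} takes {_KIND_ARITY[self.kind]} "
                f"communit{'y' if _KIND_ARITY[self.kind] == 1 else 'ies'}, "
                f"got {len(self.communities)}"
            )

    def to_dict(self) -> dict:
        return {"kind": self.kind, "communities": list(self.communities)}

    @classmethod
    def from_dict(cls, data: dict) -> "Condition":
        return cls(kind=data["kind"], communities=tuple(data["communities"]))

    def __repr__(self) -> str:
        return f"{self.kind}({', '.join(self.communities)})"


@dataclass(frozen=True)
class ConditionSet:
    """A conjunction of conditions defining an intervention target."""

    conditions: FrozenSet[Condition]

    def __init__(self, conditions: Iterable[Condition]):
        object.__setattr__(self, "conditions", frozenset(conditions))

    def __iter__(self):
        return iter(sorted(self.conditions, key=lambda c: (c.kind, c.communities)))

    def __len__(self) -> int:
        return len(self.conditions)

    def to_dict(self) -> dict:
        return {"conditions": [c.to_dict() for c in self]}

    @classmethod
    def from_dict(cls, data: dict) -> "ConditionSet":
        return cls(Condition.from_dict(c) for c in data["conditions"])

    def __repr__(self) -> str:
        return "ConditionSet{" + ", ".join(repr(c) for c in self) + "}"


def evaluate(net: SocialNetwork, cond: Condition) -> bool:
    """Evaluate one condition on a network."""
    kind = cond.kind
    if kind == "all-singletons":
        (a,) = cond.communities
        return profile(community_subgraph(net, a)).all_singletons()
    if kind == "coverage-all":
        (b,) = cond.communities
        cb = community_subgraph(net, b)
        return all(
            len(profile(intersect(ego(net, v), cb))) >= 1
            for v in net.graph.sorted_vertices()
        )

    a, b = cond.communities
    if kind == "empty-intersection":
        return profile_relation(net, "I", a, b).is_empty
    if kind == "nonempty-intersection":
        return not profile_relation(net, "I", a, b).is_empty
    if kind == "empty-subtraction":
        return profile_relation(net, "S", a, b).is_empty
    if kind == "nonempty-subtraction":
        return not profile_relation(net, "S", a, b).is_empty
    if kind == "single-component-union":
        return len(profile_relation(net, "U", a, b)) == 1
    if kind == "touch-bound":
        t_a = profile(community_subgraph(net, a))
        t_b = profile(community_subgraph(net, b))
        t_u = profile(induced_union(net, a, b))
        return len(t_u) < len(t_a) + len(t_b)
    raise ValueError(f"unknown condition kind {kind!r}")  # pragma: no cover


def evaluate_all(net: SocialNetwork, conds: ConditionSet) -> Dict[Condition, bool]:
    return {c: evaluate(net, c) for c in conds}


# --------------------------------------------------------------------------
# Relationship classification

RELATIONSHIPS = (
    "disjoint",
    "A-in-B",
    "B-in-A",
    "equal",
    "partial-overlap",
    "touch",
)


def relationship_conditions(name: str, a: str, b: str) -> ConditionSet:
    """Expand a relationship name to its necessary-and-sufficient conditions."""
    if name == "disjoint":
        conds = [Condition("empty-intersection", (a, b))]
    elif name == "A-in-B":
        conds = [Condition("empty-subtraction", (a, b))]
    elif name == "B-in-A":
        conds = [Condition("empty-subtraction", (b, a))]
    elif name == "equal":
        conds = [
            Condition("empty-subtraction", (a, b)),
            Condition("empty-subtraction", (b, a)),
        ]
    elif name == "partial-overlap":
        conds = [
            Condition("nonempty-intersection", (a, b)),
            Condition("nonempty-subtraction", (a, b)),
            Condition("nonempty-subtraction", (b, a)),
        ]
    elif name == "touch":
        conds = [
            Condition("empty-intersection", (a, b)),
            Condition("touch-bound", (a, b)),
        ]
    else:
        raise ValueError(
            f"unknown relationship {name!r}; expected one of {RELATIONSHIPS}"
        )
    return ConditionSet(conds)


def classify(net: SocialNetwork, a: str, b: str) -> FrozenSet[str]:
    """Every relationship whose condition set holds between communities a, b.

    The relationship rows are not mutually exclusive — touch implies disjoint
    and equal implies both containments — so all satisfied names are returned.
    """
    satisfied: List[str] = []
    for name in RELATIONSHIPS:
        conds = relationship_conditions(name, a, b)
        if all(evaluate(net, c) for c in conds):
            satisfied.append(name)
    return frozenset(satisfied)


_PRECEDENCE = ("equal", "A-in-B", "B-in-A", "touch", "disjoint", "partial-overlap")


def most_specific(names: Iterable[str]) -> str | None:
    """Pick the most specific relationship: equal ≻ containment ≻ touch ≻ rest."""
    names = set(names)
    for name in _PRECEDENCE:
        if name in names:
            return name
    return None


# --------------------------------------------------------------------------
# Condition-set serialisation (YAML/JSON schema shared with the CLI)

def conditions_to_payload(conds: ConditionSet) -> dict:
    return conds.to_dict()


def conditions_from_payload(data: dict, a: str | None = None, b: str | None = None) -> ConditionSet:
    """Parse a condition-set payload.

    Accepts either an explicit ``{"conditions": [{kind, communities}, ...]}``
    mapping or a relationship-name shorthand ``{"relationship": name,
    "communities": [A, B]}`` that expands to its Table of conditions.
    """
    if "relationship" in data:
        comm = data.get("communities") or [a, b]
        if len(comm) != 2 or None in comm:
            raise ValueError("relationship shorthand requires two community names")
        return relationship_conditions(data["relationship"], comm[0], comm[1])
    return ConditionSet.from_dict(data)
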