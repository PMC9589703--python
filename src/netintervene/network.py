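"""Core data model: graphs and social networks with typed, overlapping communities.

A social network is a graph ``G = (V, E)`` together with a set of community
type names ``L`` and a crisp membership map assigning each vertex a (possibly
empty) subset of ``L``.  A community is realised as the vertex-induced
subgraph of its members, so community structure can never drift out of sync
with the underlying graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Mapping, Tuple

__all__ = ["Graph", "SocialNetwork", "community_subgraph"]

Vertex = str
Edge = Tuple[str, str]


def canonical_edge(u: Vertex, v: Vertex, directed: bool) -> Edge:
    """Canonical stored form of an edge: lex-smaller endpoint first when undirected."""
    if u == v:
        raise ValueError(f"self-loop ({u!r}, {v!r}) is not allowed")
    if directed or u < v:
        return (u, v)
    return (v, u)


@dataclass(frozen=True)
class Graph:
    """A simple graph: opaque string vertices, no self-loops, no multi-edges.

    Undirected edges are stored in one canonical orientation (lexicographically
    smaller endpoint first) so that graph equality is plain field equality.
    """

    vertices: FrozenSet[Vertex] = field(default_factory=frozenset)
    edges: FrozenSet[Edge] = field(default_factory=frozenset)
    directed: bool = False

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u not in self.vertices or v not in self.vertices:
                raise ValueError(f"edge ({u!r}, {v!r}) references an unknown vertex")
            if u == v:
                raise ValueError(f"self-loop on {u!r} is not allowed")
            if not self.directed and u > v:
                raise ValueError(f"undirected edge ({u!r}, {v!r}) is not in canonical order")

    @classmethod
    def build(
        cls,
        vertices: Iterable[Vertex] = (),
        edges: Iterable[Tuple[Vertex, Vertex]] = (),
        directed: bool = False,
    ) -> "Graph":
        """Build a graph, canonicalising edge orientation and collapsing duplicates."""
        vset = frozenset(str(v) for v in vertices)
        eset = frozenset(canonical_edge(str(u), str(v), directed) for u, v in edges)
        return cls(vertices=vset, edges=eset, directed=directed)

    @property
    def is_empty(self) -> bool:
        return not self.vertices

    def has_edge(self, u: Vertex, v: Vertex) -> bool:
        return canonical_edge(u, v, self.directed) in self.edges

    def neighbors(self, v: Vertex) -> FrozenSet[Vertex]:
        """Adjacent vertices of ``v``; out-neighbours when the graph is directed."""
        if v not in self.vertices:
            raise KeyError(f"unknown vertex {v!r}")
        if self.directed:
            return frozenset(b for a, b in self.edges if a == v)
        return frozenset(b if a == v else a for a, b in self.edges if v in (a, b))

    def sorted_vertices(self) -> Tuple[Vertex, ...]:
        return tuple(sorted(self.vertices))

    def sorted_edges(self) -> Tuple[Edge, ...]:
        return tuple(sorted(self.edges))


EMPTY_GRAPH = Graph()


class SocialNetwork:
    """A graph plus community types ``L`` and a crisp vertex→labels membership map.

    Every vertex has a membership entry (possibly the empty set: a vertex may
    belong to zero, one or several communities).  The per-community subgraph
    map ``C`` is derived, not stored — see :func:`community_subgraph`.
    """

    __slots__ = ("graph", "labels", "_membership")

    def __init__(
        self,
        graph: Graph,
        labels: Iterable[str],
        membership: Mapping[Vertex, Iterable[str]],
    ) -> None:
        self.graph = graph
        self.labels: FrozenSet[str] = frozenset(str(x) for x in labels)
        mem = {}
        for v in graph.vertices:
            vlabels = frozenset(str(x) for x in membership.get(v, ()))
            unknown = vlabels - self.labels
            if unknown:
                raise ValueError(
                    f"vertex {v!r} uses undeclared community label(s) {sorted(unknown)}"
                )
            mem[v] = vlabels
        extra = set(membership) - graph.vertices
        if extra:
            raise ValueError(f"membership given for unknown vertices {sorted(extra)}")
        self._membership = mem

    @classmethod
    def build(
        cls,
        vertices: Iterable[Vertex] = (),
        edges: Iterable[Tuple[Vertex, Vertex]] = (),
        membership: Mapping[Vertex, Iterable[str]] | None = None,
        labels: Iterable[str] | None = None,
        directed: bool = False,
    ) -> "SocialNetwork":
        """Convenience constructor; labels default to the union of memberships."""
        membership = dict(membership or {})
        vset = set(str(v) for v in vertices) | set(membership)
        graph = Graph.build(vset, edges, directed=directed)
        if labels is None:
            labels = set().union(*(set(ls) for ls in membership.values()), set())
        return cls(graph, labels, membership)

    @property
    def directed(self) -> bool:
        return self.graph.directed

    def membership(self, v: Vertex) -> FrozenSet[str]:
        try:
            return self._membership[v]
        except KeyError:
            raise KeyError(f"unknown vertex {v!r}") from None

    def membership_table(self) -> Mapping[Vertex, FrozenSet[str]]:
        return dict(self._membership)

    def members(self, label: str) -> FrozenSet[Vertex]:
        if label not in self.labels:
            raise KeyError(f"unknown community label {label!r}")
        return frozenset(v for v, ls in self._membership.items() if label in ls)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SocialNetwork):
            return NotImplemented
        return (
            self.graph == other.graph
            and self.labels == other.labels
            and self._membership == other._membership
        )

    def __hash__(self) -> int:
        return hash((self.graph, self.labels, frozenset(self._membership.items())))

    def __repr__(self) -> str:
        return (
            f"SocialNetwork(|V|={len(self.graph.vertices)}, "
            f"|E|={len(self.graph.edges)}, labels={sorted(self.labels)}, "
            f"directed={self.directed})"
        )


def community_subgraph(net: SocialNetwork, label: str) -> Graph:
    """The vertex-induced subgraph of a community (the map ``C``).

    Vertices are the members of ``label``; edges are exactly the edges of the
    network with both endpoints in the community.
    """
    members = net.members(label)  # raises on unknown label
    edges = frozenset(e for e in net.graph.edges if e[0] in members and e[1] in members)
    return Graph(vertices=members, edges=edges, directed=net.directed)
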