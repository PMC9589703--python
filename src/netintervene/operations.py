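"""Network edit operations and declarative feasibility policies.

Four primitive edits alter a social network: removing a vertex (``V⁻``),
adding or removing an edge (``E⁺``/``E⁻``) and reassigning a vertex's
community memberships (``CΔ``).  Which edits are *feasible* depends on the
application domain — e.g. undercover agents may only cut links between
agents — and is expressed as a :class:`FeasibilityPolicy` of per-variant
rules with membership guards.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, FrozenSet, Iterable, List, Optional, Sequence, Tuple, Union

import yaml

from .network import Graph, SocialNetwork, canonical_edge

__all__ = [
    "Operation",
    "RemoveVertex",
    "AddEdge",
    "RemoveEdge",
    "SetMembership",
    "OperationError",
    "apply",
    "apply_sequence",
    "FeasibilityPolicy",
    "PolicyRule",
    "is_feasible",
]


class OperationError(ValueError):
    """An operation whose preconditions do not hold on the given network."""


@dataclass(frozen=True)
class RemoveVertex:
    """``V⁻(v)``: delete a vertex, its membership entry and incident edges."""

    vertex: str

    variant = "V-"

    def vertices(self) -> Tuple[str, ...]:
        return (self.vertex,)

    def to_dict(self) -> dict:
        return {"op": "V-", "vertex": self.vertex}


@dataclass(frozen=True)
class AddEdge:
    """``E⁺(u, v)``: add an edge between two existing vertices."""

    u: str
    v: str

    variant = "E+"

    def __post_init__(self) -> None:
        if self.u == self.v:
            raise ValueError("edge endpoints must be distinct")

    def vertices(self) -> Tuple[str, ...]:
        return (self.u, self.v)

    @property
    def endpoints(self) -> FrozenSet[str]:
        return frozenset((self.u, self.v))

    def to_dict(self) -> dict:
        return {"op": "E+", "u": self.u, "v": self.v}


@dataclass(frozen=True)
class RemoveEdge:
    """``E⁻(u, v)``: remove an existing edge."""

    u: str
    v: str

    variant = "E-"

    def __post_init__(self) -> None:
        if self.u == self.v:
            raise ValueError("edge endpoints must be distinct")

    def vertices(self) -> Tuple[str, ...]:
        return (self.u, self.v)

    @property
    def endpoints(self) -> FrozenSet[str]:
        return frozenset((self.u, self.v))

    def to_dict(self) -> dict:
        return {"op": "E-", "u": self.u, "v": self.v}


@dataclass(frozen=True)
class SetMembership:
    """``CΔ(v, S)``: replace a vertex's community membership with ``S ⊆ L``."""

    vertex: str
    labels: FrozenSet[str]

    variant = "C^"

    def __init__(self, vertex: str, labels: Iterable[str]):
        object.__setattr__(self, "vertex", vertex)
        object.__setattr__(self, "labels", frozenset(labels))

    def vertices(self) -> Tuple[str, ...]:
        return (self.vertex,)

    def to_dict(self) -> dict:
        return {"op": "C^", "vertex": self.vertex, "labels": sorted(self.labels)}


Operation = Union[RemoveVertex, AddEdge, RemoveEdge, SetMembership]

_VARIANTS = {"V-": RemoveVertex, "E+": AddEdge, "E-": RemoveEdge, "C^": SetMembership}


def operation_from_dict(data: dict) -> Operation:
    op = data["op"]
    if op == "V-":
        return RemoveVertex(data["vertex"])
    if op == "E+":
        return AddEdge(data["u"], data["v"])
    if op == "E-":
        return RemoveEdge(data["u"], data["v"])
    if op == "C^":
        return SetMembership(data["vertex"], data["labels"])
    raise ValueError(f"unknown operation variant {op!r}")


# --------------------------------------------------------------------------
# Applying operations (pure: the input network value is never mutated)

def apply(net: SocialNetwork, op: Operation) -> SocialNetwork:
    """Apply one edit, returning a new network; the input is unchanged."""
    g = net.graph
    membership = dict(net.membership_table())

    if isinstance(op, RemoveVertex):
        if op.vertex not in g.vertices:
            raise OperationError(f"cannot remove absent vertex {op.vertex!r}")
        vertices = g.vertices - {op.vertex}
        edges = frozenset(e for e in g.edges if op.vertex not in e)
        del membership[op.vertex]
        new_graph = Graph(vertices=vertices, edges=edges, directed=g.directed)
        return SocialNetwork(new_graph, net.labels, membership)

    if isinstance(op, (AddEdge, RemoveEdge)):
        for w in (op.u, op.v):
            if w not in g.vertices:
                raise OperationError(f"edge operation references absent vertex {w!r}")
        e = canonical_edge(op.u, op.v, g.directed)
        if isinstance(op, AddEdge):
            if e in g.edges:
                raise OperationError(f"edge {e} already present")
            edges = g.edges | {e}
        else:
            if e not in g.edges:
                raise OperationError(f"cannot remove absent edge {e}")
            edges = g.edges - {e}
        new_graph = Graph(vertices=g.vertices, edges=edges, directed=g.directed)
        return SocialNetwork(new_graph, net.labels, membership)

    if isinstance(op, SetMembership):
        if op.vertex not in g.vertices:
            raise OperationError(f"cannot reassign absent vertex {op.vertex!r}")
        unknown = op.labels - net.labels
        if unknown:
            raise OperationError(
                f"membership uses undeclared label(s) {sorted(unknown)}"
            )
        membership[op.vertex] = op.labels
        return SocialNetwork(g, net.labels, membership)

    raise TypeError(f"not an operation: {op!r}")  # pragma: no cover


def apply_sequence(
    net: SocialNetwork, ops: Sequence[Operation]
) -> Tuple[SocialNetwork, List[dict]]:
    """Left-to-right fold of :func:`apply` with a per-step log.

    The log records, for each applied operation, the pre/post vertex and edge
    counts (JSON-lines friendly).  The first failing operation aborts with its
    index and reason; no partial result is returned.
    """
    current = net
    log: List[dict] = []
    for i, op in enumerate(ops):
        pre = (len(current.graph.vertices), len(current.graph.edges))
        try:
            current = apply(current, op)
        except OperationError as exc:
            raise OperationError(f"operation {i} ({op!r}) failed: {exc}") from exc
        log.append(
            {
                "index": i,
                "operation": op.to_dict(),
                "pre_vertices": pre[0],
                "pre_edges": pre[1],
                "post_vertices": len(current.graph.vertices),
                "post_edges": len(current.graph.edges),
            }
        )
    return current, log


def write_operation_log(log: List[dict], dest) -> None:
    with open(dest, "w", encoding="utf-8") as fh:
        for record in log:
            fh.write(json.dumps(record) + "\n")


# --------------------------------------------------------------------------
# Feasibility policies

Guard = Callable[[Operation, SocialNetwork], bool]


@dataclass(frozen=True)
class PolicyRule:
    """One feasibility rule: an operation-variant pattern plus a guard.

    Declarative guards restrict the memberships of the operation's own
    vertices: ``all_endpoints_in`` / ``any_endpoint_in`` name a community the
    endpoints must belong to.  ``realisation`` is a free-text note on how the
    edit maps to a real-world action; it is reporting-only.  A programmatic
    ``predicate`` may be supplied instead of a declarative guard (it is not
    serialisable).
    """

    variant: str
    all_endpoints_in: Optional[str] = None
    any_endpoint_in: Optional[str] = None
    realisation: Optional[str] = None
    predicate: Optional[Guard] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS and self.variant != "*":
            raise ValueError(f"unknown operation variant {self.variant!r}")

    def matches(self, op: Operation, net: SocialNetwork) -> bool:
        if self.variant != "*" and op.variant != self.variant:
            return False
        memberships = []
        for v in op.vertices():
            if v not in net.graph.vertices:
                return False
            memberships.append(net.membership(v))
        if self.all_endpoints_in is not None:
            if not all(self.all_endpoints_in in m for m in memberships):
                return False
        if self.any_endpoint_in is not None:
            if not any(self.any_endpoint_in in m for m in memberships):
                return False
        if self.predicate is not None and not self.predicate(op, net):
            return False
        return True

    def to_dict(self) -> dict:
        if self.predicate is not None:
            raise ValueError("programmatic guards are not serialisable")
        data: dict = {"op": self.variant}
        require = {}
        if self.all_endpoints_in is not None:
            require["all_endpoints_in"] = self.all_endpoints_in
        if self.any_endpoint_in is not None:
            require["any_endpoint_in"] = self.any_endpoint_in
        if require:
            data["require"] = require
        if self.realisation is not None:
            data["realisation"] = self.realisation
        return data

    @classmethod
    def from_dict(cls, data: dict) -> "PolicyRule":
        require = data.get("require", {})
        return cls(
            variant=data["op"],
            all_endpoints_in=require.get("all_endpoints_in"),
            any_endpoint_in=require.get("any_endpoint_in"),
            realisation=data.get("realisation"),
        )


@dataclass(frozen=True)
class FeasibilityPolicy:
    """A sequence of rules; an operation is feasible iff some rule matches.

    A policy with no rules permits nothing.
    """

    rules: Tuple[PolicyRule, ...] = ()

    def __init__(self, rules: Iterable[PolicyRule] = ()):
        object.__setattr__(self, "rules", tuple(rules))

    @classmethod
    def allow_all(cls) -> "FeasibilityPolicy":
        return cls([PolicyRule("*")])

    @classmethod
    def allow_variants(cls, *variants: str) -> "FeasibilityPolicy":
        return cls([PolicyRule(v) for v in variants])

    def permits_variant(self, variant: str) -> bool:
        """True iff some rule could ever match the variant (ignoring guards)."""
        return any(r.variant in ("*", variant) for r in self.rules)

    def to_yaml(self) -> str:
        return yaml.safe_dump({"rules": [r.to_dict() for r in self.rules]}, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "FeasibilityPolicy":
        data = yaml.safe_load(text) or {}
        return cls(PolicyRule.from_dict(r) for r in data.get("rules", []))


def is_feasible(policy: FeasibilityPolicy, op: Operation, net: SocialNetwork) -> bool:
    """True iff some policy rule's pattern matches ``op`` and its guard holds."""
    return any(rule.matches(op, net) for rule in policy.rules)
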