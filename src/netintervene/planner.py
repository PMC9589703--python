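"""Compile desired topological relationships into feasible operation sequences.

Each planner takes a network, the communities concerned and a feasibility
policy, and returns an :class:`InterventionPlan` — an ordered sequence of
edit operations together with the conjunction of necessary-and-sufficient
conditions the plan is meant to establish.  :func:`verify` replays a plan on
a copy of the network (running membership diffusion when the plan depends on
it) and checks every target condition, so a plan is never trusted, only
checked.

Five strategies are provided:

* ``plan_disjoint`` — make two communities disjoint, by vertex removal or by
  membership reassignment;
* ``plan_atomize`` — break a community into singletons (every intra-community
  edge removed), e.g. so covert agents cannot expose one another;
* ``plan_infiltrate`` — embed one (atomised, disjoint) community inside
  another, connecting every cross pair;
* ``plan_influence_containment`` — seed a small influential subset with a
  second membership and let directed assimilative influence carry it to the
  rest of the community;
* ``plan_coverage`` — guarantee every vertex a neighbour in (or membership
  of) a designated community, adding randomly targeted edges where absent.
"""

from __future__ import annotations

import json
import logging
import random
from dataclasses import dataclass, field
from itertools import product
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

from .diffusion import propagate
from .network import SocialNetwork, community_subgraph
from .operations import (
    AddEdge,
    FeasibilityPolicy,
    Operation,
    OperationError,
    RemoveEdge,
    RemoveVertex,
    SetMembership,
    apply_sequence,
    is_feasible,
    operation_from_dict,
)
from .topology import (
    Condition,
    ConditionSet,
    classify,
    evaluate,
    intersect,
    most_specific,
)

logger = logging.getLogger(__name__)

__all__ = [
    "InterventionPlan",
    "VerificationReport",
    "InfeasiblePlanError",
    "plan_disjoint",
    "plan_atomize",
    "plan_infiltrate",
    "plan_influence_containment",
    "plan_coverage",
    "verify",
    "plan",
]


class InfeasiblePlanError(RuntimeError):
    """The policy forbids an operation variant the strategy requires."""


@dataclass(frozen=True)
class InterventionPlan:
    """An ordered operation sequence targeting a condition set.

    ``diffusion`` records a (community, adopted-labels) dependency when the
    target is only reached after influence propagation — the plan's edits
    seed the process, propagation completes it.
    """

    ops: Tuple[Operation, ...]
    target: ConditionSet
    strategy: str
    seed: Optional[int] = None
    diffusion: Optional[Tuple[str, FrozenSet[str]]] = None

    def __len__(self) -> int:
        return len(self.ops)

    def to_dict(self) -> dict:
        data: dict = {
            "strategy": self.strategy,
            "ops": [op.to_dict() for op in self.ops],
            "target": self.target.to_dict(),
        }
        if self.seed is not None:
            data["seed"] = self.seed
        if self.diffusion is not None:
            within, adopt = self.diffusion
            data["diffusion"] = {"within": within, "adopt": sorted(adopt)}
        return data

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, data: dict) -> "InterventionPlan":
        diffusion = None
        if "diffusion" in data:
            diffusion = (
                data["diffusion"]["within"],
                frozenset(data["diffusion"]["adopt"]),
            )
        return cls(
            ops=tuple(operation_from_dict(o) for o in data["ops"]),
            target=ConditionSet.from_dict(data["target"]),
            strategy=data["strategy"],
            seed=data.get("seed"),
            diffusion=diffusion,
        )

    @classmethod
    def from_json(cls, text: str) -> "InterventionPlan":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class VerificationReport:
    """Outcome of replaying a plan and checking its target conditions."""

    satisfied: bool
    per_condition: Dict[Condition, bool]
    resulting_network_summary: dict
    failure: Optional[str] = None

    def __post_init__(self) -> None:
        if self.failure is None:
            assert self.satisfied == all(self.per_condition.values())


def _require_feasible(
    policy: FeasibilityPolicy, ops: Sequence[Operation], net: SocialNetwork
) -> None:
    for op in ops:
        if not is_feasible(policy, op, net):
            raise InfeasiblePlanError(
                f"policy forbids required operation variant {op.variant} ({op!r})"
            )


def plan_disjoint(
    net: SocialNetwork,
    a: str,
    b: str,
    strategy: str = "remove-vertex",
    policy: Optional[FeasibilityPolicy] = None,
) -> InterventionPlan:
    """Make communities ``a`` and ``b`` disjoint.

    ``remove-vertex`` deletes every shared vertex (``V⁻``); the
    ``reassign-membership`` alternative instead strips label ``b`` from each
    shared vertex (``CΔ``), leaving the graph untouched.
    """
    policy = policy or FeasibilityPolicy.allow_all()
    shared = intersect(community_subgraph(net, a), community_subgraph(net, b))
    ops: List[Operation]
    if strategy == "remove-vertex":
        ops = [RemoveVertex(v) for v in sorted(shared.vertices)]
    elif strategy == "reassign-membership":
        ops = [
            SetMembership(v, net.membership(v) - {b})
            for v in sorted(shared.vertices)
        ]
    else:
        raise ValueError(f"unknown disjoint strategy {strategy!r}")
    _require_feasible(policy, ops, net)
    target = ConditionSet([Condition("empty-intersection", (a, b))])
    return InterventionPlan(tuple(ops), target, strategy=f"disjoint/{strategy}")


def plan_atomize(
    net: SocialNetwork,
    a: str,
    b: str,
    policy: Optional[FeasibilityPolicy] = None,
) -> InterventionPlan:
    """Remove every intra-``a`` edge so all of ``a``'s components are singletons.

    Intended for a community already disjoint from ``b`` (the other community
    of the target): the resulting conditions assert both singleton structure
    and disjointness.
    """
    policy = policy or FeasibilityPolicy.allow_all()
    sub = community_subgraph(net, a)
    ops = [RemoveEdge(u, v) for u, v in sub.sorted_edges()]
    _require_feasible(policy, ops, net)
    target = ConditionSet(
        [
            Condition("all-singletons", (a,)),
            Condition("empty-intersection", (a, b)),
        ]
    )
    return InterventionPlan(tuple(ops), target, strategy="atomize")


def plan_infiltrate(
    net: SocialNetwork,
    a: str,
    b: str,
    policy: Optional[FeasibilityPolicy] = None,
) -> InterventionPlan:
    """Embed community ``a`` inside community ``b``.

    Memberships of ``a`` and ``b`` are snapshotted before any edit: each
    original ``a`` member additionally joins ``b`` (``CΔ``), then an edge is
    added between every original a×b pair not already connected (``E⁺``).
    Assumes ``a`` is atomised and disjoint from ``b`` initially; the target
    then asserts singleton structure, containment and a single union
    component.
    """
    policy = policy or FeasibilityPolicy.allow_all()
    a_members = sorted(net.members(a))
    b_members = sorted(net.members(b))
    ops: List[Operation] = [
        SetMembership(v, net.membership(v) | {b}) for v in a_members
    ]
    for v, w in product(a_members, b_members):
        if v != w and not net.graph.has_edge(v, w):
            ops.append(AddEdge(v, w))
    _require_feasible(policy, ops, net)
    target = ConditionSet(
        [
            Condition("all-singletons", (a,)),
            Condition("empty-subtraction", (a, b)),
            Condition("single-component-union", (a, b)),
        ]
    )
    return InterventionPlan(tuple(ops), target, strategy="infiltrate")


def _greedy_in_dominating_set(net: SocialNetwork, members: FrozenSet[str]) -> List[str]:
    """Greedy minimum in-dominating set of a community in a directed network.

    Every community member outside the returned set has an in-edge from the
    set.  A vertex covers itself plus its out-neighbours within the
    community; ties break lexicographically.
    """
    cover = {
        v: ({v} | set(net.graph.neighbors(v))) & members for v in members
    }
    uncovered = set(members)
    chosen: List[str] = []
    while uncovered:
        best = max(sorted(members), key=lambda v: len(cover[v] & uncovered))
        chosen.append(best)
        uncovered -= cover[best]
    return sorted(chosen)


def plan_influence_containment(
    net: SocialNetwork,
    a: str,
    b: str,
    policy: Optional[FeasibilityPolicy] = None,
) -> InterventionPlan:
    """Contain community ``a`` in ``b`` by seeding influential members.

    A "green" subset of ``a`` — a greedy in-dominating set, so every other
    member is directly influenced by it — gains membership of ``b``; directed
    assimilative influence then spreads the membership to the rest of ``a``.
    The plan records the diffusion dependency: its target holds only after
    propagation.
    """
    policy = policy or FeasibilityPolicy.allow_all()
    if not net.directed:
        raise ValueError("influence containment requires a directed network")
    members = net.members(a)
    green = _greedy_in_dominating_set(net, members) if members else []
    ops: List[Operation] = [
        SetMembership(v, net.membership(v) | {b}) for v in green
    ]
    _require_feasible(policy, ops, net)
    target = ConditionSet([Condition("empty-subtraction", (a, b))])
    return InterventionPlan(
        tuple(ops),
        target,
        strategy="influence-containment",
        diffusion=(a, frozenset({b})),
    )


def _is_covered(net: SocialNetwork, v: str, b_members: FrozenSet[str]) -> bool:
    # |T∘I(N(v), C(b))| >= 1: the ego community (edgeless) shares a vertex
    # with the covering community.
    return v in b_members or bool(net.graph.neighbors(v) & b_members)


def plan_coverage(
    net: SocialNetwork,
    a: str,
    b: str,
    seed: Optional[int] = None,
    policy: Optional[FeasibilityPolicy] = None,
) -> InterventionPlan:
    """Guarantee every vertex a connection to (or membership of) community ``b``.

    Every vertex whose ego community misses ``b`` — taken over all of V, in
    lexicographic order — gains an edge to a uniformly random ``b`` member,
    drawn with the stated seed.  The plan length (one edge per uncovered
    vertex) is seed-independent; the seed only picks the endpoints.
    """
    policy = policy or FeasibilityPolicy.allow_all()
    b_members = net.members(b)
    if not b_members:
        raise ValueError(f"covering community {b!r} is empty")
    a_members = net.members(a)
    rng = random.Random(seed)
    candidates = sorted(b_members)
    ops: List[Operation] = []
    for v in net.graph.sorted_vertices():
        if _is_covered(net, v, b_members):
            continue
        if v not in a_members:
            logger.info(
                "coverage: vertex %r is uncovered but outside community %r; "
                "covering it anyway (the condition quantifies over all vertices)",
                v,
                a,
            )
        ops.append(AddEdge(v, rng.choice(candidates)))
    _require_feasible(policy, ops, net)
    target = ConditionSet([Condition("coverage-all", (b,))])
    return InterventionPlan(tuple(ops), target, strategy="coverage", seed=seed)


# --------------------------------------------------------------------------
# Verification

def verify(net: SocialNetwork, intervention: InterventionPlan) -> VerificationReport:
    """Replay a plan and check every target condition on the result.

    The input network is untouched (operations are pure).  When the plan
    depends on diffusion, propagation runs after the edits, before the
    conditions are evaluated.
    """
    try:
        result, _log = apply_sequence(net, intervention.ops)
    except OperationError as exc:
        return VerificationReport(
            satisfied=False,
            per_condition={c: False for c in intervention.target},
            resulting_network_summary={},
            failure=str(exc),
        )
    if intervention.diffusion is not None:
        within, adopt = intervention.diffusion
        result = propagate(result, within, adopt).final

    per_condition = {c: evaluate(result, c) for c in intervention.target}
    summary: dict = {
        "vertices": len(result.graph.vertices),
        "edges": len(result.graph.edges),
    }
    pair = _relevant_pair(intervention.target)
    if pair is not None:
        names = classify(result, *pair)
        summary["pair"] = list(pair)
        summary["relationships"] = sorted(names)
        summary["most_specific"] = most_specific(names)
    return VerificationReport(
        satisfied=all(per_condition.values()),
        per_condition=per_condition,
        resulting_network_summary=summary,
    )


def _relevant_pair(target: ConditionSet) -> Optional[Tuple[str, str]]:
    for cond in target:
        if len(cond.communities) == 2:
            return cond.communities  # type: ignore[return-value]
    return None


# --------------------------------------------------------------------------
# Strategy dispatch

def _strategies_for(target_name: str):
    if target_name == "disjoint":
        return [
            ("remove-vertex", lambda net, a, b, seed, pol: plan_disjoint(net, a, b, "remove-vertex", pol)),
            ("reassign-membership", lambda net, a, b, seed, pol: plan_disjoint(net, a, b, "reassign-membership", pol)),
        ]
    if target_name in ("atomize", "disjoint-singletons"):
        return [("atomize", lambda net, a, b, seed, pol: plan_atomize(net, a, b, pol))]
    if target_name in ("infiltrate", "contained-singletons"):
        return [("infiltrate", lambda net, a, b, seed, pol: plan_infiltrate(net, a, b, pol))]
    if target_name in ("A-in-B", "containment", "influence-containment"):
        return [("influence-containment", lambda net, a, b, seed, pol: plan_influence_containment(net, a, b, pol))]
    if target_name == "coverage":
        return [("coverage", lambda net, a, b, seed, pol: plan_coverage(net, a, b, seed, pol))]
    raise ValueError(f"no strategy registered for target {target_name!r}")


_NAMED_TARGETS = (
    "disjoint",
    "atomize",
    "infiltrate",
    "A-in-B",
    "coverage",
)


def _target_name_for_conditions(conds: ConditionSet, a: str, b: str) -> Optional[str]:
    kinds = {c.kind for c in conds}
    if kinds == {"empty-intersection"}:
        return "disjoint"
    if kinds == {"all-singletons", "empty-intersection"}:
        return "atomize"
    if kinds == {"all-singletons", "empty-subtraction", "single-component-union"}:
        return "infiltrate"
    if kinds == {"empty-subtraction"}:
        return "A-in-B"
    if kinds == {"coverage-all"}:
        return "coverage"
    return None


def plan(
    net: SocialNetwork,
    target,
    a: str,
    b: str,
    policy: Optional[FeasibilityPolicy] = None,
    seed: Optional[int] = None,
) -> InterventionPlan:
    """Dispatch over the registered strategies for a target.

    ``target`` is a relationship/strategy name or a :class:`ConditionSet`.
    Feasible candidate plans are built in declared strategy order; the plan
    with the fewest operations wins, earliest declared strategy breaking
    ties.  Raises :class:`InfeasiblePlanError` naming every strategy tried
    when none is feasible.
    """
    policy = policy or FeasibilityPolicy.allow_all()
    if isinstance(target, ConditionSet):
        name = _target_name_for_conditions(target, a, b)
        if name is None:
            raise ValueError(f"no strategy can realise condition set {target!r}")
    else:
        name = str(target)
    candidates = _strategies_for(name)

    built: List[Tuple[int, int, InterventionPlan]] = []
    tried: List[str] = []
    for order, (label, builder) in enumerate(candidates):
        tried.append(label)
        try:
            built.append((order, label, builder(net, a, b, seed, policy)))
        except (InfeasiblePlanError, ValueError):
            continue
    if not built:
        raise InfeasiblePlanError(
            f"no feasible strategy for target {name!r}; tried {tried}"
        )
    built.sort(key=lambda t: (len(t[2].ops), t[0]))
    return built[0][2]
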