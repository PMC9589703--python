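"""Assimilative-influence propagation of community membership.

A directed edge (u, v) models assimilative social influence: u moves v
towards reducing their differences.  Here that is realised as membership
adoption — a vertex of the focal community adopts a label set once some
in-neighbour in the same community already carries it.  Adoption proceeds in
synchronous rounds to a fixpoint; memberships only grow, so at most |V|
rounds occur.  Influence is confined to the focal community: spillover to
other communities is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Iterable, List, Tuple

from .network import SocialNetwork
from .operations import SetMembership, apply

__all__ = ["DiffusionResult", "propagate"]


@dataclass(frozen=True)
class DiffusionResult:
    """Outcome of a propagation run.

    ``adopters_per_round[r]`` is the set of vertices that adopted in round
    ``r+1``; the sets are pairwise disjoint by monotonicity.
    """

    final: SocialNetwork
    rounds: int
    adopters_per_round: Tuple[FrozenSet[str], ...]


def propagate(
    net: SocialNetwork, within: str, adopt: Iterable[str]
) -> DiffusionResult:
    """Propagate adoption of ``adopt`` labels inside community ``within``.

    Each round, every member of ``within`` that has an in-neighbour in
    ``within`` already carrying all of ``adopt`` gains those labels; rounds
    repeat until no vertex changes.  Requires a directed network: influence
    has a source and a target.
    """
    if not net.directed:
        raise ValueError(
            "propagation requires a directed network; model influence edges "
            "as directed (source influences target)"
        )
    adopt = frozenset(adopt)
    unknown = adopt - net.labels
    if unknown:
        raise ValueError(f"adopt uses undeclared label(s) {sorted(unknown)}")
    if within not in net.labels:
        raise KeyError(f"unknown community label {within!r}")

    current = net
    adopters_per_round: List[FrozenSet[str]] = []
    rounds = 0
    while True:
        members = current.members(within)
        influenced = []
        for v in sorted(members):
            if adopt <= current.membership(v):
                continue
            has_source = any(
                u in members and adopt <= current.membership(u)
                for (u, w) in current.graph.edges
                if w == v
            )
            if has_source:
                influenced.append(v)
        if not influenced:
            break
        for v in influenced:
            current = apply(
                current, SetMembership(v, current.membership(v) | adopt)
            )
        adopters_per_round.append(frozenset(influenced))
        rounds += 1
    return DiffusionResult(
        final=current, rounds=rounds, adopters_per_round=tuple(adopters_per_round)
    )
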