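"""Worked-example fixtures and synthetic network generators.

The fixtures reproduce the small printed social networks that the calculus
and the planners are demonstrated on: a five-vertex two-community network
given in full, plus minimal reconstructions of the drawn figures pinned down
by every printed constraint (worked multiset values, listed operation
sequences, stated community memberships).  The generators plant a requested
topological relationship between two communities, or emulate a school
friendship network partitioned into frequent/infrequent drinkers in the
style of the Michell & Amos 50-student excerpt.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

from .network import SocialNetwork
from .operations import RemoveEdge, RemoveVertex, apply

__all__ = [
    "FIXTURE_NAMES",
    "fixture",
    "GeneratorConfig",
    "generate_with_relationship",
    "generate_school_like",
    "load_school_excerpt",
]

FIXTURE_NAMES = (
    "fig1a",
    "fig1b",
    "fig3a",
    "fig3b",
    "fig4",
    "fig5a",
    "fig5b",
    "fig7a",
)


def _fig1a() -> SocialNetwork:
    # The fully printed example: a five-vertex network whose blue community
    # {a,b,c} forms a triangle and whose red community {c,d,e} forms a path,
    # overlapping in the single vertex c.
    return SocialNetwork.build(
        vertices="abcde",
        edges=[("a", "b"), ("a", "c"), ("b", "c"), ("c", "d"), ("d", "e")],
        membership={"a": {"blue"}, "b": {"blue"}, "c": {"blue", "red"},
                    "d": {"red"}, "e": {"red"}},
    )


def _fig3a() -> SocialNetwork:
    # Two vertex-disjoint triangles joined by the single cross edge (c, d):
    # the communities are disjoint yet touching.  Reconstruction — only the
    # disjointness, the cross edge and the touch classification are printed.
    return SocialNetwork.build(
        vertices="abcdef",
        edges=[("a", "b"), ("a", "c"), ("b", "c"),
               ("d", "e"), ("d", "f"), ("e", "f"), ("c", "d")],
        membership={"a": {"blue"}, "b": {"blue"}, "c": {"blue"},
                    "d": {"red"}, "e": {"red"}, "f": {"red"}},
    )


def _fig3b() -> SocialNetwork:
    # The same graph as fig3a with different memberships: red is now a subset
    # of blue, so an identical graph carries a containment relationship —
    # the pair of figures exists to show that graph topology alone cannot
    # distinguish relationships.
    net = _fig3a()
    membership = {v: {"blue"} for v in "abc"}
    membership.update({v: {"blue", "red"} for v in "def"})
    return SocialNetwork.build(
        vertices=net.graph.vertices,
        edges=net.graph.edges,
        membership=membership,
    )


def _fig4() -> SocialNetwork:
    # Containment example with worked multisets.  Reconstruction pinned by:
    # I(blue, red) = ({a,b,e,d}, {(a,b)}) with profile {2,1,1};
    # T∘U = {3,1,1}; T∘S(blue,red) = {}; T∘S(red,blue) = {1}.
    # blue = {a,b,d,e} (induced edge (a,b)), red = blue ∪ {c} with edge (b,c)
    # forces all four values.
    return SocialNetwork.build(
        vertices="abcde",
        edges=[("a", "b"), ("b", "c")],
        membership={"a": {"blue", "red"}, "b": {"blue", "red"},
                    "c": {"red"}, "d": {"blue", "red"}, "e": {"blue", "red"}},
    )


def _fig5a() -> SocialNetwork:
    # Infiltration starting point: terrorists {a,b} (blue, connected) and
    # undercover agents {d,e} (red, joined by the edge (e,d)); the two
    # communities are vertex-disjoint with no cross links.
    return SocialNetwork.build(
        vertices="abde",
        edges=[("a", "b"), ("d", "e")],
        membership={"a": {"blue"}, "b": {"blue"}, "d": {"red"}, "e": {"red"}},
    )


def _fig7a() -> SocialNetwork:
    # Directed assimilative-influence network: the red community's member d
    # directly influences every other red vertex; blue is a separate
    # community.  Reconstruction pinned by the single printed seeding
    # operation on d and the containment reached after influence spreads.
    return SocialNetwork.build(
        vertices="abdef",
        edges=[("a", "b"), ("d", "e"), ("d", "f")],
        membership={"a": {"blue"}, "b": {"blue"},
                    "d": {"red"}, "e": {"red"}, "f": {"red"}},
        directed=True,
    )


def fixture(name: str) -> SocialNetwork:
    """Return a named worked-example network."""
    if name == "fig1a":
        return _fig1a()
    if name == "fig1b":
        return apply(_fig1a(), RemoveVertex("c"))
    if name == "fig3a":
        return _fig3a()
    if name == "fig3b":
        return _fig3b()
    if name == "fig4":
        return _fig4()
    if name == "fig5a":
        return _fig5a()
    if name == "fig5b":
        return apply(_fig5a(), RemoveEdge("d", "e"))
    if name == "fig7a":
        return _fig7a()
    raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")


# --------------------------------------------------------------------------
# Planted-relationship generator

@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration for planting a topological relationship.

    ``sizes`` are the two communities' member counts (for overlapping
    relationships the first size includes the shared part);
    ``extra_vertices`` lie outside both communities; ``edge_density`` is the
    Bernoulli probability for each permitted vertex pair.
    """

    relationship: str
    sizes: Tuple[int, int] = (4, 4)
    extra_vertices: int = 2
    edge_density: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.edge_density <= 1.0):
            raise ValueError("edge_density must lie in [0, 1]")
        na, nb = self.sizes
        minima = {
            "disjoint": (1, 1),
            "touch": (1, 1),
            "A-in-B": (1, 2),
            "B-in-A": (2, 1),
            "equal": (1, 1),
            "partial-overlap": (2, 2),
        }
        if self.relationship not in minima:
            raise ValueError(f"unknown relationship {self.relationship!r}")
        mina, minb = minima[self.relationship]
        if na < mina or nb < minb:
            raise ValueError(
                f"sizes {self.sizes} too small for {self.relationship!r} "
                f"(need at least {(mina, minb)})"
            )
        if self.relationship == "equal" and na != nb:
            raise ValueError("'equal' requires identical community sizes")
        if self.relationship == "A-in-B" and na >= nb:
            raise ValueError("'A-in-B' requires the first community strictly smaller")
        if self.relationship == "B-in-A" and nb >= na:
            raise ValueError("'B-in-A' requires the second community strictly smaller")


def generate_with_relationship(cfg: GeneratorConfig) -> SocialNetwork:
    """Generate a network whose communities A, B satisfy exactly the requested
    relationship (it is the most specific satisfied Table row); deterministic
    given the seed.
    """
    rng = random.Random(cfg.seed)
    na, nb = cfg.sizes
    rel = cfg.relationship

    # Decide member sets.  Shared vertices are drawn from a common pool.
    if rel in ("disjoint", "touch"):
        shared = 0
    elif rel == "equal":
        shared = na
    elif rel == "A-in-B":
        shared = na
    elif rel == "B-in-A":
        shared = nb
    else:  # partial-overlap
        shared = 1 + rng.randrange(min(na, nb) - 1)

    n_total = na + nb - shared + cfg.extra_vertices
    names = [f"v{i:03d}" for i in range(n_total)]
    shared_vs = names[:shared]
    a_only = names[shared: shared + (na - shared)]
    b_only = names[shared + (na - shared): na + nb - shared]
    extras = names[na + nb - shared:]
    a_members = set(shared_vs) | set(a_only)
    b_members = set(shared_vs) | set(b_only)

    membership = {}
    for v in names:
        labels = set()
        if v in a_members:
            labels.add("A")
        if v in b_members:
            labels.add("B")
        membership[v] = labels

    cross_forbidden = rel == "disjoint"
    edges = set()
    for u, v in itertools.combinations(names, 2):
        is_cross = (u in a_members and v in b_members) or (
            u in b_members and v in a_members
        )
        if cross_forbidden and is_cross:
            continue
        if rng.random() < cfg.edge_density:
            edges.add((u, v))

    if rel == "touch" and a_only and b_only:
        wanted = (rng.choice(sorted(a_only)), rng.choice(sorted(b_only)))
        edges.add(tuple(sorted(wanted)))

    return SocialNetwork.build(
        vertices=names, edges=edges, membership=membership, labels={"A", "B"}
    )


# --------------------------------------------------------------------------
# School friendship network emulator

def generate_school_like(
    n: int = 50,
    frac_frequent: float = 0.4,
    mean_degree: float = 3.0,
    homophily: float = 0.7,
    seed: int = 0,
) -> SocialNetwork:
    """A school friendship network partitioned into drinker communities.

    Emulates a cohort of students whose undirected friendship ties are
    sparser across the frequent/infrequent drinker boundary than within it.
    Every vertex belongs to exactly one of the two communities; the expected
    degree is approximately ``mean_degree``, and ``homophily`` in [0, 1]
    weights same-community pairs (1 means no cross-community friendships).
    The defaults mirror the published 50-student excerpt's scale: fifty
    students, a minority of frequent drinkers, sparse ties.
    """
    if not (0.0 <= frac_frequent <= 1.0):
        raise ValueError("frac_frequent must lie in [0, 1]")
    if not (0.0 <= homophily <= 1.0):
        raise ValueError("homophily must lie in [0, 1]")
    rng = random.Random(seed)
    names = [f"s{i:03d}" for i in range(n)]
    n_freq = round(n * frac_frequent)
    frequent = set(rng.sample(names, n_freq))
    membership = {
        v: {"frequent"} if v in frequent else {"infrequent"} for v in names
    }

    same_pairs = cross_pairs = 0
    for u, v in itertools.combinations(names, 2):
        if (u in frequent) == (v in frequent):
            same_pairs += 1
        else:
            cross_pairs += 1
    target_edges = n * mean_degree / 2.0
    denom = homophily * same_pairs + (1.0 - homophily) * cross_pairs
    scale = target_edges / denom if denom else 0.0
    p_same = min(1.0, homophily * scale)
    p_cross = min(1.0, (1.0 - homophily) * scale)

    edges = set()
    for u, v in itertools.combinations(names, 2):
        p = p_same if (u in frequent) == (v in frequent) else p_cross
        if rng.random() < p:
            edges.add((u, v))
    return SocialNetwork.build(
        vertices=names,
        edges=edges,
        membership=membership,
        labels={"frequent", "infrequent"},
    )


def load_school_excerpt(
    adjacency_path, attribute_path, wave: int = 1, frequent_threshold: int = 4
) -> SocialNetwork:
    """Load the published 50-student friendship excerpt, if downloaded.

    ``adjacency_path`` is a whitespace-separated 0/1 adjacency matrix (one
    wave); ``attribute_path`` a per-student table of alcohol-use codes, one
    column per wave (1 = never … 5 = more than once a week).  Students with a
    code of ``frequent_threshold`` or above (once a week or more) at column
    ``wave`` form the 'frequent' community; all others 'infrequent'.
    Friendship ties are symmetrised to an undirected graph.  No bundled data:
    this is an optional loader for the externally published files.
    """
    rows = [
        line.split()
        for line in Path(adjacency_path).read_text().splitlines()
        if line.strip()
    ]
    n = len(rows)
    names = [f"s{i + 1:02d}" for i in range(n)]
    edges = set()
    for i, row in enumerate(rows):
        if len(row) != n:
            raise ValueError(f"adjacency row {i + 1} has {len(row)} fields, expected {n}")
        for j, cell in enumerate(row):
            if i != j and float(cell) > 0:
                edges.add(tuple(sorted((names[i], names[j]))))
    attr_rows = [
        line.split()
        for line in Path(attribute_path).read_text().splitlines()
        if line.strip() and not line.lower().startswith("alcohol")
    ]
    if len(attr_rows) != n:
        raise ValueError(
            f"attribute table has {len(attr_rows)} rows, adjacency has {n}"
        )
    membership = {}
    for name, row in zip(names, attr_rows):
        code = float(row[wave])
        membership[name] = (
            {"frequent"} if code >= frequent_threshold else {"infrequent"}
        )
    return SocialNetwork.build(
        vertices=names,
        edges=edges,
        membership=membership,
        labels={"frequent", "infrequent"},
    )
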