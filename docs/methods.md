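# Methods

## The relationship calculus

A social network is a simple graph `G = (V, E)` — undirected for
friendship/information ties, directed for influence — together with a set
of community types `L` and a crisp membership map `V → 2^L`. A vertex may
belong to zero, one or several communities. A community is *realised* as
the vertex-induced subgraph of its members; it is never stored, so no edit
can ever leave a community's edge set inconsistent with the graph.

Two communities are compared through three graph-valued binary relations:

* `I(g, g')` — intersection of vertex and edge sets;
* `U(g, g')` — union of vertex and edge sets;
* `S(g, g')` — subtraction; removing a vertex removes its incident edges,
  so the surviving edge set is additionally restricted to surviving
  endpoint pairs.

The component-profile map `T` sends a graph to the multiset of its
connected-component vertex counts, stored canonically as a non-increasing
tuple (hashable, order-free, multiset equality). Directed graphs use weak
connectivity: an influence edge connects its endpoints regardless of
orientation, which is what containment reasoning over influence networks
needs. `T∘I` and `T∘U` are symmetric in their arguments; `T∘S` is not.

Qualitative relationships (disjoint, containment each way, equal, partial
overlap, touch) are defined by necessary-and-sufficient conditions on these
multisets; `classify` returns *every* satisfied relationship, because the
rows are not mutually exclusive (touch implies disjoint; equal implies both
containments). `most_specific` applies the precedence
equal ≻ containment ≻ touch ≻ {disjoint, partial overlap}.

### The touch bound and the induced union

Touch is "no shared vertex, but at least one connecting edge", detected by
`T∘I(A,B) = {}` together with `|T∘U(A,B)| < |T(A)| + |T(B)|`. Taken
literally over the two induced community subgraphs the bound is vacuous: a
plain union of the subgraphs cannot contain an edge *between* the
communities, because such an edge has one endpoint outside each member set.
The bound is therefore evaluated on the subgraph of the **network** induced
by `V(A) ∪ V(B)` (`induced_union`), which retains cross edges and is the
only reading under which the bound is equivalent to the definition. The
equivalence is machine-checked against a brute-force oracle (shared-vertex
test plus cross-edge scan) on 1000 random networks of up to 12 vertices.
`union_graphs` and `profile_relation(..., "U", ...)` keep the literal plain
union; the two views agree whenever the communities overlap.

### Ego communities

The ego community `N(v)` is `{v} ∪ neighbours(v)` with a deliberately
empty edge set (out-neighbours when directed). Because it is edgeless,
`|T∘I(N(v), C(B))|` simply counts vertices shared with the community `B` —
membership of `v` itself included. The coverage condition
(`coverage-all(B)`) asserts this count is ≥ 1 for **every** vertex of the
network.

### Known typographical discrepancies in the source material

The worked description of the five-vertex example prints the intersection
of its communities as `({a}, {})` although the stated memberships give
`{a,b,c} ∩ {c,d,e} = {c}`, and prints the post-removal subtraction as the
empty graph although the blue community `{a,b}` survives intact. Both are
treated as typos: the implementation follows the definitions, and the unit
tests assert the derived values (`({c}, {})` and `({a,b}, {(a,b)})`).
Similarly the prose once attributes disjointness to removing vertex `a`
where every other occurrence (and the worked plan) removes the shared
vertex `c`.

## Operations and feasibility

Edits are pure: `apply` returns a new network and never mutates its input,
so verification and what-if analysis need no defensive copying.
`RemoveVertex` deletes the vertex, its membership entry and incident edges;
`AddEdge` on a present edge and `RemoveEdge` on an absent one are errors at
this layer (planners are responsible for check-and-skip), keeping every
application auditable. `apply_sequence` folds left-to-right, emits a
JSON-lines-friendly log of pre/post counts, and aborts on the first failure
with its index.

A `FeasibilityPolicy` is an ordered list of rules, each an operation-variant
pattern plus a membership guard over the operation's own vertices
(`all_endpoints_in` / `any_endpoint_in`); an operation is feasible iff some
rule matches, and an empty policy permits nothing. Guards are deliberately
this narrow — every domain constraint used by the planners is of this form
(e.g. "edge removal only between agents") — and hence YAML-serialisable;
arbitrary predicates are accepted programmatically but not serialised. How
an edit maps to a real-world action (detainment, device confiscation) is
out of computational scope; rules carry a free-text `realisation` note for
reporting only.

## Planners and their guarantees

Every planner emits operations in lexicographic vertex/edge order, checks
each against the policy on the *planning-time* network (raising
`InfeasiblePlanError` naming the variant otherwise), and packages the
operations with the target condition set. Guarantees, each machine-checked
on 1000 random networks with planted preconditions:

* **disjoint** — remove every vertex of `I(A,B)` (or strip membership of
  `B` from it). Plan length = `|V(I(A,B))|`. Post: `T∘I(A,B) = {}`.
* **atomize** — remove every intra-community edge. Plan length = intra-edge
  count. Post (given initial disjointness): all components singletons,
  communities disjoint.
* **infiltrate** — with memberships of `A` and `B` snapshotted *before any
  edit*, add `B`'s label to every `A` member, then add every absent `A×B`
  edge. The snapshot matters: after the membership step `A ⊆ B`, and a
  naive pair loop would add `A`–`A` edges, contradicting both the intended
  semantics and the worked six-operation example. Post (given the atomized
  disjoint precondition): `A`'s components singletons, `T∘S(A,B) = {}`,
  `|T∘U(A,B)| = 1`. Already-present edges are skipped, never duplicated;
  self-edges are never emitted.
* **influence containment** — directed networks only. "Highly influential
  members" is operationalised as a greedy minimum in-dominating set of the
  community (every non-seed member has an in-edge from a seed), matching
  the guarantee's stated assumption that seeds directly connect to all other
  members; the greedy selector picks the vertex covering the most uncovered
  members, ties lexicographic. Seeds gain the second membership; the plan
  records a diffusion dependency, and its target (`T∘S(A,B) = {}`) holds
  only after propagation.
* **coverage** — every vertex failing the ego condition, scanned over
  **all** of `V` in lexicographic order, gains one edge to a uniformly
  random member of the covering community (seeded RNG; the seed is recorded
  in the plan). The loop over all vertices equals a loop over the
  uncovered community whenever the two communities partition `V`; when
  they do not, out-of-community repairs are logged at INFO level. Plan
  length — one edge per initially uncovered vertex — is seed-independent.
  An uncovered vertex can have no existing edge into the community, so the
  random choice never duplicates an edge.

`verify` replays the plan on a copy, runs diffusion when the plan depends
on it, evaluates every target condition, and reports per-condition truth
plus a summary classifying the relevant community pair. A failing operation
yields `satisfied = False` with the failure recorded, not an exception.

The `plan` dispatcher builds every feasible registered strategy for the
requested target and returns the one with the fewest operations, earliest
declared strategy breaking ties — so a policy permitting only membership
changes automatically selects reassignment over removal. Networks are
assumed static between planning and application; re-planning after external
change is the caller's responsibility. No cost model or minimum-cost search
is attempted, and success probabilities are out of scope.

## Diffusion

Assimilative influence (a directed edge's source moves its target toward
reducing differences) is modelled as monotone membership adoption:
synchronous rounds in which every member of the focal community with an
in-neighbour — in the same community — already carrying the adopted labels
gains them; repeat to fixpoint. Memberships only grow, so the process
terminates within `|V|` rounds; adopter sets per round are pairwise
disjoint; propagation is idempotent. Under the dominating-seed assumption
it terminates in exactly one round. The source material specifies no
dynamics beyond "through influence", so this simplest monotone fixpoint
consistent with the containment guarantee is a documented modelling choice;
in particular influence is confined to the focal community (no
cross-community spillover), and whether influence may flow through
not-yet-adopting intermediaries is resolved by the fixpoint (it may, one
round later). Continuous opinion dynamics, thresholds and probabilistic
adoption are out of scope.

## Synthetic data

**Fixtures.** The five-vertex two-community network is printed in full and
reproduced exactly, as is its image under removing the shared vertex. The
other figures are drawings without printed vertex/edge lists; their
fixtures are *minimal reconstructions* pinned by every printed constraint,
with the derivation in each fixture's docstring. E.g. the containment
example is forced by its four worked multisets (`T∘I = {2,1,1}`,
`T∘U = {3,1,1}`, `T∘S(blue,red) = {}`, `T∘S(red,blue) = {1}`) to be
`blue = {a,b,d,e}` with induced edge `(a,b)` and `red = blue ∪ {c}` with
edge `(b,c)`; the infiltration fixture needs agents `{d,e}` joined by one
edge, terrorists `{a,b}`, no cross ties; the influence fixture is directed
with one hub dominating its community. Fixtures claim consistency with the
printed constraints, not pictorial identity.

**Planted relationships.** `generate_with_relationship` draws member sets
realising the requested relationship (shared/exclusive counts per its
minimum requirements), then Bernoulli edges at `edge_density` (default 0.3)
over all permitted pairs — cross-community edges are forbidden for
*disjoint* and one is forced for *touch*, since those are the only
relationships the graph structure (as opposed to memberships) decides.
Deterministic given the seed. The generated relationship is exact by
construction, so the generator→classifier round trip is a genuine test of
the classifier, not of the generator's luck.

**School-like networks.** `generate_school_like` emulates a school
friendship network partitioned into frequent/infrequent drinkers at the
scale of the published 50-student excerpt: `n = 50` students,
`frac_frequent = 0.4` (a minority of frequent drinkers, matching the
excerpt's roughly 40/60 split), sparse ties (`mean_degree = 3`, typical of
reported adolescent friendship nominations), and homophily 0.7 (same-group
pairs weighted 0.7 : 0.3, reflecting the strong drinking-behaviour
homophily the cohort literature reports). Pair probabilities are scaled so
the expected total degree matches `mean_degree`; homophily 1 produces no
cross-community ties. The generator does **not** reproduce the real
excerpt's degree distribution, transitivity or longitudinal structure — a
green coverage test on it establishes the planner's guarantee (one added
edge per initially unsupported student, verified coverage), not the
real-data count of six added edges, which requires the downloadable
excerpt. `load_school_excerpt` reads the published adjacency/attribute
layout (0/1 matrix plus per-wave alcohol codes, "frequent" = drinking once
a week or more) for users who have fetched it; no bundled data and no test
depends on it.

## Numerical and degenerate-input choices

* Vertex identifiers are opaque strings; all iteration is lexicographic,
  so every deterministic operation is reproducible bit-for-bit.
* Undirected edges are stored with the lexicographically smaller endpoint
  first; duplicate edges collapse on read with a warning.
* Empty communities evaluate per the formulas — an empty community is
  vacuously all-singletons, contained in anything, and disjoint from
  everything; no special-casing.
* All randomness (coverage targeting, generators) flows through one
  explicit integer seed; coverage plans record theirs.
* Plan application is all-or-nothing: a failing operation aborts with its
  index; `verify` reports it rather than raising.

## Limitations

* Community detection is out of scope — memberships are given.
* Crisp membership only; no weights, no temporal edges, no multigraphs.
* Component profiles are the only topological descriptor; richer invariants
  (cycles, persistent homology) are not modelled.
* Plans are not cost-optimal and carry no success probabilities; the
  infiltration planner adds *all* cross pairs even when a sparser edge set
  would satisfy the single-component condition, because sparser
  implementations have no stated guarantee.
* The static-network assumption: concurrent external changes invalidate a
  plan, and no re-planning is triggered automatically.
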