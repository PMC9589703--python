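# netintervene

Plan and verify **social-network interventions** defined as **topological
relationships between communities**.

A social network intervention deliberately alters a network — detaining an
individual, severing or brokering a tie, changing someone's group
affiliation — to reach an objective: breaking the overlap between a
terrorist group and a weapons-skills community, embedding undercover agents,
guaranteeing every student a non-drinking friend. `netintervene` lets you
state such objectives *qualitatively*, as a desired relationship between two
communities (disjoint, containment, equal, partial overlap, touch), and
compiles them into concrete, policy-feasible edit sequences whose effect is
then machine-verified.

## The model

A social network is a graph `G = (V, E)` plus community types `L` and a
crisp membership map; each community is the vertex-induced subgraph `C(ℓ)`
of its members. Two communities `A`, `B` are compared through graph-valued
binary relations — intersection `I`, union `U`, subtraction `S` — composed
with the component-profile map

```
T : 𝒢 → 𝒵,   T(g) = { |V'| : (V', E') a connected component of g }
```

which sends a graph to the multiset of its connected-component sizes.
Relationships are characterised by necessary-and-sufficient conditions on
these multisets:

| relationship      | conditions                                              |
|-------------------|---------------------------------------------------------|
| A, B disjoint     | `T∘I(A,B) = {}`                                         |
| A contained in B  | `T∘S(A,B) = {}`                                         |
| B contained in A  | `T∘S(B,A) = {}`                                         |
| A, B equal        | both subtractions empty                                 |
| partial overlap   | `T∘I ≠ {}`, `T∘S(A,B) ≠ {}`, `T∘S(B,A) ≠ {}`            |
| A, B touch        | `T∘I(A,B) = {}` and `|T∘U(A,B)| < |T(A)| + |T(B)|`      |

Four edit operations realise interventions — `V⁻` (remove vertex), `E⁺` /
`E⁻` (add / remove edge), `CΔ` (reassign memberships) — filtered by a
domain-specific *feasibility policy* (e.g. "edges may only be removed
between agents"). Five planners compile targets into operation sequences:
disjointness (by removal or reassignment), atomisation, infiltration,
influence-seeded containment (with assimilative-influence diffusion on
directed networks), and ego-network coverage. Every plan carries its target
conditions, and `verify` replays it and checks them.

## Worked example

The bundled five-vertex network has a blue community `{a,b,c}` (a triangle)
and a red community `{c,d,e}` (a path) sharing the vertex `c`:

```python
import netintervene as ni

net = ni.fixture("fig1a")
print("relationships:", sorted(ni.classify(net, "blue", "red")))
print("T∘I(blue, red) =", ni.profile_relation(net, "I", "blue", "red"))

plan = ni.plan(net, "disjoint", "blue", "red")
print("strategy:", plan.strategy)
print("operations:", [op.to_dict() for op in plan.ops])

report = ni.verify(net, plan)
print("satisfied:", report.satisfied)
print("after:", report.resulting_network_summary)
```

prints

```
relationships: ['partial-overlap']
T∘I(blue, red) = {1}
strategy: disjoint/remove-vertex
operations: [{'op': 'V-', 'vertex': 'c'}]
satisfied: True
after: {'vertices': 4, 'edges': 2, 'pair': ['blue', 'red'], 'relationships': ['disjoint'], 'most_specific': 'disjoint'}
```

Read: the communities partially overlap — their intersection has one
singleton component (`{1}`). The planner's cheapest feasible implementation
of the *disjoint* target is the single operation `V⁻(c)`; replaying it
leaves a 4-vertex, 2-edge network in which the communities are disjoint, so
the intervention's necessary-and-sufficient condition is satisfied. Under a
policy permitting only membership changes (`CΔ`), the same target compiles
instead to `CΔ(c, {'blue'})` — removing `c` from the red community rather
than from the network.

The same API drives the other scenarios: `plan_atomize` /
`plan_infiltrate` for covert infiltration, `plan_influence_containment` +
`propagate` for influence-seeded containment on directed networks, and
`plan_coverage` to guarantee every vertex a neighbour in a designated
community (e.g. reducing network support for drinking in a school
friendship network).

## Command line

```sh
netintervene fixture fig1a -o net/
netintervene classify net/ blue red
netintervene plan net/ --target disjoint --communities blue red -o plan.json
netintervene apply net/ plan.json -o out/
netintervene verify net/ plan.json
netintervene generate --school --n 50 --seed 1 -o school/
```

Networks on disk are an edge list plus a `vertex,labels` membership CSV
(GraphML and JSON are also supported); plans are JSON; policies are YAML.

## Acceptance script

`scripts/acceptance.py` rebuilds the package's worked-example inputs and
recomputes the reported quantity from scratch — the maximum
connected-component size in the component profile of the two communities'
intersection in the containment example — writing the result as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Documentation

See `docs/methods.md` for the full account of the calculus, the planners'
guarantees and assumptions, the synthetic generators, and known
limitations.
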