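"""Planners: worked-example plans, verification, dispatch, feasibility."""

import random

import pytest

from netintervene import (
    AddEdge,
    Condition,
    FeasibilityPolicy,
    InfeasiblePlanError,
    InterventionPlan,
    PolicyRule,
    RemoveEdge,
    RemoveVertex,
    SetMembership,
    SocialNetwork,
    apply_sequence,
    community_subgraph,
    evaluate,
    fixture,
    intersect,
    plan,
    plan_atomize,
    plan_coverage,
    plan_disjoint,
    plan_infiltrate,
    plan_influence_containment,
    relationship_conditions,
    verify,
)

from conftest import random_disjoint_communities, random_social_network


class TestPlanDisjoint:
    def test_single_vertex_removal_on_printed_network(self, fig1a, fig1b):
        p = plan_disjoint(fig1a, "blue", "red", strategy="remove-vertex")
        assert p.ops == (RemoveVertex("c"),)
        out, _ = apply_sequence(fig1a, p.ops)
        assert out == fig1b
        assert verify(fig1a, p).satisfied

    def test_reassignment_alternative_on_printed_network(self, fig1a):
        p = plan_disjoint(fig1a, "blue", "red", strategy="reassign-membership")
        assert p.ops == (SetMembership("c", {"blue"}),)
        assert verify(fig1a, p).satisfied

    def test_already_disjoint_gives_empty_plan(self, fig5a):
        p = plan_disjoint(fig5a, "blue", "red")
        assert len(p) == 0
        assert verify(fig5a, p).satisfied

    def test_plan_length_equals_intersection_size(self):
        for seed in range(30):
            net = random_social_network(random.Random(seed), max_vertices=15)
            p = plan_disjoint(net, "blue", "red")
            shared = intersect(community_subgraph(net, "blue"),
                               community_subgraph(net, "red"))
            assert len(p) == len(shared.vertices)

    def test_infeasible_variant_names_it(self, fig1a):
        no_removals = FeasibilityPolicy([PolicyRule("E+")])
        with pytest.raises(InfeasiblePlanError, match="V-"):
            plan_disjoint(fig1a, "blue", "red", policy=no_removals)


class TestPlanAtomize:
    def test_single_edge_removal_on_printed_network(self, fig5a, fig5b):
        p = plan_atomize(fig5a, "red", "blue")
        assert len(p.ops) == 1
        (op,) = p.ops
        assert isinstance(op, RemoveEdge) and op.endpoints == {"d", "e"}
        out, _ = apply_sequence(fig5a, p.ops)
        assert out == fig5b
        assert verify(fig5a, p).satisfied

    def test_singleton_community_needs_no_ops(self):
        net = SocialNetwork.build(vertices="ax", membership={"a": {"red"}, "x": {"blue"}},
                                  labels={"blue", "red"})
        assert len(plan_atomize(net, "red", "blue")) == 0

    def test_triangle_community_needs_three_removals(self):
        net = SocialNetwork.build(
            vertices="xyzq", edges=[("x", "y"), ("x", "z"), ("y", "z")],
            membership={"x": {"red"}, "y": {"red"}, "z": {"red"}, "q": {"blue"}},
            labels={"blue", "red"})
        p = plan_atomize(net, "red", "blue")
        assert len(p) == 3
        assert verify(net, p).satisfied

    def test_plan_length_equals_intra_community_edge_count(self):
        for seed in range(30):
            net = random_disjoint_communities(random.Random(seed))
            p = plan_atomize(net, "red", "blue")
            assert len(p) == len(community_subgraph(net, "red").edges)


class TestPlanInfiltrate:
    def test_six_printed_operations(self, fig5b):
        p = plan_infiltrate(fig5b, "red", "blue")
        memberships = [op for op in p.ops if isinstance(op, SetMembership)]
        additions = [op for op in p.ops if isinstance(op, AddEdge)]
        assert {op.vertex for op in memberships} == {"d", "e"}
        assert all(op.labels == {"blue", "red"} for op in memberships)
        assert {frozenset((op.u, op.v)) for op in additions} == {
            frozenset("da"), frozenset("db"), frozenset("ea"), frozenset("eb")}
        assert len(p) == 6
        # memberships are snapshotted before editing: no red-red edges added
        assert not any({op.u, op.v} == {"d", "e"} for op in additions)

    def test_verify_confirms_all_three_target_conditions(self, fig5b):
        p = plan_infiltrate(fig5b, "red", "blue")
        report = verify(fig5b, p)
        assert report.satisfied
        assert set(report.per_condition) == {
            Condition("all-singletons", ("red",)),
            Condition("empty-subtraction", ("red", "blue")),
            Condition("single-component-union", ("red", "blue")),
        }

    def test_empty_community_gives_empty_plan(self):
        net = SocialNetwork.build(vertices="ab", edges=[("a", "b")],
                                  membership={"a": {"blue"}, "b": {"blue"}},
                                  labels={"blue", "red"})
        assert len(plan_infiltrate(net, "red", "blue")) == 0

    def test_pair_enumeration_one_times_three(self):
        net = SocialNetwork.build(
            vertices="xpqr",
            membership={"x": {"red"}, "p": {"blue"}, "q": {"blue"}, "r": {"blue"}},
            labels={"blue", "red"})
        p = plan_infiltrate(net, "red", "blue")
        assert sum(isinstance(op, SetMembership) for op in p.ops) == 1
        assert sum(isinstance(op, AddEdge) for op in p.ops) == 3
        assert verify(net, p).satisfied

    def test_existing_cross_edges_are_skipped_not_duplicated(self):
        net = SocialNetwork.build(
            vertices="xp", edges=[("p", "x")],
            membership={"x": {"red"}, "p": {"blue"}},
            labels={"blue", "red"})
        p = plan_infiltrate(net, "red", "blue")
        assert not any(isinstance(op, AddEdge) for op in p.ops)
        assert verify(net, p).satisfied

    def test_dropping_agent_edges_breaks_single_component(self, fig5b):
        # dropping both edges added for agent e leaves e an isolated
        # component of the union
        p = plan_infiltrate(fig5b, "red", "blue")
        truncated = InterventionPlan(p.ops[:-2], p.target, p.strategy)
        report = verify(fig5b, truncated)
        assert not report.satisfied
        assert report.per_condition[
            Condition("single-component-union", ("red", "blue"))] is False


class TestPlanInfluenceContainment:
    def test_single_seed_on_printed_network(self, fig7a):
        p = plan_influence_containment(fig7a, "red", "blue")
        assert p.ops == (SetMembership("d", {"red", "blue"}),)
        assert p.diffusion == ("red", frozenset({"blue"}))
        assert verify(fig7a, p).satisfied

    def test_singleton_community_seeds_itself(self):
        net = SocialNetwork.build(
            vertices="vq", membership={"v": {"red"}, "q": {"blue"}},
            labels={"blue", "red"}, directed=True)
        p = plan_influence_containment(net, "red", "blue")
        assert p.ops == (SetMembership("v", {"red", "blue"}),)
        assert verify(net, p).satisfied

    def test_two_hub_star_needs_two_seeds(self):
        # h1 covers x1,x2; h2 covers y1,y2; neither hub reaches the other's leaves
        net = SocialNetwork.build(
            vertices=["h1", "h2", "x1", "x2", "y1", "y2", "b"],
            edges=[("h1", "x1"), ("h1", "x2"), ("h2", "y1"), ("h2", "y2")],
            membership={v: {"red"} for v in ["h1", "h2", "x1", "x2", "y1", "y2"]}
            | {"b": {"blue"}},
            labels={"blue", "red"}, directed=True)
        p = plan_influence_containment(net, "red", "blue")
        assert {op.vertex for op in p.ops} == {"h1", "h2"}
        assert verify(net, p).satisfied

    def test_undirected_network_rejected(self, fig1a):
        with pytest.raises(ValueError, match="directed"):
            plan_influence_containment(fig1a, "red", "blue")


class TestPlanCoverage:
    def covered(self, net, b="infrequent"):
        return evaluate(net, Condition("coverage-all", (b,)))

    @pytest.fixture
    def school(self):
        return SocialNetwork.build(
            vertices=["f1", "f2", "f3", "i1", "i2"],
            edges=[("f1", "i1"), ("f2", "f3")],
            membership={"f1": {"frequent"}, "f2": {"frequent"}, "f3": {"frequent"},
                        "i1": {"infrequent"}, "i2": {"infrequent"}},
            labels={"frequent", "infrequent"})

    def test_already_covered_network_gives_empty_plan(self, fig1a):
        p = plan_coverage(fig1a, "blue", "red", seed=3)
        assert len(p) == 0 and verify(fig1a, p).satisfied

    def test_isolated_vertices_all_wired_to_single_candidate(self):
        net = SocialNetwork.build(
            vertices=["a1", "a2", "a3", "b1"],
            membership={"a1": {"frequent"}, "a2": {"frequent"},
                        "a3": {"frequent"}, "b1": {"infrequent"}},
            labels={"frequent", "infrequent"})
        p = plan_coverage(net, "frequent", "infrequent", seed=0)
        assert len(p) == 3
        assert all(isinstance(op, AddEdge) and "b1" in (op.u, op.v) for op in p.ops)
        assert verify(net, p).satisfied

    @pytest.mark.parametrize("seed", [0, 1, 7, 99])
    def test_plan_length_is_seed_independent(self, school, seed):
        # exactly f2 and f3 lack an infrequent neighbour
        p = plan_coverage(school, "frequent", "infrequent", seed=seed)
        assert len(p) == 2
        assert {op.u for op in p.ops} == {"f2", "f3"}
        assert verify(school, p).satisfied

    def test_seed_recorded_and_respected(self, school):
        p1 = plan_coverage(school, "frequent", "infrequent", seed=42)
        p2 = plan_coverage(school, "frequent", "infrequent", seed=42)
        assert p1 == p2 and p1.seed == 42

    def test_empty_covering_community_is_an_error(self):
        net = SocialNetwork.build(vertices="a", membership={"a": {"frequent"}},
                                  labels={"frequent", "infrequent"})
        with pytest.raises(ValueError, match="empty"):
            plan_coverage(net, "frequent", "infrequent", seed=0)


class TestVerify:
    def test_input_network_unchanged(self, fig1a):
        p = plan_disjoint(fig1a, "blue", "red")
        before = (fig1a.graph, fig1a.membership_table())
        verify(fig1a, p)
        assert (fig1a.graph, fig1a.membership_table()) == before

    def test_inapplicable_op_reports_failure(self, fig1a):
        bad = InterventionPlan(
            (RemoveVertex("nope"),),
            relationship_conditions("disjoint", "blue", "red"),
            strategy="manual")
        report = verify(fig1a, bad)
        assert not report.satisfied
        assert "nope" in report.failure

    def test_summary_classifies_the_relevant_pair(self, fig1a):
        report = verify(fig1a, plan_disjoint(fig1a, "blue", "red"))
        assert report.resulting_network_summary["most_specific"] == "disjoint"


class TestDispatcher:
    def test_policy_restricted_to_membership_changes_picks_reassignment(self, fig1a):
        only_membership = FeasibilityPolicy([PolicyRule("C^")])
        p = plan(fig1a, "disjoint", "blue", "red", policy=only_membership)
        assert p.strategy == "disjoint/reassign-membership"
        assert verify(fig1a, p).satisfied

    def test_tie_on_length_broken_by_declared_order(self, fig1a):
        # both strategies need exactly one operation; remove-vertex is declared first
        p = plan(fig1a, "disjoint", "blue", "red")
        assert p.strategy == "disjoint/remove-vertex"

    def test_already_satisfied_target_gives_empty_plan(self, fig5a):
        p = plan(fig5a, "disjoint", "blue", "red")
        assert len(p) == 0

    def test_condition_set_target_is_recognised(self, fig5b):
        target = relationship_conditions("disjoint", "red", "blue")
        p = plan(fig5b, target, "red", "blue")
        assert verify(fig5b, p).satisfied

    def test_nothing_feasible_lists_strategies_tried(self, fig1a):
        with pytest.raises(InfeasiblePlanError, match="remove-vertex.*reassign"):
            plan(fig1a, "disjoint", "blue", "red", policy=FeasibilityPolicy())

    def test_plan_json_round_trip(self, fig7a, fig5b):
        for p in (plan_influence_containment(fig7a, "red", "blue"),
                  plan_infiltrate(fig5b, "red", "blue"),
                  plan_coverage(fig5b, "blue", "red", seed=5)):
            assert InterventionPlan.from_json(p.to_json()) == p


class TestTheoremSweeps:
    """Machine-checked post-conditions on random networks with planted
    preconditions (small sweeps; the full 1000-network sweeps run in the
    acceptance suite)."""

    @pytest.mark.parametrize("seed", range(50))
    def test_disjoint_both_strategies(self, seed):
        net = random_social_network(random.Random(seed), max_vertices=30)
        for strategy in ("remove-vertex", "reassign-membership"):
            assert verify(net, plan_disjoint(net, "blue", "red", strategy)).satisfied

    @pytest.mark.parametrize("seed", range(50))
    def test_atomize_on_disjoint_communities(self, seed):
        net = random_disjoint_communities(random.Random(seed))
        assert verify(net, plan_atomize(net, "red", "blue")).satisfied

    @pytest.mark.parametrize("seed", range(50))
    def test_infiltrate_on_atomized_disjoint_communities(self, seed):
        net = random_disjoint_communities(random.Random(seed), atomized_a=True)
        assert verify(net, plan_infiltrate(net, "red", "blue")).satisfied

    @pytest.mark.parametrize("seed", range(50))
    def test_influence_containment_with_diffusion(self, seed):
        net = random_social_network(random.Random(seed), max_vertices=30,
                                    directed=True)
        assert verify(net, plan_influence_containment(net, "red", "blue")).satisfied

    @pytest.mark.parametrize("seed", range(50))
    def test_coverage_on_random_networks(self, seed):
        rng = random.Random(seed)
        net = random_social_network(rng, max_vertices=30)
        if not net.members("red"):
            return  # covering community must be non-empty
        p = plan_coverage(net, "blue", "red", seed=seed)
        assert verify(net, p).satisfied
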