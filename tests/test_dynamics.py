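"""Update semantics, state-transition graphs and attractor detection,
cross-checked against brute-force truth-table/reachability oracles."""

import pytest

from oracles import (
    all_states,
    async_successors,
    brute_force_attractors,
    brute_force_basins,
    rules_from_text,
    sync_successor,
)
from tnfboolnet.dynamics import (
    CapacityError,
    Perturbation,
    asynchronous_successors,
    attractors_to_tsv,
    build_state_transition_graph,
    evaluate_node,
    find_attractors,
    stg_to_dot,
    summarize_attractor,
    synchronous_step,
)
from tnfboolnet.network import parse_rules, serialize_rules
from tnfboolnet.synthetic import make_random_network


def net_of(text):
    return parse_rules("targets, factors\n" + text)


class TestEvaluateNode:
    def test_negation(self):
        net = net_of("A, !A")
        assert evaluate_node(net, "A", {"A": 0}) == 1

    def test_and_truth_table(self):
        net = net_of("A, B & C\nB, B\nC, C")
        assert evaluate_node(net, "A", {"A": 0, "B": 1, "C": 0}) == 0
        assert evaluate_node(net, "A", {"A": 0, "B": 1, "C": 1}) == 1

    def test_clamp_dominates_rule(self):
        net = net_of("A, !A")
        pert = Perturbation({"A": 1})
        for bit in (0, 1):
            assert evaluate_node(net, "A", {"A": bit}, pert) == 1

    def test_unknown_node_raises(self):
        net = net_of("A, A")
        with pytest.raises(KeyError, match="Z"):
            evaluate_node(net, "Z", {"A": 0})


class TestSynchronousStep:
    def test_toggle(self):
        net = net_of("A, !A")
        assert synchronous_step(net, {"A": 0}) == {"A": 1}

    def test_copy_chain(self):
        net = net_of("A, A\nB, A")
        assert synchronous_step(net, {"A": 1, "B": 0}) == {"A": 1, "B": 1}

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_truth_table_oracle_exhaustively(self, seed):
        net = make_random_network(6, 3, seed=seed)
        rules = rules_from_text(serialize_rules(net))
        nodes = list(net.nodes)
        for state in all_states(len(nodes)):
            got = synchronous_step(net, dict(zip(nodes, state)))
            assert tuple(got[n] for n in nodes) == sync_successor(rules, nodes, state)


class TestAsynchronousSuccessors:
    def test_two_unstable_nodes_two_successors(self):
        net = net_of("A, !A\nB, !B")
        assert asynchronous_successors(net, (0, 0)) == {(1, 0), (0, 1)}

    def test_fixed_point_self_loop(self):
        net = net_of("A, A")
        assert asynchronous_successors(net, (1,)) == {(1,)}

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_single_flip_oracle_exhaustively(self, seed):
        net = make_random_network(6, 3, seed=seed)
        rules = rules_from_text(serialize_rules(net))
        nodes = list(net.nodes)
        for state in all_states(len(nodes)):
            assert asynchronous_successors(net, state) == async_successors(rules, nodes, state)


class TestStateTransitionGraph:
    def test_one_node_identity(self):
        stg = build_state_transition_graph(net_of("A, A"), scheme="asynchronous")
        assert stg.n_states == 2
        assert set(stg.graph.edges) == {((0,), (0,)), ((1,), (1,))}

    def test_double_toggle_asynchronous_counts(self):
        stg = build_state_transition_graph(net_of("A, !A\nB, !B"), scheme="asynchronous")
        assert stg.n_states == 4
        assert stg.graph.number_of_edges() == 8
        assert all(stg.graph.out_degree(s) == 2 for s in stg.graph)

    def test_synchronous_out_degree_exactly_one(self):
        net = make_random_network(5, 3, seed=3)
        stg = build_state_transition_graph(net, scheme="synchronous")
        assert all(stg.graph.out_degree(s) == 1 for s in stg.graph)

    def test_clamped_inputs_shrink_the_state_space(self, paper_model):
        pert = Perturbation({"Macrophage": 1, "TNF": 0})
        stg = build_state_transition_graph(paper_model, pert)
        assert stg.n_states == 2 ** (len(paper_model) - 2)
        i_m = paper_model.nodes.index("Macrophage")
        i_t = paper_model.nodes.index("TNF")
        assert all(s[i_m] == 1 and s[i_t] == 0 for s in stg.graph)

    def test_capacity_bound_enforced(self):
        net = make_random_network(6, 2, seed=0)
        with pytest.raises(CapacityError, match="smaller model"):
            build_state_transition_graph(net, max_nodes=5)


class TestFindAttractors:
    def test_bistable_identity(self):
        stg = build_state_transition_graph(net_of("A, A"))
        atts = find_attractors(stg)
        assert [a.kind for a in atts] == ["fixed_point", "fixed_point"]
        assert {next(iter(a.states)) for a in atts} == {(0,), (1,)}

    def test_synchronous_toggle_is_a_two_cycle(self):
        stg = build_state_transition_graph(net_of("A, !A"), scheme="synchronous")
        atts = find_attractors(stg)
        assert len(atts) == 1 and atts[0].kind == "cyclic" and atts[0].size == 2
        assert summarize_attractor(atts[0]) == {"A": "oscillating"}

    @pytest.mark.parametrize("scheme", ["synchronous", "asynchronous"])
    @pytest.mark.parametrize("seed", range(25))
    def test_equals_brute_force_reachability(self, scheme, seed):
        net = make_random_network(7, 3, seed=seed)
        rules = rules_from_text(serialize_rules(net))
        stg = build_state_transition_graph(net, scheme=scheme)
        got = {frozenset(a.states) for a in find_attractors(stg, compute_basins=False)}
        assert got == brute_force_attractors(rules, list(net.nodes), scheme)

    @pytest.mark.parametrize("seed", range(10))
    def test_synchronous_basins_partition_the_state_space(self, seed):
        net = make_random_network(6, 3, seed=seed)
        rules = rules_from_text(serialize_rules(net))
        stg = build_state_transition_graph(net, scheme="synchronous")
        atts = find_attractors(stg)
        assert sum(a.basin_size for a in atts) == 2 ** len(net)
        expected = brute_force_basins(rules, list(net.nodes))
        for att in atts:
            assert expected[frozenset(att.states)] == att.basin_size

    @pytest.mark.parametrize("seed", range(25))
    def test_fixed_points_coincide_across_schemes(self, seed):
        net = make_random_network(7, 3, seed=seed)
        fps = {}
        for scheme in ("synchronous", "asynchronous"):
            stg = build_state_transition_graph(net, scheme=scheme)
            fps[scheme] = {
                next(iter(a.states))
                for a in find_attractors(stg, compute_basins=False)
                if a.kind == "fixed_point"
            }
        assert fps["synchronous"] == fps["asynchronous"]

    @pytest.mark.parametrize("seed", range(10))
    def test_clamped_node_is_fixed_in_every_attractor_state(self, seed):
        net = make_random_network(6, 3, seed=seed)
        node = net.nodes[0]
        idx = 0
        for value in (0, 1):
            stg = build_state_transition_graph(net, Perturbation({node: value}))
            for att in find_attractors(stg, compute_basins=False):
                assert all(s[idx] == value for s in att.states)

    def test_deterministic_ordering_by_size_then_state(self):
        net = make_random_network(6, 3, seed=11)
        stg = build_state_transition_graph(net)
        atts = find_attractors(stg, compute_basins=False)
        keys = [(a.size, min(a.states)) for a in atts]
        assert keys == sorted(keys)

    def test_asynchronous_weak_basin_counts_reaching_states(self):
        # Both toggle attractor states can be reached from everywhere here
        stg = build_state_transition_graph(net_of("A, !A\nB, B"))
        atts = find_attractors(stg)
        assert all(a.weak_basin_size == 2 for a in atts)


class TestSummaries:
    def test_fixed_point_summary_is_the_state(self):
        stg = build_state_transition_graph(net_of("A, 1\nB, 0"))
        (att,) = find_attractors(stg)
        assert summarize_attractor(att) == {"A": 1, "B": 0}

    def test_complex_attractor_summary_matches_per_state_scan(self):
        net = make_random_network(7, 3, seed=5)
        stg = build_state_transition_graph(net)
        for att in find_attractors(stg, compute_basins=False):
            summary = summarize_attractor(att)
            for i, name in enumerate(net.nodes):
                vals = {s[i] for s in att.states}
                assert summary[name] == (vals.pop() if len(vals) == 1 else "oscillating")

    def test_unknown_node_rejected(self):
        stg = build_state_transition_graph(net_of("A, A"))
        (att, _) = find_attractors(stg)
        with pytest.raises(KeyError):
            summarize_attractor(att, ["Zebra"])


class TestReports:
    def test_tsv_has_one_row_per_attractor_node_pair(self):
        stg = build_state_transition_graph(net_of("A, A\nB, !B"))
        atts = find_attractors(stg)
        lines = attractors_to_tsv(atts).strip().splitlines()
        assert len(lines) == 1 + len(atts) * 2

    def test_dot_marks_attractor_states(self):
        stg = build_state_transition_graph(net_of("A, 1"))
        atts = find_attractors(stg)
        dot = stg_to_dot(stg, atts)
        assert dot.startswith("digraph") and "lightblue" in dot
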