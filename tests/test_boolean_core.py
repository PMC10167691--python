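"""Rule enumeration, evaluation and synchronous simulation.

Independent oracles: rule evaluation is cross-checked against sympy's
boolean algebra; attractors are cross-checked against exhaustive
state-transition-graph analysis over all 2^n states.
"""

import itertools

import pytest
import sympy
from hypothesis import given, settings
from hypothesis import strategies as st

from boolpath.boolrules import Rule, enumerate_rule_space, rule_space_size
from boolpath.network import SignedNetwork
from boolpath.simulate import (
    NetworkModel,
    attractor_average,
    simulate_synchronous,
    steady_state,
)


def sympy_oracle(rule: Rule, state: dict[str, int]) -> int:
    """Evaluate a rule via sympy boolean algebra (independent route)."""
    symbols = {g: sympy.Symbol(g) for g, _ in rule.regulators}
    literals = [
        symbols[g] if sign == 1 else sympy.Not(symbols[g])
        for g, sign in rule.regulators
    ]
    expr = sympy.Or(*[sympy.And(*[literals[i] for i in clause]) for clause in rule.clauses])
    return int(bool(expr.subs({symbols[g]: bool(state[g]) for g, _ in rule.regulators})))


def exhaustive_attractor_average(
    model: NetworkModel, init: dict[str, int], clamp: dict[str, int] | None = None
) -> dict[str, float]:
    """Brute-force oracle: walk the full state-transition graph.

    Successor states are computed from scratch with the sympy oracle,
    independently of the package's truth-table machinery.
    """
    nodes = sorted(model.network.nodes)
    clamp = clamp or {}

    def successor(state: dict[str, int]) -> dict[str, int]:
        nxt = {}
        for node in nodes:
            if node in clamp:
                nxt[node] = clamp[node]
            elif node in model.rules:
                nxt[node] = sympy_oracle(model.rules[node], state)
            else:
                nxt[node] = state[node]
        return nxt

    state = {n: clamp.get(n, init[n]) for n in nodes}
    seen: list[tuple[int, ...]] = []
    key = tuple(state[n] for n in nodes)
    while key not in seen:
        seen.append(key)
        state = successor(state)
        key = tuple(state[n] for n in nodes)
    cycle = seen[seen.index(key):]
    return {n: sum(s[i] for s in cycle) / len(cycle) for i, n in enumerate(nodes)}


class TestRuleSpace:
    @pytest.mark.parametrize("k,expected", [(1, 1), (2, 7), (3, 127)])
    def test_enumeration_count(self, k, expected):
        regulators = [(f"R{i}", 1) for i in range(k)]
        rules = enumerate_rule_space("T", regulators)
        assert len(rules) == expected == rule_space_size(k)

    def test_rules_are_distinct(self):
        rules = enumerate_rule_space("T", [("A", 1), ("B", -1), ("C", 1)])
        assert len({r.clauses for r in rules}) == 127

    @pytest.mark.parametrize("k", [0, 4])
    def test_out_of_range_indegree_rejected(self, k):
        with pytest.raises(ValueError):
            enumerate_rule_space("T", [(f"R{i}", 1) for i in range(k)])


class TestEvaluateRule:
    def test_or_rule(self):
        rule = Rule("T", (("A", 1), ("B", 1)),
                    frozenset({frozenset({0}), frozenset({1})}))
        assert rule.evaluate({"A": 0, "B": 1}) == 1
        assert rule.evaluate({"A": 0, "B": 0}) == 0

    def test_inhibitor_negated_in_and_clause(self):
        rule = Rule("T", (("A", -1), ("B", 1)), frozenset({frozenset({0, 1})}))
        assert rule.evaluate({"A": 1, "B": 1}) == 0
        assert rule.evaluate({"A": 0, "B": 1}) == 1

    def test_missing_regulator_state_errors(self):
        rule = Rule("T", (("A", 1),), frozenset({frozenset({0})}))
        with pytest.raises(KeyError):
            rule.evaluate({"B": 1})

    @pytest.mark.parametrize("k", [1, 2, 3])
    @pytest.mark.parametrize("signs_seed", [0, 1])
    def test_agrees_with_sympy_oracle_exhaustively(self, k, signs_seed):
        """Every rule in the k-regulator space, on every input state."""
        import random

        rng = random.Random(signs_seed)
        regulators = [(f"R{i}", rng.choice([1, -1])) for i in range(k)]
        for rule in enumerate_rule_space("T", regulators):
            for bits in itertools.product([0, 1], repeat=k):
                state = {f"R{i}": bits[i] for i in range(k)}
                assert rule.evaluate(state) == sympy_oracle(rule, state), rule.to_text()

    def test_text_rendering(self):
        rule = Rule("T", (("A", 1), ("B", -1), ("C", 1)),
                    frozenset({frozenset({0, 1}), frozenset({2})}))
        assert rule.to_text() == "T* = C or (A and not B)"


def two_node_model(edges, rules) -> NetworkModel:
    net = SignedNetwork.from_edges("toy", ["A", "B"], edges)
    return NetworkModel(network=net, rules=rules)


class TestSimulation:
    def test_isolated_node_is_fixed_point(self):
        net = SignedNetwork.from_edges("one", ["A"], [])
        model = NetworkModel(network=net, rules={})
        traj = simulate_synchronous(model, {"A": 1}, steps=5)
        assert all(s == {"A": 1} for s in traj)

    def test_mutual_inhibition_fixed_point(self):
        rules = {
            "A": Rule("A", (("B", -1),), frozenset({frozenset({0})})),
            "B": Rule("B", (("A", -1),), frozenset({frozenset({0})})),
        }
        model = two_node_model([("A", "B", -1), ("B", "A", -1)], rules)
        traj = simulate_synchronous(model, {"A": 1, "B": 0}, steps=10)
        assert traj[-1] == {"A": 1, "B": 0}

    def test_negative_feedback_limit_cycle(self):
        # A -| B, B -> A gives an oscillation from (1,1)
        rules = {
            "B": Rule("B", (("A", -1),), frozenset({frozenset({0})})),
            "A": Rule("A", (("B", 1),), frozenset({frozenset({0})})),
        }
        model = two_node_model([("A", "B", -1), ("B", "A", 1)], rules)
        traj1 = simulate_synchronous(model, {"A": 1, "B": 1}, steps=12)
        traj2 = simulate_synchronous(model, {"A": 1, "B": 1}, steps=12)
        assert traj1 == traj2  # deterministic
        # period divides 4 (exhaustive 4-state transition graph)
        assert traj1[-1] == traj1[-5]
        avg = attractor_average(model, {"A": 1, "B": 1})
        assert avg == exhaustive_attractor_average(model, {"A": 1, "B": 1})

    def test_trajectory_length(self):
        net = SignedNetwork.from_edges("one", ["A"], [])
        model = NetworkModel(network=net, rules={})
        assert len(simulate_synchronous(model, {"A": 0}, steps=7)) == 8


class TestSteadyState:
    def test_fixed_point(self):
        traj = [{"A": 1}] * 6
        assert steady_state(traj, window=4) == {"A": 1.0}

    def test_two_cycle_average(self):
        traj = [{"A": i % 2} for i in range(10)]
        assert steady_state(traj, window=4) == {"A": 0.5}

    def test_window_validation(self):
        with pytest.raises(ValueError):
            steady_state([{"A": 1}], window=0)
        with pytest.raises(ValueError):
            steady_state([{"A": 1}], window=5)

    @given(bits=st.lists(st.integers(0, 1), min_size=2, max_size=20),
           window=st.integers(1, 20))
    @settings(max_examples=50, deadline=None)
    def test_bounded_in_unit_interval(self, bits, window):
        window = min(window, len(bits))
        value = steady_state([{"A": b} for b in bits], window=window)["A"]
        assert 0.0 <= value <= 1.0


class TestAttractorOracle:
    @pytest.mark.parametrize("seed", range(6))
    def test_random_small_networks_match_state_graph_analysis(self, seed):
        """Attractor averages equal exhaustive state-graph results (n <= 8)."""
        from boolpath.synthetic import generate_ground_truth, generate_network

        net = generate_network(6, edge_density=0.4, seed=seed)
        truth = generate_ground_truth(net, seed=seed + 100)
        model = truth.model
        for trial in range(4):
            import random

            rng = random.Random(1000 * seed + trial)
            init = {n: rng.randint(0, 1) for n in net.nodes}
            fast = attractor_average(model, init)
            brute = exhaustive_attractor_average(model, init)
            assert fast == pytest.approx(brute)

    def test_clamped_attractor_matches_oracle(self):
        from boolpath.synthetic import generate_ground_truth, generate_network

        net = generate_network(5, edge_density=0.5, seed=3)
        truth = generate_ground_truth(net, seed=4)
        init = dict.fromkeys(net.nodes, 0)
        g = sorted(net.nodes)[0]
        for bit in (0, 1):
            fast = attractor_average(truth.model, init, clamp={g: bit})
            brute = exhaustive_attractor_average(truth.model, init, clamp={g: bit})
            assert fast == pytest.approx(brute)

    def test_steady_state_stable_once_cycle_entered(self):
        """Extending the horizon does not change the windowed average when
        the window spans whole cycle periods."""
        from boolpath.synthetic import generate_ground_truth, generate_network

        net = generate_network(6, edge_density=0.4, seed=9)
        truth = generate_ground_truth(net, seed=10)
        init = dict.fromkeys(net.nodes, 1)
        short = simulate_synchronous(truth.model, init, steps=80)
        long = simulate_synchronous(truth.model, init, steps=160)
        # window 24 is divisible by every period <= 4; deviations would
        # indicate the cycle was not yet entered
        assert steady_state(short, 24) == steady_state(long, 24)
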