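"""Expression parsing, evaluation, synchronous updates and clamping."""

import random
from itertools import product

import pytest
from hypothesis import given, strategies as st

from gas5net import (And, BooleanNetwork, Const, Not, Or, Perturbation,
                     RuleSyntaxError, UnknownNodeError, Var,
                     apply_perturbation, evaluate, parse_rule,
                     synchronous_step)
from gas5net.attractors import find_fixed_points_exhaustive
from gas5net.logic import NetworkError
from gas5net.synth import RandomNetSpec, generate_random_network

from conftest import oracle_eval, oracle_truth_table


def toggle_switch():
    nodes = ("A", "B")
    return BooleanNetwork(nodes, {"A": Not(Var("B")), "B": Not(Var("A"))},
                          label="toggle")


# ---------------------------------------------------------------------------
# parse_rule
# ---------------------------------------------------------------------------

class TestParseRule:
    def test_precedence_not_and_or(self):
        expr = parse_rule("A & !B | C", {"A", "B", "C"})
        assert expr == Or(And(Var("A"), Not(Var("B"))), Var("C"))

    def test_single_identifier(self):
        assert parse_rule("A", {"A"}) == Var("A")

    def test_keyword_operators_match_symbols(self):
        assert parse_rule("A AND NOT B OR C", {"A", "B", "C"}) == \
            parse_rule("A & !B | C", {"A", "B", "C"})

    def test_negated_conjunction_truth_table(self):
        # NAND semantics checked against the independent oracle on all 4 states
        expr = parse_rule("!(ATM & p53)", {"ATM", "p53"})
        for atm, p53 in product((0, 1), repeat=2):
            state = {"ATM": atm, "p53": p53}
            expected = 0 if (atm and p53) else 1
            assert evaluate(expr, state) == expected
            assert oracle_eval("!(ATM & p53)", state) == expected

    def test_constants(self):
        assert parse_rule("0", set()) == Const(0)
        assert parse_rule("A | 1", {"A"}) == Or(Var("A"), Const(1))

    @pytest.mark.parametrize("bad", ["", "   ", "A &", "(A | B", "A ~ B", "& A"])
    def test_syntax_error_carries_position(self, bad):
        with pytest.raises(RuleSyntaxError) as err:
            parse_rule(bad, {"A", "B"})
        assert "position" in str(err.value)

    def test_unknown_identifier_is_named(self):
        with pytest.raises(UnknownNodeError, match="Mdm2"):
            parse_rule("A & Mdm2", {"A"})

    def test_unrestricted_parse_accepts_any_identifier(self):
        assert parse_rule("X & Y").variables() == {"X", "Y"}


# ---------------------------------------------------------------------------
# evaluate
# ---------------------------------------------------------------------------

def _random_expr(rng, names, depth):
    if depth == 0 or rng.random() < 0.3:
        return Var(rng.choice(names)) if rng.random() < 0.9 \
            else Const(rng.randint(0, 1))
    kind = rng.choice(["not", "and", "or"])
    if kind == "not":
        return Not(_random_expr(rng, names, depth - 1))
    children = [_random_expr(rng, names, depth - 1)
                for _ in range(rng.randint(2, 3))]
    return And(*children) if kind == "and" else Or(*children)


class TestEvaluate:
    def test_tautology(self):
        expr = Or(Var("A"), Not(Var("A")))
        assert evaluate(expr, {"A": 0}) == 1
        assert evaluate(expr, {"A": 1}) == 1

    def test_conjunction(self):
        assert evaluate(And(Var("A"), Var("B")), {"A": 1, "B": 0}) == 0

    def test_missing_variable_raises(self):
        with pytest.raises(NetworkError, match="missing"):
            evaluate(Var("A"), {"B": 1})

    @given(st.integers(0, 10_000))
    def test_truth_tables_match_independent_oracle(self, seed):
        """Random expressions over <=4 variables agree with the oracle on
        every assignment (brute force over <=16 states)."""
        rng = random.Random(seed)
        names = ["A", "B", "C", "D"][: rng.randint(1, 4)]
        expr = _random_expr(rng, names, depth=3)
        text = expr.to_text()
        for bits in product((0, 1), repeat=len(names)):
            state = dict(zip(names, bits))
            assert evaluate(expr, state) == oracle_eval(text, state)

    @given(st.integers(0, 10_000))
    def test_serialize_parse_round_trip(self, seed):
        """serialize -> parse preserves the truth table (<=10 variables)."""
        rng = random.Random(seed)
        names = [f"v{i}" for i in range(rng.randint(1, 10))]
        expr = _random_expr(rng, names, depth=3)
        reparsed = parse_rule(expr.to_text(), names)
        used = sorted(expr.variables())
        for bits in product((0, 1), repeat=len(used)):
            state = dict(zip(used, bits))
            assert evaluate(expr, state) == evaluate(reparsed, state)


# ---------------------------------------------------------------------------
# synchronous_step
# ---------------------------------------------------------------------------

class TestSynchronousStep:
    def test_all_nodes_read_the_old_state(self):
        assert synchronous_step(toggle_switch(), {"A": 1, "B": 1}) == \
            {"A": 0, "B": 0}

    def test_fixed_state_maps_to_itself(self):
        assert synchronous_step(toggle_switch(), {"A": 1, "B": 0}) == \
            {"A": 1, "B": 0}

    def test_determinism_across_calls(self):
        net = generate_random_network(RandomNetSpec(8, 2, seed=3))
        s = {n: i % 2 for i, n in enumerate(net.nodes)}
        results = {tuple(sorted(synchronous_step(net, s).items()))
                   for _ in range(5)}
        assert len(results) == 1

    @pytest.mark.parametrize("seed", range(0, 100, 10))
    def test_trajectories_reenter_within_state_space_bound(self, seed):
        """Iterating the deterministic map on an 8-node network must revisit
        a state within 2^8 steps (finite state space)."""
        for sub in range(10):
            net = generate_random_network(RandomNetSpec(8, 2, seed=seed + sub))
            step, _ = net.compiled()
            rng = random.Random(seed * 97 + sub)
            s = tuple(rng.randint(0, 1) for _ in net.nodes)
            seen = {s}
            for _ in range(2 ** 8):
                s = step(s)
                if s in seen:
                    break
                seen.add(s)
            else:
                pytest.fail("trajectory did not re-enter within 2^8 steps")

    def test_locality(self):
        """States agreeing on a node's regulators get the same next value
        for that node."""
        net = generate_random_network(RandomNetSpec(6, 2, seed=11))
        rng = random.Random(5)
        for _ in range(50):
            s1 = {n: rng.randint(0, 1) for n in net.nodes}
            v = rng.choice(net.nodes)
            regs = net.regulators(v)
            s2 = {n: (s1[n] if n in regs else rng.randint(0, 1))
                  for n in net.nodes}
            assert synchronous_step(net, s1)[v] == synchronous_step(net, s2)[v]


# ---------------------------------------------------------------------------
# apply_perturbation (clamping)
# ---------------------------------------------------------------------------

class TestPerturbation:
    def test_clamp_replaces_rule_with_constant(self):
        net = toggle_switch()
        clamped = apply_perturbation(net, Perturbation({"A": 1}, "A E1"))
        assert clamped.rules["A"] == Const(1)
        assert clamped.rules["B"] == net.rules["B"]
        assert net.rules["A"] == Not(Var("B"))  # original untouched

    def test_clamped_toggle_has_single_fixed_point(self):
        clamped = apply_perturbation(toggle_switch(), Perturbation({"A": 1}))
        report = find_fixed_points_exhaustive(clamped)
        assert report.fixed_point_bits() == [(1, 0)]

    def test_empty_clamp_is_identity_on_dynamics(self):
        net = toggle_switch()
        same = apply_perturbation(net, Perturbation({}))
        assert find_fixed_points_exhaustive(same).fixed_point_bits() == \
            find_fixed_points_exhaustive(net).fixed_point_bits()

    def test_unknown_node_rejected(self):
        with pytest.raises(UnknownNodeError, match="Zzz"):
            apply_perturbation(toggle_switch(), Perturbation({"Zzz": 0}))

    def test_clamp_value_validated(self):
        with pytest.raises(NetworkError):
            Perturbation({"A": 2})

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_clamp_persists_along_trajectories(self, seed):
        net = generate_random_network(RandomNetSpec(7, 2, seed=seed))
        clamps = {net.nodes[0]: 1, net.nodes[3]: 0}
        clamped = apply_perturbation(net, Perturbation(clamps))
        rng = random.Random(seed)
        s = {n: rng.randint(0, 1) for n in net.nodes}
        for _ in range(20):
            s = synchronous_step(clamped, s)
            assert all(s[n] == v for n, v in clamps.items())


def test_network_rejects_dangling_references():
    with pytest.raises(UnknownNodeError):
        BooleanNetwork(("A",), {"A": Var("B")})


def test_network_requires_rule_per_node():
    with pytest.raises(NetworkError, match="without a rule"):
        BooleanNetwork(("A", "B"), {"A": Const(1)})
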