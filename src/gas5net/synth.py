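"""Seeded generators of random and canonical Boolean networks.

These make the update engine and both fixed-point solvers testable
independently of the shipped checkpoint model.  All randomness flows
through :class:`random.Random` (MT19937 with integer seeding, identical
across platforms and Python builds), so a spec + seed pair always yields
a byte-identical serialized network.

Rule schemes
------------
random-truth-table
    each node gets a uniformly random non-constant Boolean function of its
    regulators, materialized as OR-of-minterms (constants are resampled so
    every sampled regulator stays structurally wired in);
nested-canalizing
    regulators are layered so each either forces the output or defers to
    the next, the common idealization of real regulatory logic;
sign-respecting
    each regulator is an activator or an inhibitor and the rule is
    OR(activators) AND NOT OR(inhibitors), mirroring the
    activation/inhibition arcs of a curated regulatory graph.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .logic import And, BoolExpr, BooleanNetwork, Const, NetworkError, Not, Or, Var

__all__ = ["RandomNetSpec", "generate_random_network", "canonical_fixtures"]

RULE_SCHEMES = ("random-truth-table", "nested-canalizing", "sign-respecting")


@dataclass(frozen=True)
class RandomNetSpec:
    """Parameters of one random-network draw (identical spec+seed =>
    identical network)."""

    n_nodes: int
    k_regulators: Union[int, Tuple[int, int]]
    rule_scheme: str = "random-truth-table"
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 1:
            raise NetworkError("n_nodes must be positive")
        k = self.k_regulators
        lo, hi = (k, k) if isinstance(k, int) else k
        if lo < 1 or hi < lo:
            raise NetworkError(f"invalid k_regulators {k!r}")
        if hi >= self.n_nodes:
            raise NetworkError("k_regulators must be < n_nodes")
        if self.rule_scheme not in RULE_SCHEMES:
            raise NetworkError(f"unknown rule_scheme {self.rule_scheme!r}; "
                               f"choose from {RULE_SCHEMES}")

    def k_range(self) -> Tuple[int, int]:
        k = self.k_regulators
        return (k, k) if isinstance(k, int) else k


def _minterm(regs: Sequence[str], bits: Sequence[int]) -> BoolExpr:
    lits: List[BoolExpr] = [Var(r) if b else Not(Var(r))
                            for r, b in zip(regs, bits)]
    return lits[0] if len(lits) == 1 else And(*lits)


def _random_truth_table(rng: random.Random, regs: Sequence[str]) -> BoolExpr:
    k = len(regs)
    table = [rng.randint(0, 1) for _ in range(2 ** k)]
    while len(set(table)) == 1:   # resample constants so every regulator
        table = [rng.randint(0, 1) for _ in range(2 ** k)]  # stays wired in
    terms = [_minterm(regs, [(i >> (k - 1 - j)) & 1 for j in range(k)])
             for i, v in enumerate(table) if v]
    return terms[0] if len(terms) == 1 else Or(*terms)


def _nested_canalizing(rng: random.Random, regs: Sequence[str]) -> BoolExpr:
    # innermost layer outward: each regulator canalizes to its output value
    expr: BoolExpr = Const(rng.randint(0, 1))
    for r in reversed(regs):
        lit: BoolExpr = Var(r) if rng.randint(0, 1) else Not(Var(r))
        if rng.randint(0, 1):          # canalized value 1: lit | rest
            expr = lit if expr == Const(0) else (
                Const(1) if expr == Const(1) else Or(lit, expr))
        else:                          # canalized value 0: lit & rest
            expr = lit if expr == Const(1) else (
                Const(0) if expr == Const(0) else And(lit, expr))
    return expr


def _sign_respecting(rng: random.Random, regs: Sequence[str]) -> BoolExpr:
    signs = [rng.randint(0, 1) for _ in regs]   # 1 = activator
    if not any(signs):
        signs[rng.randrange(len(signs))] = 1    # at least one activator
    acts = [Var(r) for r, s in zip(regs, signs) if s]
    inhs = [Var(r) for r, s in zip(regs, signs) if not s]
    act: BoolExpr = acts[0] if len(acts) == 1 else Or(*acts)
    if not inhs:
        return act
    inh: BoolExpr = inhs[0] if len(inhs) == 1 else Or(*inhs)
    return And(act, Not(inh))


def generate_random_network(spec: RandomNetSpec) -> BooleanNetwork:
    """Draw a random Boolean network reproducibly from ``spec.seed``.

    Each node receives k regulators sampled without replacement from the
    other nodes and a rule built per ``spec.rule_scheme``.
    """
    rng = random.Random(spec.seed)
    nodes = tuple(f"n{i}" for i in range(spec.n_nodes))
    lo, hi = spec.k_range()
    builder = {"random-truth-table": _random_truth_table,
               "nested-canalizing": _nested_canalizing,
               "sign-respecting": _sign_respecting}[spec.rule_scheme]
    rules: Dict[str, BoolExpr] = {}
    for node in nodes:
        k = rng.randint(lo, hi)
        pool = [n for n in nodes if n != node]
        regs = [pool[i] for i in sorted(rng.sample(range(len(pool)), k))]
        rules[node] = builder(rng, regs)
    return BooleanNetwork(
        nodes, rules,
        label=f"random_{spec.rule_scheme}_n{spec.n_nodes}_seed{spec.seed}")


def canonical_fixtures() -> Dict[str, BooleanNetwork]:
    """Small networks with analytically known synchronous attractors.

    toggle_switch      A=!B, B=!A: fixed points (0,1),(1,0) plus the
                       2-cycle (0,0)<->(1,1);
    negation_loop      A=!A: a single 2-cycle, no fixed point;
    constant_cascade   A=1, B=A, C=B: unique fixed point (1,1,1);
    repressilator      3-ring of inhibitions: no fixed point (all six
                       states outside the two 'steady' candidates cycle);
    clamp_readout      input + processing pair + readout, for exercising
                       clamping semantics.
    """
    def net(label, text_rules):
        nodes = tuple(n for n, _ in text_rules)
        from .logic import parse_rule
        return BooleanNetwork(
            nodes, {n: parse_rule(r, nodes) for n, r in text_rules}, label=label)

    return {
        "toggle_switch": net("toggle_switch", [("A", "!B"), ("B", "!A")]),
        "negation_loop": net("negation_loop", [("A", "!A")]),
        "constant_cascade": net("constant_cascade",
                                [("A", "1"), ("B", "A"), ("C", "B")]),
        "repressilator": net("repressilator",
                             [("A", "!C"), ("B", "!A"), ("C", "!B")]),
        "clamp_readout": net("clamp_readout",
                             [("In", "In"), ("X", "In & !Y"),
                              ("Y", "!In"), ("Out", "X | Y")]),
    }
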