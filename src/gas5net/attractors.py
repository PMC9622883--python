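"""Attractor computation for synchronous Boolean networks.

Fixed points (stable states) are the states ``s`` with ``step(s) = s``;
under the synchronous scheme they coincide with asynchronous stable
states, which :func:`verify_fixed_point_asynchronous` exploits as a
soundness check.  Two complete fixed-point routes are provided:

* :func:`find_fixed_points_exhaustive` enumerates the full state space
  (only sensible for small n);
* :func:`find_fixed_points_constraint` solves the conjunction of the
  per-node constraints ``v == rule_v(s)`` by three-valued unit
  propagation plus branching, and scales to the 26-node checkpoint model.

Cyclic attractors of small networks come from the synchronous state
transition graph (STG): the successor map is a function, so the terminal
strongly-connected components are exactly the cycles reached by iterating
the map, found by :func:`find_attractors_small`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Dict, List, Optional, Sequence, Tuple

from .logic import BooleanNetwork, NetworkError, NetworkState

__all__ = [
    "AttractorReport", "NetworkTooLargeError",
    "find_fixed_points_exhaustive", "find_fixed_points_constraint",
    "find_attractors_small", "verify_fixed_point_asynchronous",
]

EXHAUSTIVE_CAP = 22
STG_CAP = 16


class NetworkTooLargeError(NetworkError):
    """Node count exceeds the cap of the requested (enumerative) method."""


@dataclass
class AttractorReport:
    """Attractors of one network: fixed points and (optionally) cycles.

    Fixed points are states (node -> 0/1); cycles are closed state
    sequences starting from their lexicographically smallest state.  Both
    are sorted lexicographically over the canonical node order, so the
    report is a pure function of the network.
    """

    network_label: str
    nodes: Tuple[str, ...]
    fixed_points: List[NetworkState]
    cycles: List[List[NetworkState]] = field(default_factory=list)
    method: str = "exhaustive"

    @property
    def n_fixed_points(self) -> int:
        return len(self.fixed_points)

    def fixed_point_bits(self) -> List[Tuple[int, ...]]:
        return [tuple(s[n] for n in self.nodes) for s in self.fixed_points]


def _sorted_states(net: BooleanNetwork,
                   bits: Sequence[Tuple[int, ...]]) -> List[NetworkState]:
    return [net.bits_to_state(b) for b in sorted(set(bits))]


def find_fixed_points_exhaustive(net: BooleanNetwork,
                                 cap: int = EXHAUSTIVE_CAP) -> AttractorReport:
    """All synchronous fixed points by full state-space enumeration."""
    n = len(net.nodes)
    if n > cap:
        raise NetworkTooLargeError(
            f"{n} nodes exceeds the exhaustive cap of {cap}; "
            "use find_fixed_points_constraint")
    step, _ = net.compiled()
    hits = [bits for bits in product((0, 1), repeat=n) if step(bits) == bits]
    return AttractorReport(net.label, net.nodes, _sorted_states(net, hits),
                           method="exhaustive")


# ---------------------------------------------------------------------------
# Constraint solver: unit propagation + branching (complete)
# ---------------------------------------------------------------------------

def _propagate(net: BooleanNetwork, assign: Dict[str, Optional[int]]) -> bool:
    """Fixed-point propagation: force v = rule_v wherever determined.

    Returns False on contradiction.  Loops until no rule's three-valued
    evaluation pins down a new node.
    """
    changed = True
    while changed:
        changed = False
        for node in net.nodes:
            want = net.rules[node].evaluate_partial(assign)
            if want is None:
                continue
            have = assign[node]
            if have is None:
                assign[node] = want
                changed = True
            elif have != want:
                return False
    return True


def find_fixed_points_constraint(net: BooleanNetwork) -> AttractorReport:
    """All synchronous fixed points by complete constraint search.

    Solves ``AND_v (v == rule_v(s))``.  Branches on the undetermined node
    whose value occurs in the most still-unresolved rules (any complete
    heuristic gives the same set; output is order-normalized).
    """
    found: List[Tuple[int, ...]] = []
    dependents: Dict[str, List[str]] = {n: [] for n in net.nodes}
    for target in net.nodes:
        for reg in net.regulators(target):
            dependents[reg].append(target)

    def choose(assign: Dict[str, Optional[int]]) -> Optional[str]:
        best, best_score = None, -1
        for n in net.nodes:
            if assign[n] is not None:
                continue
            score = sum(1 for t in dependents[n] if assign[t] is None)
            if score > best_score:
                best, best_score = n, score
        return best

    def search(assign: Dict[str, Optional[int]]) -> None:
        if not _propagate(net, assign):
            return
        branch = choose(assign)
        if branch is None:
            # total assignment; propagation guarantees consistency, but
            # re-check defensively so soundness never rests on it
            bits = tuple(assign[n] for n in net.nodes)  # type: ignore[misc]
            step, _ = net.compiled()
            if step(bits) == bits:
                found.append(bits)
            return
        for value in (0, 1):
            child = dict(assign)
            child[branch] = value
            search(child)

    search({n: None for n in net.nodes})
    return AttractorReport(net.label, net.nodes, _sorted_states(net, found),
                           method="constraint")


# ---------------------------------------------------------------------------
# Full STG attractors (small networks)
# ---------------------------------------------------------------------------

def find_attractors_small(net: BooleanNetwork, cap: int = STG_CAP) -> AttractorReport:
    """Fixed points and cycles from the full synchronous STG.

    The synchronous successor map is a function on 2^n states, so every
    terminal SCC is a simple cycle (length 1 = fixed point).  Each state's
    trajectory is walked until it re-enters a known component.
    """
    n = len(net.nodes)
    if n > cap:
        raise NetworkTooLargeError(
            f"{n} nodes exceeds the STG cap of {cap}")
    step, _ = net.compiled()
    color: Dict[Tuple[int, ...], int] = {}   # 1 = on current path, 2 = done
    fixed: List[Tuple[int, ...]] = []
    cycles: List[List[Tuple[int, ...]]] = []

    for start in product((0, 1), repeat=n):
        if start in color:
            continue
        path: List[Tuple[int, ...]] = []
        s = start
        while s not in color:
            color[s] = 1
            path.append(s)
            s = step(s)
        if color[s] == 1:  # new cycle discovered on this walk
            k = path.index(s)
            cyc = path[k:]
            if len(cyc) == 1:
                fixed.append(cyc[0])
            else:
                m = cyc.index(min(cyc))  # rotate to lexicographic start
                cycles.append(cyc[m:] + cyc[:m])
        for v in path:
            color[v] = 2

    cycles.sort(key=lambda c: c[0])
    return AttractorReport(
        net.label, net.nodes, _sorted_states(net, fixed),
        cycles=[[net.bits_to_state(b) for b in c] for c in cycles],
        method="exhaustive")


def verify_fixed_point_asynchronous(net: BooleanNetwork,
                                    state: NetworkState) -> int:
    """1 iff updating each node individually leaves ``state`` unchanged.

    Synchronous and asynchronous fixed points coincide, so this must hold
    for every reported fixed point.
    """
    net.check_state(state)
    for node in net.nodes:
        if net.rules[node].evaluate(state) != state[node]:
            return 0
    return 1
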