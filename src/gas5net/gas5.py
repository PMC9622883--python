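"""The 26-node lncRNA-GAS5 G1/S-checkpoint model and its perturbation suite.

The packaged network couples DNA-damage signalling (ATM -> p38 MAPK), the
lncRNA-GAS5 -> E2F1 -| miR-34c axis, the p53 arrester/killer switch
(p53-A / p53-K governed by Wip1 and p53-INP1) and the p53-independent
p21/caspase decision, with three phenotype readouts: proliferation, cell
cycle arrest and apoptosis.  Knockdown (KO) clamps a node OFF, ectopic
expression (E1) clamps it ON; the DNA-damage input is never clamped and
every scenario is evaluated at both input values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import yaml

from .attractors import AttractorReport, find_fixed_points_constraint
from .logic import (BooleanNetwork, NetworkError, NetworkState, Perturbation,
                    apply_perturbation)
from . import io as bnet_io

__all__ = [
    "EXPECTED_NODE_COUNT", "EXPECTED_EDGE_COUNT", "INPUT_NODE", "OUTPUT_NODES",
    "ModelIntegrityError", "Gas5ModelDefinition", "PhenotypeCall",
    "Expectation", "ScenarioSpec", "ScenarioResult", "SuiteResult",
    "load_gas5_model", "load_scenarios", "classify_phenotype",
    "validate_gas5_network",
    "run_scenario", "run_full_suite",
]

EXPECTED_NODE_COUNT = 26
EXPECTED_EDGE_COUNT = 73
INPUT_NODE = "DNA_damage"
OUTPUT_NODES = ("Proliferation", "CellCycleArrest", "Apoptosis")

DAMAGE_VALUES = {"off": 0, "on": 1}


class ModelIntegrityError(NetworkError):
    """The loaded model violates the published structural counts/roles."""


# ---------------------------------------------------------------------------
# Model definition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gas5ModelDefinition:
    network: BooleanNetwork
    display_names: Mapping[str, str]
    node_roles: Mapping[str, str]  # input | regulator | output

    @property
    def outputs(self) -> Tuple[str, ...]:
        return tuple(n for n in self.network.nodes
                     if self.node_roles[n] == "output")


def _data_text(name: str) -> str:
    return (resources.files("gas5net") / "data" / name).read_text("utf-8")


def _load_node_metadata() -> Tuple[Dict[str, str], Dict[str, str]]:
    display: Dict[str, str] = {}
    roles: Dict[str, str] = {}
    for line in _data_text("gas5_gc_nodes.tsv").splitlines()[1:]:
        if not line.strip():
            continue
        node, name, role = line.split("\t")
        display[node], roles[node] = name, role
    return display, roles


def validate_gas5_network(net: BooleanNetwork,
                          roles: Optional[Mapping[str, str]] = None) -> None:
    """Assert the published structural counts and roles on ``net``.

    Raises ModelIntegrityError unless the network has 26 nodes, 73
    rule-derived interactions, DNA damage as its unique free input, and
    the three phenotype readouts as outputs.
    """
    if roles is None:
        roles = _load_node_metadata()[1]
    if set(roles) != set(net.nodes):
        raise ModelIntegrityError("node metadata does not match the rule file")
    if len(net.nodes) != EXPECTED_NODE_COUNT:
        raise ModelIntegrityError(
            f"expected {EXPECTED_NODE_COUNT} nodes, found {len(net.nodes)}")
    if net.n_edges != EXPECTED_EDGE_COUNT:
        raise ModelIntegrityError(
            f"expected {EXPECTED_EDGE_COUNT} interactions, found {net.n_edges}")
    if net.input_nodes != (INPUT_NODE,):
        raise ModelIntegrityError(
            f"expected the unique input {INPUT_NODE!r}, found {net.input_nodes}")
    outputs = tuple(n for n in net.nodes if roles[n] == "output")
    if outputs != OUTPUT_NODES:
        raise ModelIntegrityError(
            f"expected outputs {OUTPUT_NODES}, found {outputs}")


def load_gas5_model() -> Gas5ModelDefinition:
    """Load and structurally validate the packaged checkpoint model.

    Fails loudly (ModelIntegrityError) if the node count, rule-derived
    edge count, input set or output set differ from the published
    26 / 73 / {DNA damage} / {proliferation, arrest, apoptosis}.
    """
    net = bnet_io.parse_bnet_text(_data_text("gas5_gc.bnet"), label="gas5_gc")
    display, roles = _load_node_metadata()
    validate_gas5_network(net, roles)
    return Gas5ModelDefinition(net, display, roles)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypeCall:
    label: str
    output_bits: Tuple[int, int, int]  # (Proliferation, CellCycleArrest, Apoptosis)


def classify_phenotype(state: NetworkState) -> PhenotypeCall:
    """Label a fixed point from its output bits.

    (1,0,0) -> proliferative; apoptosis dominates arrest for damage-driven
    fates ((0,0,1) and (0,1,1) -> apoptotic, (0,1,0) -> arrest);
    (0,0,0) -> null; proliferation together with a damage fate -> mixed
    (never exhibited by the shipped model).
    """
    bits = tuple(int(state[n]) for n in OUTPUT_NODES)
    prolif, arrest, apop = bits
    if prolif and not arrest and not apop:
        label = "proliferative"
    elif prolif:
        label = "mixed"
    elif apop:
        label = "apoptotic"
    elif arrest:
        label = "arrest"
    else:
        label = "null"
    return PhenotypeCall(label, bits)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Expectation:
    """One qualitative assertion about the fixed points at one input value.

    kind: 'count' (number of fixed points), 'phenotypes' (sorted labels)
    or 'node' (a node value holding in scope 'all', 'any' or
    'phenotype:<label>' fixed points).
    """

    kind: str
    damage: int
    node: Optional[str] = None
    value: Optional[int] = None
    equals: Optional[object] = None
    scope: str = "all"

    def describe(self) -> str:
        inp = "damage ON" if self.damage else "damage OFF"
        if self.kind == "count":
            return f"[{inp}] fixed-point count = {self.equals}"
        if self.kind == "phenotypes":
            return f"[{inp}] phenotypes = {sorted(self.equals)}"
        return f"[{inp}] {self.node}={self.value} in {self.scope} fixed points"


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    perturbation: Perturbation
    expectations: Tuple[Expectation, ...] = ()
    note: str = ""


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    reports: Dict[int, AttractorReport]            # damage value -> report
    phenotypes: Dict[int, List[PhenotypeCall]]
    verdicts: List[Tuple[str, bool]]

    @property
    def n_failed(self) -> int:
        return sum(1 for _, ok in self.verdicts if not ok)

    def all_fixed_points(self) -> List[Tuple[int, NetworkState, PhenotypeCall]]:
        out = []
        for damage in (0, 1):
            for s, ph in zip(self.reports[damage].fixed_points,
                             self.phenotypes[damage]):
                out.append((damage, s, ph))
        return out


def _parse_expectation(raw: Mapping) -> Expectation:
    damage = raw["damage"]
    if isinstance(damage, str):
        damage = DAMAGE_VALUES[damage.lower()]
    return Expectation(kind=raw["kind"], damage=int(damage),
                       node=raw.get("node"), value=raw.get("value"),
                       equals=raw.get("equals"), scope=raw.get("scope", "all"))


def load_scenarios(path: Optional[Union[str, Path]] = None) -> List[ScenarioSpec]:
    """Load the packaged (or a user-supplied) YAML scenario suite."""
    text = Path(path).read_text("utf-8") if path else _data_text("scenarios.yaml")
    doc = yaml.safe_load(text)
    specs: List[ScenarioSpec] = []
    seen = set()
    for raw in doc["scenarios"]:
        name = raw["name"]
        if name in seen:
            raise NetworkError(f"duplicate scenario name {name!r}")
        seen.add(name)
        clamps = {k: int(v) for k, v in (raw.get("clamps") or {}).items()}
        if INPUT_NODE in clamps:
            raise NetworkError(
                f"scenario {name!r} clamps the input {INPUT_NODE!r}; "
                "both input values are always run instead")
        specs.append(ScenarioSpec(
            name=name,
            perturbation=Perturbation(clamps, label=name),
            expectations=tuple(_parse_expectation(e)
                               for e in raw.get("expectations") or ()),
            note=(raw.get("note") or "").strip()))
    return specs


def _check_expectation(exp: Expectation, report: AttractorReport,
                       phenos: List[PhenotypeCall]) -> bool:
    if exp.kind == "count":
        return report.n_fixed_points == exp.equals
    if exp.kind == "phenotypes":
        return sorted(p.label for p in phenos) == sorted(exp.equals)
    if exp.kind == "node":
        values = [s[exp.node] for s in report.fixed_points]
        if exp.scope == "all":
            return bool(values) and all(v == exp.value for v in values)
        if exp.scope == "any":
            return any(v == exp.value for v in values)
        if exp.scope.startswith("phenotype:"):
            want = exp.scope.split(":", 1)[1]
            hits = [v for v, p in zip(values, phenos) if p.label == want]
            return bool(hits) and all(v == exp.value for v in hits)
        raise NetworkError(f"unknown expectation scope {exp.scope!r}")
    raise NetworkError(f"unknown expectation kind {exp.kind!r}")


def run_scenario(model: Gas5ModelDefinition, spec: ScenarioSpec,
                 solver=find_fixed_points_constraint) -> ScenarioResult:
    """Apply the perturbation, compute fixed points for both input values,
    classify phenotypes and evaluate every expectation."""
    net = model.network
    for node in spec.perturbation.clamps:
        if node not in net.rules:
            raise NetworkError(f"scenario {spec.name!r} clamps unknown node {node!r}")
    reports: Dict[int, AttractorReport] = {}
    phenos: Dict[int, List[PhenotypeCall]] = {}
    for damage in (0, 1):
        clamps = dict(spec.perturbation.clamps)
        clamps[INPUT_NODE] = damage  # fixing the free input closes the dynamics
        label = f"{spec.name}, damage={'ON' if damage else 'OFF'}"
        perturbed = apply_perturbation(net, Perturbation(clamps, label=label))
        report = solver(perturbed)
        report.network_label = label
        reports[damage] = report
        phenos[damage] = [classify_phenotype(s) for s in report.fixed_points]
    verdicts = [(e.describe(), _check_expectation(e, reports[e.damage],
                                                  phenos[e.damage]))
                for e in spec.expectations]
    return ScenarioResult(spec, reports, phenos, verdicts)


# ---------------------------------------------------------------------------
# Full suite
# ---------------------------------------------------------------------------

@dataclass
class SuiteResult:
    model: Gas5ModelDefinition
    results: List[ScenarioResult]

    @property
    def n_failed(self) -> int:
        return sum(r.n_failed for r in self.results)

    def to_tsv(self) -> str:
        """Consolidated fixed-point table (one row per scenario fixed point)."""
        nodes = self.model.network.nodes
        header = ["scenario", "attractor_id", "type",
                  f"input_{INPUT_NODE}", "phenotype"] + list(nodes)
        rows = ["\t".join(header)]
        for res in self.results:
            aid = 0
            for damage, state, ph in res.all_fixed_points():
                aid += 1
                rows.append("\t".join(
                    [res.spec.name, f"fp{aid}", "fixed_point",
                     str(damage), ph.label] + [str(state[n]) for n in nodes]))
        return "\n".join(rows) + "\n"

    def verdicts_tsv(self) -> str:
        rows = ["\t".join(["scenario", "expectation", "status"])]
        for res in self.results:
            for desc, ok in res.verdicts:
                rows.append("\t".join([res.spec.name, desc,
                                       "pass" if ok else "FAIL"]))
        return "\n".join(rows) + "\n"

    def to_text(self) -> str:
        """Plain-text heatmap of every fixed point (1 = active, . = inactive)."""
        nodes = self.model.network.nodes
        width = max(len(n) for n in nodes)
        lines = []
        for d in range(width):
            lines.append(" " * 34 + " ".join((" " * (width - len(n)) + n)[d]
                                             for n in nodes))
        for res in self.results:
            aid = 0
            for damage, state, ph in res.all_fixed_points():
                aid += 1
                tag = f"{res.spec.name} fp{aid} [{'ON ' if damage else 'OFF'}] {ph.label}"
                cells = " ".join("1" if state[n] else "." for n in nodes)
                lines.append(f"{tag:<34}" + cells)
            if res.spec.note:
                lines.append(f"  note ({res.spec.name}): {res.spec.note}")
        failed = self.n_failed
        lines.append(f"expectations: "
                     f"{sum(len(r.verdicts) for r in self.results) - failed} passed, "
                     f"{failed} failed")
        return "\n".join(lines) + "\n"


def run_full_suite(model: Optional[Gas5ModelDefinition] = None,
                   scenario_names: Optional[Sequence[str]] = None,
                   scenarios_path: Optional[Union[str, Path]] = None,
                   solver=find_fixed_points_constraint) -> SuiteResult:
    """Run WT plus the named perturbation scenarios; nothing is swallowed:
    every expectation verdict is reported."""
    model = model or load_gas5_model()
    specs = load_scenarios(scenarios_path)
    if scenario_names is not None:
        known = {s.name: s for s in specs}
        unknown = [n for n in scenario_names if n not in known]
        if unknown:
            raise NetworkError(f"unknown scenario name(s): {unknown}")
        specs = [known[n] for n in scenario_names]
    return SuiteResult(model, [run_scenario(model, s, solver=solver)
                               for s in specs])
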