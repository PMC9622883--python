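"""Reading/writing the ``.bnet`` dialect and diff-stable attractor reports.

Model files follow the BoolNet-style plain-text layout::

    targets, factors
    # comment
    NodeA, NodeB & !NodeC
    NodeB, 1

One rule per node, ``#`` comments, UTF-8.  Everything written back out is
a pure function of its inputs (fixed ordering, no floats), so reruns are
byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

from .attractors import AttractorReport
from .logic import (BooleanNetwork, NetworkError, RuleSyntaxError,
                    UnknownNodeError, parse_rule)

__all__ = [
    "read_bnet", "parse_bnet_text", "write_bnet", "network_to_bnet_text",
    "report_to_tsv", "report_to_heatmap", "write_report",
]

log = logging.getLogger("gas5net")

_HEADER = "targets, factors"


def parse_bnet_text(text: str, label: str = "network") -> BooleanNetwork:
    """Parse ``.bnet`` content.  Errors carry 1-based line numbers."""
    entries: List[tuple] = []  # (line_no, target, rule_text)
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower().replace(" ", "") == _HEADER.replace(" ", ""):
            continue
        if "," not in line:
            raise RuleSyntaxError("expected 'target, expression'", 0, line_no)
        target, rule_text = line.split(",", 1)
        target = target.strip()
        if not target:
            raise RuleSyntaxError("empty target name", 0, line_no)
        entries.append((line_no, target, rule_text.strip()))

    if not entries:
        raise NetworkError(f"no rules found in {label}")
    nodes = [t for _, t, _ in entries]
    seen = set()
    for line_no, t, _ in entries:
        if t in seen:
            raise RuleSyntaxError(f"duplicate rule for {t!r}", 0, line_no)
        seen.add(t)
    rules = {}
    for line_no, target, rule_text in entries:
        rules[target] = parse_rule(rule_text, known_nodes=nodes, line=line_no)
    return BooleanNetwork(tuple(nodes), rules, label=label)


def read_bnet(path: Union[str, Path]) -> BooleanNetwork:
    path = Path(path)
    return parse_bnet_text(path.read_text(encoding="utf-8"), label=path.stem)


def network_to_bnet_text(net: BooleanNetwork) -> str:
    lines = [_HEADER]
    lines += [f"{n}, {net.rules[n].to_text()}" for n in net.nodes]
    return "\n".join(lines) + "\n"


def write_bnet(net: BooleanNetwork, path: Union[str, Path]) -> None:
    Path(path).write_text(network_to_bnet_text(net), encoding="utf-8")


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def report_to_tsv(report: AttractorReport,
                  phenotypes: Optional[Sequence[str]] = None,
                  input_node: Optional[str] = None) -> str:
    """One row per attractor state, one column per node.

    Columns: ``attractor_id``, ``type``, optionally ``input_<node>`` and
    ``phenotype``, then every node in canonical order.  Cycles contribute
    one row per member state under a shared id.
    """
    if phenotypes is not None and len(phenotypes) != len(report.fixed_points):
        raise NetworkError("one phenotype label per fixed point required")
    header = ["attractor_id", "type"]
    if input_node is not None:
        header.append(f"input_{input_node}")
    if phenotypes is not None:
        header.append("phenotype")
    header += list(report.nodes)

    rows = ["\t".join(header)]
    aid = 0
    for k, state in enumerate(report.fixed_points):
        aid += 1
        row = [f"fp{aid}", "fixed_point"]
        if input_node is not None:
            row.append(str(state[input_node]))
        if phenotypes is not None:
            row.append(phenotypes[k])
        row += [str(state[n]) for n in report.nodes]
        rows.append("\t".join(row))
    for k, cycle in enumerate(report.cycles, start=1):
        for state in cycle:
            row = [f"cycle{k}", f"cycle_len{len(cycle)}"]
            if input_node is not None:
                row.append(str(state[input_node]))
            if phenotypes is not None:
                row.append("-")
            row += [str(state[n]) for n in report.nodes]
            rows.append("\t".join(row))
    return "\n".join(rows) + "\n"


def report_to_heatmap(report: AttractorReport,
                      labels: Optional[Sequence[str]] = None) -> str:
    """Plain-text heatmap: rows = attractor states, columns = nodes.

    ``1`` marks an active node, ``.`` an inactive one — the textual twin
    of a purple/light-purple fixed-point heatmap.
    """
    nodes = report.nodes
    name_w = max([len("state")] + [len(n) for n in nodes])
    lines = []
    # vertical node names, one character row per needed line
    depth = name_w
    for d in range(depth):
        cells = []
        for n in nodes:
            pad = " " * (depth - len(n))
            padded = pad + n
            cells.append(padded[d])
        lines.append("         " + " ".join(cells))
    aid = 0
    for k, state in enumerate(report.fixed_points):
        aid += 1
        label = labels[k] if labels else f"fp{aid}"
        cells = " ".join("1" if state[n] else "." for n in nodes)
        lines.append(f"{label:>8} " + cells)
    for k, cycle in enumerate(report.cycles, start=1):
        for j, state in enumerate(cycle):
            cells = " ".join("1" if state[n] else "." for n in nodes)
            lines.append(f"{f'cy{k}.{j}':>8} " + cells)
    return "\n".join(lines) + "\n"


def write_report(report: AttractorReport, path: Union[str, Path],
                 phenotypes: Optional[Sequence[str]] = None,
                 input_node: Optional[str] = None) -> None:
    """Write the TSV report plus an adjacent ``.heatmap.txt`` rendering."""
    path = Path(path)
    path.write_text(report_to_tsv(report, phenotypes, input_node),
                    encoding="utf-8")
    heat = path.with_suffix(path.suffix + ".heatmap.txt") \
        if path.suffix != ".tsv" else path.with_name(path.stem + ".heatmap.txt")
    heat.write_text(report_to_heatmap(report), encoding="utf-8")
    n = report.n_fixed_points
    if n == 0 and not report.cycles:
        log.info("%s: 0 attractors", report.network_label)
    else:
        log.info("%s: %d fixed point(s), %d cycle(s) -> %s",
                 report.network_label, n, len(report.cycles), path)
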