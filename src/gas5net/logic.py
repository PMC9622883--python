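"""Boolean expressions, networks, synchronous dynamics and clamping.

A Boolean (logical) model of a gene-regulatory network assigns every
molecule a binary activity value (0 = OFF, 1 = ON) and one update rule
written with AND/OR/NOT over the activities of its regulators.  Under the
synchronous scheme all nodes recompute simultaneously from the current
state, so the dynamics is a deterministic map on the finite state space
{0,1}^n.  In-silico perturbations (knockdown / ectopic expression) clamp a
node to a constant, replacing its rule.

Rule text follows the BoolNet-style grammar::

    expr   := term ('|' term)*          # OR, lowest precedence
    term   := factor ('&' factor)*      # AND
    factor := '!' factor | '(' expr ')' | '0' | '1' | identifier

``AND``/``OR``/``NOT`` keywords are accepted as synonyms of ``&``/``|``/``!``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

__all__ = [
    "BoolExpr", "Var", "Const", "Not", "And", "Or",
    "BooleanNetwork", "Perturbation",
    "parse_rule", "evaluate", "synchronous_step", "apply_perturbation",
    "RuleSyntaxError", "UnknownNodeError", "NetworkError",
]

NetworkState = Dict[str, int]


class NetworkError(ValueError):
    """Structural problem with a network or state."""


class RuleSyntaxError(NetworkError):
    """Malformed rule text; carries the 0-based character position."""

    def __init__(self, message: str, position: int, line: Optional[int] = None):
        self.position = position
        self.line = line
        where = f" at position {position}"
        if line is not None:
            where += f" (line {line})"
        super().__init__(message + where)


class UnknownNodeError(NetworkError):
    """A rule references an identifier that is not a declared node."""

    def __init__(self, name: str, line: Optional[int] = None):
        self.name = name
        self.line = line
        where = f" (line {line})" if line is not None else ""
        super().__init__(f"unknown node {name!r}{where}")


# ---------------------------------------------------------------------------
# Expression AST
# ---------------------------------------------------------------------------

class BoolExpr:
    """Base class for Boolean expression trees."""

    def variables(self) -> FrozenSet[str]:
        raise NotImplementedError

    def evaluate(self, state: Mapping[str, int]) -> int:
        """Standard Boolean semantics; raises KeyError text on missing vars."""
        raise NotImplementedError

    def evaluate_partial(self, state: Mapping[str, int]) -> Optional[int]:
        """Three-valued (Kleene) evaluation; None means undetermined."""
        raise NotImplementedError

    def to_text(self) -> str:
        """Serialize; ``parse_rule`` on the result yields an equivalent tree."""
        raise NotImplementedError

    def _py(self, index: Mapping[str, int]) -> str:
        """Python source fragment over a tuple ``s`` (used for compiled eval)."""
        raise NotImplementedError

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_text()


@dataclass(frozen=True)
class Var(BoolExpr):
    name: str

    def variables(self):
        return frozenset((self.name,))

    def evaluate(self, state):
        try:
            return int(state[self.name])
        except KeyError:
            raise NetworkError(f"state is missing a value for node {self.name!r}")

    def evaluate_partial(self, state):
        v = state.get(self.name)
        return None if v is None else int(v)

    def to_text(self):
        return self.name

    def _py(self, index):
        return f"s[{index[self.name]}]"


@dataclass(frozen=True)
class Const(BoolExpr):
    value: int

    def __post_init__(self):
        if self.value not in (0, 1):
            raise NetworkError(f"constant must be 0 or 1, got {self.value!r}")

    def variables(self):
        return frozenset()

    def evaluate(self, state):
        return self.value

    def evaluate_partial(self, state):
        return self.value

    def to_text(self):
        return str(self.value)

    def _py(self, index):
        return str(self.value)


@dataclass(frozen=True)
class Not(BoolExpr):
    child: BoolExpr

    def variables(self):
        return self.child.variables()

    def evaluate(self, state):
        return 1 - self.child.evaluate(state)

    def evaluate_partial(self, state):
        v = self.child.evaluate_partial(state)
        return None if v is None else 1 - v

    def to_text(self):
        if isinstance(self.child, (Var, Const, Not)):
            return f"!{self.child.to_text()}"
        return f"!({self.child.to_text()})"

    def _py(self, index):
        return f"(1 - {self.child._py(index)})"


def _nary_init(children: Sequence[BoolExpr], kind: str) -> Tuple[BoolExpr, ...]:
    children = tuple(children)
    if len(children) < 2:
        raise NetworkError(f"{kind} requires at least 2 operands")
    return children


@dataclass(frozen=True)
class And(BoolExpr):
    children: Tuple[BoolExpr, ...]

    def __init__(self, *children: BoolExpr):
        if len(children) == 1 and isinstance(children[0], (tuple, list)):
            children = tuple(children[0])
        object.__setattr__(self, "children", _nary_init(children, "AND"))

    def variables(self):
        return frozenset().union(*(c.variables() for c in self.children))

    def evaluate(self, state):
        for c in self.children:
            if not c.evaluate(state):
                return 0
        return 1

    def evaluate_partial(self, state):
        out: Optional[int] = 1
        for c in self.children:
            v = c.evaluate_partial(state)
            if v == 0:
                return 0
            if v is None:
                out = None
        return out

    def to_text(self):
        parts = []
        for c in self.children:
            t = c.to_text()
            parts.append(f"({t})" if isinstance(c, Or) else t)
        return " & ".join(parts)

    def _py(self, index):
        return "(" + " and ".join(c._py(index) for c in self.children) + ")"


@dataclass(frozen=True)
class Or(BoolExpr):
    children: Tuple[BoolExpr, ...]

    def __init__(self, *children: BoolExpr):
        if len(children) == 1 and isinstance(children[0], (tuple, list)):
            children = tuple(children[0])
        object.__setattr__(self, "children", _nary_init(children, "OR"))

    def variables(self):
        return frozenset().union(*(c.variables() for c in self.children))

    def evaluate(self, state):
        for c in self.children:
            if c.evaluate(state):
                return 1
        return 0

    def evaluate_partial(self, state):
        out: Optional[int] = 0
        for c in self.children:
            v = c.evaluate_partial(state)
            if v == 1:
                return 1
            if v is None:
                out = None
        return out

    def to_text(self):
        return " | ".join(c.to_text() for c in self.children)

    def _py(self, index):
        return "(" + " or ".join(c._py(index) for c in self.children) + ")"


# ---------------------------------------------------------------------------
# Parser: hand-rolled recursive descent with exact error positions
# ---------------------------------------------------------------------------

_IDENT_START = set("ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz_")
_IDENT_CONT = _IDENT_START | set("0123456789")


class _Tok:
    __slots__ = ("kind", "text", "pos")

    def __init__(self, kind, text, pos):
        self.kind, self.text, self.pos = kind, text, pos


def _tokenize(text: str, line: Optional[int]) -> List[_Tok]:
    toks: List[_Tok] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch in " \t":
            i += 1
            continue
        if ch in "&|!()":
            kind = {"&": "AND", "|": "OR", "!": "NOT", "(": "LP", ")": "RP"}[ch]
            toks.append(_Tok(kind, ch, i))
            i += 1
        elif ch in "01" and (i + 1 == n or text[i + 1] not in _IDENT_CONT):
            toks.append(_Tok("CONST", ch, i))
            i += 1
        elif ch in _IDENT_START:
            j = i + 1
            while j < n and text[j] in _IDENT_CONT:
                j += 1
            word = text[i:j]
            upper = word.upper()
            if upper == "AND":
                toks.append(_Tok("AND", word, i))
            elif upper == "OR":
                toks.append(_Tok("OR", word, i))
            elif upper == "NOT":
                toks.append(_Tok("NOT", word, i))
            else:
                toks.append(_Tok("IDENT", word, i))
            i = j
        else:
            raise RuleSyntaxError(f"unexpected character {ch!r}", i, line)
    toks.append(_Tok("EOF", "", n))
    return toks


class _Parser:
    def __init__(self, toks: List[_Tok], known: Optional[Iterable[str]], line):
        self.toks = toks
        self.i = 0
        self.known = None if known is None else set(known)
        self.line = line

    def peek(self) -> _Tok:
        return self.toks[self.i]

    def take(self) -> _Tok:
        tok = self.toks[self.i]
        self.i += 1
        return tok

    def parse(self) -> BoolExpr:
        expr = self.expr()
        tok = self.peek()
        if tok.kind != "EOF":
            raise RuleSyntaxError(f"unexpected {tok.text!r}", tok.pos, self.line)
        return expr

    def expr(self) -> BoolExpr:  # OR level
        parts = [self.term()]
        while self.peek().kind == "OR":
            self.take()
            parts.append(self.term())
        return parts[0] if len(parts) == 1 else Or(*parts)

    def term(self) -> BoolExpr:  # AND level
        parts = [self.factor()]
        while self.peek().kind == "AND":
            self.take()
            parts.append(self.factor())
        return parts[0] if len(parts) == 1 else And(*parts)

    def factor(self) -> BoolExpr:
        tok = self.take()
        if tok.kind == "NOT":
            return Not(self.factor())
        if tok.kind == "LP":
            inner = self.expr()
            closing = self.take()
            if closing.kind != "RP":
                raise RuleSyntaxError("expected ')'", closing.pos, self.line)
            return inner
        if tok.kind == "CONST":
            return Const(int(tok.text))
        if tok.kind == "IDENT":
            if self.known is not None and tok.text not in self.known:
                raise UnknownNodeError(tok.text, self.line)
            return Var(tok.text)
        raise RuleSyntaxError(
            f"expected an expression, got {tok.text or 'end of input'!r}",
            tok.pos, self.line)


def parse_rule(text: str, known_nodes: Optional[Iterable[str]] = None,
               line: Optional[int] = None) -> BoolExpr:
    """Parse one update-rule expression.

    NOT binds tighter than AND, which binds tighter than OR.  When
    ``known_nodes`` is given, any identifier outside it raises
    :class:`UnknownNodeError`.  ``line`` is only used to decorate errors.
    """
    if not text or not text.strip():
        raise RuleSyntaxError("empty rule", 0, line)
    return _Parser(_tokenize(text, line), known_nodes, line).parse()


def evaluate(expr: BoolExpr, state: Mapping[str, int]) -> int:
    """Evaluate ``expr`` on a (total) state; pure function of its inputs."""
    return expr.evaluate(state)


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BooleanNetwork:
    """An ordered set of named nodes with exactly one update rule each.

    The regulator set of a node is the set of variables occurring in its
    rule; the union over nodes of regulator->target pairs is the edge list
    of the regulatory graph (self-loops included).
    """

    nodes: Tuple[str, ...]
    rules: Mapping[str, BoolExpr]
    label: str = "network"

    def __post_init__(self):
        nodes = tuple(self.nodes)
        object.__setattr__(self, "nodes", nodes)
        if len(set(nodes)) != len(nodes):
            raise NetworkError("duplicate node names")
        missing = [n for n in nodes if n not in self.rules]
        if missing:
            raise NetworkError(f"nodes without a rule: {missing}")
        extra = [n for n in self.rules if n not in set(nodes)]
        if extra:
            raise NetworkError(f"rules for undeclared nodes: {extra}")
        declared = set(nodes)
        for n in nodes:
            dangling = self.rules[n].variables() - declared
            if dangling:
                raise UnknownNodeError(sorted(dangling)[0])

    # -- structure ---------------------------------------------------------

    def regulators(self, node: str) -> FrozenSet[str]:
        return self.rules[node].variables()

    def edges(self) -> List[Tuple[str, str]]:
        """Regulator->target pairs in canonical order."""
        out = []
        for target in self.nodes:
            for reg in sorted(self.regulators(target), key=self.nodes.index):
                out.append((reg, target))
        return out

    @property
    def n_edges(self) -> int:
        return sum(len(self.regulators(n)) for n in self.nodes)

    @property
    def input_nodes(self) -> Tuple[str, ...]:
        """Nodes whose rule is the identity on themselves (free inputs)."""
        return tuple(n for n in self.nodes if self.rules[n] == Var(n))

    # -- dynamics ----------------------------------------------------------

    def check_state(self, state: Mapping[str, int]) -> None:
        if set(state) != set(self.nodes):
            raise NetworkError("state keys must equal the node list")
        for n, v in state.items():
            if v not in (0, 1):
                raise NetworkError(f"state[{n!r}] = {v!r} is not 0/1")

    def compiled(self):
        """Per-node rule functions over a tuple state (canonical node order).

        Returns ``(step, per_node)`` where ``step(bits) -> bits`` is the
        synchronous map and ``per_node[i](bits) -> 0|1`` evaluates node i's
        rule.  Compiled once per network; results cached on the instance.
        """
        cache = getattr(self, "_compiled", None)
        if cache is not None:
            return cache
        index = {n: i for i, n in enumerate(self.nodes)}
        per_node = tuple(
            eval(compile(f"lambda s: 1 if {self.rules[n]._py(index)} else 0",
                         "<rule>", "eval"))
            for n in self.nodes
        )
        def step(bits: Tuple[int, ...]) -> Tuple[int, ...]:
            return tuple(f(bits) for f in per_node)
        object.__setattr__(self, "_compiled", (step, per_node))
        return step, per_node

    def state_to_bits(self, state: Mapping[str, int]) -> Tuple[int, ...]:
        return tuple(int(state[n]) for n in self.nodes)

    def bits_to_state(self, bits: Sequence[int]) -> NetworkState:
        return {n: int(b) for n, b in zip(self.nodes, bits)}


def synchronous_step(net: BooleanNetwork, state: Mapping[str, int]) -> NetworkState:
    """One synchronous update: every rule reads the *current* state."""
    net.check_state(state)
    return {n: net.rules[n].evaluate(state) for n in net.nodes}


# ---------------------------------------------------------------------------
# Perturbations (in-silico GoF / LoF)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Perturbation:
    """A set of node clamps: KO = clamp 0 (LoF), E1 = clamp 1 (GoF)."""

    clamps: Mapping[str, int]
    label: str = ""

    def __post_init__(self):
        for node, v in self.clamps.items():
            if v not in (0, 1):
                raise NetworkError(f"clamp value for {node!r} must be 0/1")

    def validate_for(self, net: BooleanNetwork) -> None:
        for node in self.clamps:
            if node not in net.rules:
                raise UnknownNodeError(node)


def apply_perturbation(net: BooleanNetwork, p: Perturbation) -> BooleanNetwork:
    """Return a new network with each clamped node's rule set to a constant.

    The original network is unmodified.  From the first update onward the
    clamped nodes hold their clamp value along every trajectory.
    """
    p.validate_for(net)
    rules = dict(net.rules)
    for node, v in p.clamps.items():
        rules[node] = Const(int(v))
    label = net.label if not p.label else f"{net.label}[{p.label}]"
    return BooleanNetwork(net.nodes, rules, label=label)
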