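"""Boolean network representation, rule parsing and the synchronous update step.

A network is a set of named nodes ``x_1..x_n``, one Boolean function per node
built from AND/OR/NOT and the constants 0/1, and an optional set of *fixed*
values (knockout = 0, knockin = 1) that override the function during
simulation.  Rule files follow the BoolNet plain-text convention::

    targets, factors
    A, B & !C
    B, A | C
    C, 1

Operators may be spelled ``&``/``|``/``!`` or ``AND``/``OR``/``NOT`` (any
case).  Node order is declaration order; in the integer encoding of a state,
node 0 occupies the least-significant bit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence


class ParseError(ValueError):
    """Raised for malformed rule files or expressions."""


# ---------------------------------------------------------------------------
# Expression AST
# ---------------------------------------------------------------------------


class Expr:
    """Base class for Boolean expressions."""

    def variables(self) -> frozenset[str]:
        raise NotImplementedError

    def evaluate(self, values: Mapping[str, int]) -> int:
        raise NotImplementedError

    def unparse(self) -> str:
        raise NotImplementedError

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"{type(self).__name__}({self.unparse()!r})"

    def __eq__(self, other) -> bool:
        return type(self) is type(other) and self._key() == other._key()

    def __hash__(self) -> int:
        return hash((type(self).__name__, self._key()))

    def _key(self):
        raise NotImplementedError


class Var(Expr):
    __slots__ = ("name",)

    def __init__(self, name: str):
        self.name = name

    def variables(self):
        return frozenset({self.name})

    def evaluate(self, values):
        return int(values[self.name])

    def unparse(self):
        return self.name

    def _key(self):
        return self.name


class Const(Expr):
    __slots__ = ("value",)

    def __init__(self, value: int):
        self.value = int(value)

    def variables(self):
        return frozenset()

    def evaluate(self, values):
        return self.value

    def unparse(self):
        return str(self.value)

    def _key(self):
        return self.value


class Not(Expr):
    __slots__ = ("arg",)

    def __init__(self, arg: Expr):
        self.arg = arg

    def variables(self):
        return self.arg.variables()

    def evaluate(self, values):
        return 1 - self.arg.evaluate(values)

    def unparse(self):
        inner = self.arg.unparse()
        if isinstance(self.arg, (And, Or)):
            return f"!({inner})"
        return f"!{inner}"

    def _key(self):
        return self.arg


class And(Expr):
    __slots__ = ("args",)

    def __init__(self, args: Sequence[Expr]):
        flat: list[Expr] = []
        for a in args:  # flatten nested conjunctions for a canonical form
            flat.extend(a.args if isinstance(a, And) else (a,))
        self.args = tuple(flat)

    def variables(self):
        return frozenset().union(*(a.variables() for a in self.args))

    def evaluate(self, values):
        return int(all(a.evaluate(values) for a in self.args))

    def unparse(self):
        parts = []
        for a in self.args:
            s = a.unparse()
            if isinstance(a, Or):
                s = f"({s})"
            parts.append(s)
        return " & ".join(parts)

    def _key(self):
        return self.args


class Or(Expr):
    __slots__ = ("args",)

    def __init__(self, args: Sequence[Expr]):
        flat: list[Expr] = []
        for a in args:  # flatten nested disjunctions for a canonical form
            flat.extend(a.args if isinstance(a, Or) else (a,))
        self.args = tuple(flat)

    def variables(self):
        return frozenset().union(*(a.variables() for a in self.args))

    def evaluate(self, values):
        return int(any(a.evaluate(values) for a in self.args))

    def unparse(self):
        return " | ".join(a.unparse() for a in self.args)

    def _key(self):
        return self.args


# ---------------------------------------------------------------------------
# Expression parser (precedence: ! > & > |)
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<not>!|\bNOT\b)|(?P<and>&+|\bAND\b)"
    r"|(?P<or>\|+|\bOR\b)|(?P<const>\b[01]\b)|(?P<name>[A-Za-z_][\w.\-]*))",
    re.IGNORECASE,
)


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            rest = text[pos:].strip()
            if not rest:
                break
            raise ParseError(f"unexpected character {rest[0]!r} in expression {text!r}")
        pos = m.end()
        kind = m.lastgroup
        value = m.group(kind)
        if kind == "name" and value.upper() in ("AND", "OR", "NOT"):
            kind = value.upper().lower()  # keyword operators
            kind = {"and": "and", "or": "or", "not": "not"}[kind]
        tokens.append((kind, value))
    return tokens


def parse_expression(text: str) -> Expr:
    """Parse a Boolean expression over node names into an :class:`Expr`."""
    tokens = _tokenize(text)
    if not tokens:
        raise ParseError(f"empty expression: {text!r}")
    pos = 0

    def peek():
        return tokens[pos][0] if pos < len(tokens) else None

    def advance():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> Expr:
        terms = [parse_and()]
        while peek() == "or":
            advance()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else Or(terms)

    def parse_and() -> Expr:
        terms = [parse_unary()]
        while peek() == "and":
            advance()
            terms.append(parse_unary())
        return terms[0] if len(terms) == 1 else And(terms)

    def parse_unary() -> Expr:
        kind = peek()
        if kind == "not":
            advance()
            return Not(parse_unary())
        if kind == "lpar":
            advance()
            inner = parse_or()
            if peek() != "rpar":
                raise ParseError(f"unbalanced parentheses in {text!r}")
            advance()
            return inner
        if kind == "const":
            return Const(int(advance()[1]))
        if kind == "name":
            return Var(advance()[1])
        raise ParseError(f"unexpected token in expression {text!r}")

    expr = parse_or()
    if pos != len(tokens):
        raise ParseError(f"trailing tokens in expression {text!r}")
    return expr


# ---------------------------------------------------------------------------
# Network and state
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NetworkState:
    """An assignment of {0,1} to every node, in declaration order.

    ``encoding`` maps losslessly to/from a nonnegative integer with node 0 in
    the least-significant bit.
    """

    bits: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "bits", tuple(int(b) for b in self.bits))
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("state bits must be 0 or 1")

    @property
    def n(self) -> int:
        return len(self.bits)

    @property
    def encoding(self) -> int:
        code = 0
        for i, b in enumerate(self.bits):
            code |= b << i
        return code

    @classmethod
    def from_encoding(cls, code: int, n: int) -> "NetworkState":
        if code < 0 or code >= (1 << n):
            raise ValueError(f"encoding {code} out of range for n={n}")
        return cls(tuple((code >> i) & 1 for i in range(n)))

    def as_dict(self, nodes: Sequence[str]) -> dict[str, int]:
        return dict(zip(nodes, self.bits))


@dataclass(frozen=True)
class BooleanNetwork:
    """A named synchronous Boolean network with optional fixed (KI/KO) values."""

    nodes: tuple[str, ...]
    functions: Mapping[str, Expr]
    fixed: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        nodes = tuple(self.nodes)
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "functions", dict(self.functions))
        object.__setattr__(self, "fixed", dict(self.fixed))
        seen = set()
        for name in nodes:
            if name in seen:
                raise ParseError(f"duplicate node name: {name!r}")
            seen.add(name)
        missing = set(nodes) - set(self.functions)
        if missing:
            raise ParseError(f"nodes without functions: {sorted(missing)}")
        declared = set(nodes)
        for name, expr in self.functions.items():
            if name not in declared:
                raise ParseError(f"function for undeclared node {name!r}")
            undeclared = expr.variables() - declared
            if undeclared:
                raise ParseError(
                    f"function of {name!r} references undeclared node(s): "
                    f"{sorted(undeclared)}"
                )
        for name, value in self.fixed.items():
            if name not in declared:
                raise ParseError(f"fixed value for undeclared node {name!r}")
            if value not in (0, 1):
                raise ParseError(f"fixed value for {name!r} must be 0 or 1")

    @property
    def n(self) -> int:
        return len(self.nodes)

    def index(self, node: str) -> int:
        try:
            return self.nodes.index(node)
        except ValueError:
            raise KeyError(f"unknown node {node!r}") from None

    @property
    def input_nodes(self) -> tuple[str, ...]:
        """Nodes whose function is a self-copy or a constant."""
        inputs = []
        for name in self.nodes:
            f = self.functions[name]
            if isinstance(f, Const) or (isinstance(f, Var) and f.name == name):
                inputs.append(name)
        return tuple(inputs)

    def with_fixed(self, assignments: Mapping[str, int]) -> "BooleanNetwork":
        """Return a copy with additional fixed values (the original is untouched)."""
        merged = dict(self.fixed)
        for node, value in assignments.items():
            if node not in self.nodes:
                raise KeyError(f"unknown node {node!r}")
            if node in merged and merged[node] != int(value):
                raise ValueError(f"conflicting fixed values for node {node!r}")
            merged[node] = int(value)
        return replace(self, fixed=merged)

    def state(self, on_nodes: Iterable[str] = ()) -> NetworkState:
        """Build a state with the listed nodes ON and all others OFF."""
        on = set(on_nodes)
        unknown = on - set(self.nodes)
        if unknown:
            raise KeyError(f"unknown node(s): {sorted(unknown)}")
        return NetworkState(tuple(1 if name in on else 0 for name in self.nodes))


def parse_network(text: str) -> BooleanNetwork:
    """Parse BoolNet-style ``targets, factors`` rule text into a network."""
    lines = [ln.strip() for ln in text.splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines:
        raise ParseError("empty rule file")
    header = lines[0].lower().replace(" ", "")
    if not header.startswith("targets,factors"):
        raise ParseError("rule file must start with a 'targets, factors' header")
    nodes: list[str] = []
    raw_exprs: list[str] = []
    for ln in lines[1:]:
        if "," not in ln:
            raise ParseError(f"malformed rule line (expected 'name, expression'): {ln!r}")
        name, expr_text = ln.split(",", 1)
        name = name.strip()
        if not name:
            raise ParseError(f"missing node name in line {ln!r}")
        if not expr_text.strip():
            raise ParseError(f"empty expression for node {name!r}")
        nodes.append(name)
        raw_exprs.append(expr_text)
    functions = {name: parse_expression(expr) for name, expr in zip(nodes, raw_exprs)}
    return BooleanNetwork(tuple(nodes), functions)


def serialize_network(net: BooleanNetwork) -> str:
    """Serialize to BoolNet text; ``parse_network`` of the result round-trips."""
    lines = ["targets, factors"]
    for name in net.nodes:
        lines.append(f"{name}, {net.functions[name].unparse()}")
    return "\n".join(lines) + "\n"


def evaluate_function(net: BooleanNetwork, node: str, state: NetworkState) -> int:
    """Value of ``node`` after one update from ``state`` (fixed values dominate)."""
    if node not in net.nodes:
        raise KeyError(f"unknown node {node!r}")
    if node in net.fixed:
        return net.fixed[node]
    return net.functions[node].evaluate(state.as_dict(net.nodes))


def synchronous_step(net: BooleanNetwork, state: NetworkState) -> NetworkState:
    """Apply every Boolean function simultaneously (one discrete time step)."""
    if state.n != net.n:
        raise ValueError(f"state has {state.n} bits, network has {net.n} nodes")
    values = state.as_dict(net.nodes)
    new_bits = []
    for name in net.nodes:
        if name in net.fixed:
            new_bits.append(net.fixed[name])
        else:
            new_bits.append(net.functions[name].evaluate(values))
    return NetworkState(tuple(new_bits))
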