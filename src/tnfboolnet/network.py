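"""Boolean networks and the ``targets, factors`` logical-rule dialect.

A Boolean network assigns every named node a logical update rule over the
node names, built from ``!`` (NOT), ``&`` (AND), ``|`` (OR), parentheses and
the constants ``0``/``1``.  Rule files follow the widely used
``targets, factors`` dialect: a single header line ``targets, factors``
followed by one ``name, expression`` line per node.

Operator precedence is NOT > AND > OR; redundant parentheses are accepted.
Serialization round-trips: ``parse_rules(serialize_rules(net))`` yields an
identical network.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Mapping

__all__ = [
    "Expr",
    "Const",
    "Var",
    "Not",
    "And",
    "Or",
    "BooleanNetwork",
    "RuleParseError",
    "parse_expression",
    "parse_rules",
    "serialize_rules",
]

_NAME_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")


class RuleParseError(ValueError):
    """Raised for malformed rule files or expressions.

    Carries the offending line number (1-based, when known) and a
    human-readable description of the position or symbol at fault.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


# --------------------------------------------------------------------------
# Expression AST


class Expr:
    """Base class for logical expressions over node names."""

    def evaluate(self, state: Mapping[str, int]) -> int:
        raise NotImplementedError

    def variables(self) -> frozenset[str]:
        raise NotImplementedError

    def __eq__(self, other) -> bool:
        return type(self) is type(other) and str(self) == str(other)

    def __hash__(self) -> int:
        return hash((type(self).__name__, str(self)))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"{type(self).__name__}({str(self)!r})"


@dataclass(frozen=True, eq=False)
class Const(Expr):
    value: int

    def evaluate(self, state: Mapping[str, int]) -> int:
        return self.value

    def variables(self) -> frozenset[str]:
        return frozenset()

    def __str__(self) -> str:
        return str(self.value)


@dataclass(frozen=True, eq=False)
class Var(Expr):
    name: str

    def evaluate(self, state: Mapping[str, int]) -> int:
        return state[self.name]

    def variables(self) -> frozenset[str]:
        return frozenset({self.name})

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True, eq=False)
class Not(Expr):
    operand: Expr

    def evaluate(self, state: Mapping[str, int]) -> int:
        return 1 - self.operand.evaluate(state)

    def variables(self) -> frozenset[str]:
        return self.operand.variables()

    def __str__(self) -> str:
        inner = str(self.operand)
        if isinstance(self.operand, (And, Or)):
            inner = f"({inner})"
        return f"!{inner}"


@dataclass(frozen=True, eq=False)
class And(Expr):
    left: Expr
    right: Expr

    def evaluate(self, state: Mapping[str, int]) -> int:
        return self.left.evaluate(state) & self.right.evaluate(state)

    def variables(self) -> frozenset[str]:
        return self.left.variables() | self.right.variables()

    def __str__(self) -> str:
        parts = []
        for side in (self.left, self.right):
            s = str(side)
            if isinstance(side, Or):
                s = f"({s})"
            parts.append(s)
        return " & ".join(parts)


@dataclass(frozen=True, eq=False)
class Or(Expr):
    left: Expr
    right: Expr

    def evaluate(self, state: Mapping[str, int]) -> int:
        return self.left.evaluate(state) | self.right.evaluate(state)

    def variables(self) -> frozenset[str]:
        return self.left.variables() | self.right.variables()

    def __str__(self) -> str:
        return f"{self.left} | {self.right}"


# --------------------------------------------------------------------------
# Expression parser (recursive descent; precedence NOT > AND > OR)

_TOKEN_RE = re.compile(r"\s*(?:(?P<name>[A-Za-z_][A-Za-z0-9_]*)|(?P<op>[!&|()])|(?P<const>[01]))")


def _tokenize(text: str, line: int | None) -> Iterator[tuple[str, str, int]]:
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            raise RuleParseError(
                f"unexpected character {stripped[0]!r} at position {pos} in expression {text!r}",
                line,
            )
        if m.lastgroup == "name":
            yield ("name", m.group("name"), m.start("name"))
        elif m.lastgroup == "const":
            yield ("const", m.group("const"), m.start("const"))
        else:
            yield ("op", m.group("op"), m.start("op"))
        pos = m.end()


class _Parser:
    def __init__(self, text: str, line: int | None = None):
        self.text = text
        self.line = line
        self.tokens = list(_tokenize(text, line))
        self.idx = 0

    def peek(self) -> tuple[str, str, int] | None:
        return self.tokens[self.idx] if self.idx < len(self.tokens) else None

    def advance(self) -> tuple[str, str, int]:
        tok = self.peek()
        if tok is None:
            raise RuleParseError(f"unexpected end of expression {self.text!r}", self.line)
        self.idx += 1
        return tok

    def parse(self) -> Expr:
        expr = self.parse_or()
        tok = self.peek()
        if tok is not None:
            raise RuleParseError(
                f"unexpected token {tok[1]!r} at position {tok[2]} in expression {self.text!r}",
                self.line,
            )
        return expr

    def parse_or(self) -> Expr:
        expr = self.parse_and()
        while (tok := self.peek()) is not None and tok[1] == "|":
            self.advance()
            expr = Or(expr, self.parse_and())
        return expr

    def parse_and(self) -> Expr:
        expr = self.parse_unary()
        while (tok := self.peek()) is not None and tok[1] == "&":
            self.advance()
            expr = And(expr, self.parse_unary())
        return expr

    def parse_unary(self) -> Expr:
        kind, value, pos = self.advance()
        if kind == "op" and value == "!":
            return Not(self.parse_unary())
        if kind == "op" and value == "(":
            expr = self.parse_or()
            tok = self.peek()
            if tok is None or tok[1] != ")":
                raise RuleParseError(
                    f"unbalanced parenthesis opened at position {pos} in expression {self.text!r}",
                    self.line,
                )
            self.advance()
            return expr
        if kind == "name":
            return Var(value)
        if kind == "const":
            return Const(int(value))
        raise RuleParseError(
            f"unexpected token {value!r} at position {pos} in expression {self.text!r}",
            self.line,
        )


def parse_expression(text: str, line: int | None = None) -> Expr:
    """Parse a single logical expression (NOT > AND > OR precedence)."""
    if not text.strip():
        raise RuleParseError("empty expression", line)
    return _Parser(text, line).parse()


# --------------------------------------------------------------------------
# Network container


class BooleanNetwork:
    """An ordered set of named nodes with one logical update rule each.

    Parameters
    ----------
    nodes:
        Node names in declaration order (unique, case-sensitive).
    rules:
        Mapping from each node name to its update rule.  Every variable
        referenced by a rule must be a declared node.
    """

    def __init__(self, nodes: list[str] | tuple[str, ...], rules: Mapping[str, Expr]):
        nodes = tuple(nodes)
        if len(set(nodes)) != len(nodes):
            dupes = sorted({n for n in nodes if nodes.count(n) > 1})
            raise RuleParseError(f"duplicate node name(s): {', '.join(dupes)}")
        if set(rules) != set(nodes):
            missing = sorted(set(nodes) - set(rules)) + sorted(set(rules) - set(nodes))
            raise RuleParseError(f"rules and nodes disagree on: {', '.join(missing)}")
        declared = set(nodes)
        for name in nodes:
            undeclared = rules[name].variables() - declared
            if undeclared:
                raise RuleParseError(
                    f"rule for {name!r} references undeclared node(s): "
                    + ", ".join(sorted(undeclared))
                )
        self.nodes: tuple[str, ...] = nodes
        self.rules: dict[str, Expr] = {n: rules[n] for n in nodes}

    @property
    def inputs(self) -> tuple[str, ...]:
        """Nodes whose rule is the identity on themselves or a constant."""
        result = []
        for name in self.nodes:
            rule = self.rules[name]
            if (isinstance(rule, Var) and rule.name == name) or isinstance(rule, Const):
                result.append(name)
        return tuple(result)

    def __len__(self) -> int:
        return len(self.nodes)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BooleanNetwork)
            and self.nodes == other.nodes
            and all(str(self.rules[n]) == str(other.rules[n]) for n in self.nodes)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"BooleanNetwork(n={len(self.nodes)}, nodes={list(self.nodes)!r})"


def parse_rules(text: str) -> BooleanNetwork:
    """Parse rule-file content in the ``targets, factors`` dialect.

    The first non-blank line must be the header ``targets, factors``;
    each subsequent non-blank, non-comment (``#``) line is
    ``name, expression``.
    """
    lines = text.splitlines()
    nodes: list[str] = []
    rules: dict[str, Expr] = {}
    header_seen = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            if [p.strip().lower() for p in line.split(",", 1)] != ["targets", "factors"]:
                raise RuleParseError(
                    f"expected header 'targets, factors', found {line!r}", lineno
                )
            header_seen = True
            continue
        if "," not in line:
            raise RuleParseError(f"expected 'name, expression', found {line!r}", lineno)
        name_part, expr_part = line.split(",", 1)
        name = name_part.strip()
        if not _NAME_RE.fullmatch(name):
            raise RuleParseError(f"invalid node name {name!r}", lineno)
        if name in rules:
            raise RuleParseError(f"duplicate node name {name!r}", lineno)
        rules[name] = parse_expression(expr_part, lineno)
        nodes.append(name)
    if not header_seen:
        raise RuleParseError("missing 'targets, factors' header")
    if not nodes:
        raise RuleParseError("rule file declares no nodes")
    return BooleanNetwork(nodes, rules)


def serialize_rules(net: BooleanNetwork) -> str:
    """Write a network back to the ``targets, factors`` dialect."""
    lines = ["targets, factors"]
    for name in net.nodes:
        lines.append(f"{name}, {net.rules[name]}")
    return "\n".join(lines) + "\n"
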