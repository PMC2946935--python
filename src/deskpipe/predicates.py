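"""Small boolean predicate language shared by cohort definitions and
workflow conditionals.

Grammar (no arbitrary code, comparisons plus boolean connectives only)::

    expr       := or_expr
    or_expr    := and_expr ("or" and_expr)*
    and_expr   := not_expr ("and" not_expr)*
    not_expr   := "not" not_expr | comparison
    comparison := primary (cmp primary)? | "(" expr ")"
    cmp        := "=" | "==" | "!=" | "<" | "<=" | ">" | ">="
    primary    := number | string | "true" | "false" | identifier

Identifiers name metadata fields or workflow variables and may contain
dots and underscores.  String literals use single or double quotes.
Comparing a number to a numeric string coerces the string to a number.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Any, Callable, Mapping


class PredicateError(ValueError):
    """Raised for syntax errors or references to unknown fields."""


_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<number>-?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?)
      | (?P<string>'[^']*'|"[^"]*")
      | (?P<op><=|>=|!=|==|=|<|>)
      | (?P<lparen>\()
      | (?P<rparen>\))
      | (?P<ident>[A-Za-z_][A-Za-z0-9_.]*)
    )""",
    re.VERBOSE,
)

_KEYWORDS = {"and", "or", "not", "true", "false"}


def tokenize(text: str) -> list[tuple[str, Any]]:
    tokens: list[tuple[str, Any]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise PredicateError(
                f"bad character {text[pos]!r} at position {pos} in predicate {text!r}"
            )
        pos = m.end()
        kind = m.lastgroup
        value = m.group(kind)
        if kind == "number":
            tokens.append(("number", float(value)))
        elif kind == "string":
            tokens.append(("string", value[1:-1]))
        elif kind == "ident":
            low = value.lower()
            if low in _KEYWORDS:
                tokens.append((low, low))
            else:
                tokens.append(("ident", value))
        else:
            tokens.append((kind, value))
    return tokens


@dataclass
class _Node:
    kind: str  # "or" | "and" | "not" | "cmp" | "lit" | "field"
    value: Any = None
    children: tuple = ()


class _Parser:
    def __init__(self, tokens: list[tuple[str, Any]], text: str):
        self.tokens = tokens
        self.pos = 0
        self.text = text

    def peek(self) -> tuple[str, Any] | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> tuple[str, Any]:
        tok = self.peek()
        if tok is None:
            raise PredicateError(f"unexpected end of predicate {self.text!r}")
        self.pos += 1
        return tok

    def parse(self) -> _Node:
        node = self.or_expr()
        if self.peek() is not None:
            raise PredicateError(
                f"trailing tokens after position {self.pos} in predicate {self.text!r}"
            )
        return node

    def or_expr(self) -> _Node:
        node = self.and_expr()
        while self.peek() and self.peek()[0] == "or":
            self.next()
            node = _Node("or", children=(node, self.and_expr()))
        return node

    def and_expr(self) -> _Node:
        node = self.not_expr()
        while self.peek() and self.peek()[0] == "and":
            self.next()
            node = _Node("and", children=(node, self.not_expr()))
        return node

    def not_expr(self) -> _Node:
        if self.peek() and self.peek()[0] == "not":
            self.next()
            return _Node("not", children=(self.not_expr(),))
        return self.comparison()

    def comparison(self) -> _Node:
        left = self.primary()
        tok = self.peek()
        if tok and tok[0] == "op":
            op = self.next()[1]
            right = self.primary()
            return _Node("cmp", value=op, children=(left, right))
        return left

    def primary(self) -> _Node:
        tok = self.next()
        kind, value = tok
        if kind == "lparen":
            node = self.or_expr()
            closing = self.next()
            if closing[0] != "rparen":
                raise PredicateError(f"missing ')' in predicate {self.text!r}")
            return node
        if kind == "number":
            return _Node("lit", value=value)
        if kind == "string":
            return _Node("lit", value=value)
        if kind == "true":
            return _Node("lit", value=True)
        if kind == "false":
            return _Node("lit", value=False)
        if kind == "ident":
            return _Node("field", value=value)
        raise PredicateError(f"unexpected token {value!r} in predicate {self.text!r}")


def _coerce_pair(a: Any, b: Any) -> tuple[Any, Any]:
    """Coerce a number/string pair to comparable types where sensible."""
    if isinstance(a, bool) or isinstance(b, bool):
        return a, b
    if isinstance(a, (int, float)) and isinstance(b, str):
        try:
            return a, float(b)
        except ValueError:
            return str(a), b
    if isinstance(b, (int, float)) and isinstance(a, str):
        try:
            return float(a), b
        except ValueError:
            return a, str(b)
    return a, b


_CMP: dict[str, Callable[[Any, Any], bool]] = {
    "=": lambda a, b: a == b,
    "==": lambda a, b: a == b,
    "!=": lambda a, b: a != b,
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
}


class Predicate:
    """A compiled predicate. ``fields()`` lists referenced identifiers."""

    def __init__(self, text: str):
        self.text = text
        self._ast = _Parser(tokenize(text), text).parse()

    def fields(self) -> set[str]:
        out: set[str] = set()

        def walk(node: _Node) -> None:
            if node.kind == "field":
                out.add(node.value)
            for child in node.children:
                walk(child)

        walk(self._ast)
        return out

    def evaluate(self, env: Mapping[str, Any]) -> bool:
        def ev(node: _Node) -> Any:
            if node.kind == "lit":
                return node.value
            if node.kind == "field":
                if node.value not in env:
                    raise PredicateError(
                        f"unknown field {node.value!r} in predicate {self.text!r}"
                    )
                return env[node.value]
            if node.kind == "not":
                return not _truthy(ev(node.children[0]))
            if node.kind == "and":
                return _truthy(ev(node.children[0])) and _truthy(ev(node.children[1]))
            if node.kind == "or":
                return _truthy(ev(node.children[0])) or _truthy(ev(node.children[1]))
            if node.kind == "cmp":
                a, b = _coerce_pair(ev(node.children[0]), ev(node.children[1]))
                try:
                    return _CMP[node.value](a, b)
                except TypeError as exc:
                    raise PredicateError(
                        f"cannot compare {a!r} and {b!r} in predicate {self.text!r}"
                    ) from exc
            raise AssertionError(node.kind)

        return _truthy(ev(self._ast))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Predicate({self.text!r})"


def _truthy(value: Any) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)):
        return value != 0
    if isinstance(value, str):
        return value.lower() not in ("", "false", "0")
    return bool(value)


def evaluate(text: str, env: Mapping[str, Any]) -> bool:
    """Compile and evaluate ``text`` against ``env`` in one call."""
    return Predicate(text).evaluate(env)
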