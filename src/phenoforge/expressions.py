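"""Class expressions for logical definitions.

The expression language is the EL-style fragment that pre-composed
phenotype patterns use: named classes, existential restrictions over named
relations, and intersections. A pattern's equivalence schema additionally
contains variable slots; substituting term bindings for the slots yields
the ground logical definition of a generated class.

Expressions are written in the pattern files as parenthesized strings over
quoted class/relation names, e.g.::

    'has part' some ('decreased size' and ('inheres in' some %s)
                     and ('has modifier' some abnormal))

``%s`` slots are paired positionally with a variable-reference list, the
same convention the text templates use.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Union

from .errors import ExpressionError


@dataclass(frozen=True)
class Atom:
    """A named class, identified by CURIE."""

    curie: str


@dataclass(frozen=True)
class Var:
    """An unbound variable slot in a pattern schema."""

    name: str


@dataclass(frozen=True)
class Some:
    """Existential restriction: ``relation some filler``.

    ``relation`` is a relation *name*; names map to CURIEs only at
    serialization time.
    """

    relation: str
    filler: "Expression"

    def __hash__(self):  # cached: trees are hashed heavily during classification
        h = self.__dict__.get("_hash")
        if h is None:
            h = hash((Some, self.relation, self.filler))
            object.__setattr__(self, "_hash", h)
        return h


@dataclass(frozen=True)
class And:
    """Intersection, kept in canonical form: flattened, deduplicated, sorted."""

    parts: tuple["Expression", ...]

    def __hash__(self):
        h = self.__dict__.get("_hash")
        if h is None:
            h = hash((And, self.parts))
            object.__setattr__(self, "_hash", h)
        return h


Expression = Union[Atom, Var, Some, And]


def intersection(parts: list[Expression]) -> Expression:
    """Build a canonical intersection (flatten, dedupe, sort)."""
    flat: list[Expression] = []
    for p in parts:
        if isinstance(p, And):
            flat.extend(p.parts)
        else:
            flat.append(p)
    unique = sorted(set(flat), key=_sort_key)
    if not unique:
        raise ExpressionError("empty intersection")
    if len(unique) == 1:
        return unique[0]
    return And(tuple(unique))


def _sort_key(expr: Expression) -> str:
    return render(expr)


def render(expr: Expression, relation_map: dict[str, str] | None = None) -> str:
    """Deterministic textual form, also used as the canonical identity key."""
    if isinstance(expr, Atom):
        return expr.curie
    if isinstance(expr, Var):
        return f"?{expr.name}"
    if isinstance(expr, Some):
        rel = relation_map.get(expr.relation, expr.relation) if relation_map else expr.relation
        if " " in rel:
            rel = f"'{rel}'"
        return f"{rel} some {_wrap(expr.filler, relation_map)}"
    if isinstance(expr, And):
        return "(" + " and ".join(_wrap(p, relation_map) for p in expr.parts) + ")"
    raise ExpressionError(f"unknown expression node {expr!r}")


def _wrap(expr: Expression, relation_map) -> str:
    text = render(expr, relation_map)
    if isinstance(expr, Some):
        return f"({text})"
    return text


def substitute(expr: Expression, bindings: dict[str, str]) -> Expression:
    """Replace variable slots with class atoms; every slot must be bound."""
    if isinstance(expr, Var):
        if expr.name not in bindings:
            raise ExpressionError(f"unbound variable {expr.name!r}")
        return Atom(bindings[expr.name])
    if isinstance(expr, Some):
        return Some(expr.relation, substitute(expr.filler, bindings))
    if isinstance(expr, And):
        return intersection([substitute(p, bindings) for p in expr.parts])
    return expr


def is_ground(expr: Expression) -> bool:
    return not variables(expr)


def variables(expr: Expression) -> set[str]:
    if isinstance(expr, Var):
        return {expr.name}
    if isinstance(expr, Some):
        return variables(expr.filler)
    if isinstance(expr, And):
        out: set[str] = set()
        for p in expr.parts:
            out |= variables(p)
        return out
    return set()


def atoms(expr: Expression) -> set[str]:
    """All class CURIEs mentioned in the expression."""
    if isinstance(expr, Atom):
        return {expr.curie}
    if isinstance(expr, Some):
        return atoms(expr.filler)
    if isinstance(expr, And):
        out: set[str] = set()
        for p in expr.parts:
            out |= atoms(p)
        return out
    return set()


def unify(schema: Expression, ground: Expression) -> dict[str, str] | None:
    """Match a schema with variables against a ground expression.

    Returns the variable bindings on success, ``None`` on mismatch.
    Variables range over named classes, so a slot only matches an atom.
    """
    if isinstance(schema, Var):
        if isinstance(ground, Atom):
            return {schema.name: ground.curie}
        return None
    if isinstance(schema, Atom):
        return {} if schema == ground else None
    if isinstance(schema, Some):
        if isinstance(ground, Some) and schema.relation == ground.relation:
            return unify(schema.filler, ground.filler)
        return None
    if isinstance(schema, And):
        if not isinstance(ground, And) or len(schema.parts) != len(ground.parts):
            return None
        return _match_parts(list(schema.parts), list(ground.parts), {})
    return None


def _match_parts(schema_parts, ground_parts, bindings) -> dict[str, str] | None:
    if not schema_parts:
        return bindings if not ground_parts else None
    head = schema_parts[0]
    for i, g in enumerate(ground_parts):
        sub = unify(head, g)
        if sub is None:
            continue
        if any(bindings.get(k, v) != v for k, v in sub.items()):
            continue
        merged = {**bindings, **sub}
        rest = _match_parts(schema_parts[1:], ground_parts[:i] + ground_parts[i + 1 :], merged)
        if rest is not None:
            return rest
    return None


# --- parsing ----------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<quoted>'[^']*')
      | (?P<slot>%s)
      | (?P<lpar>\()
      | (?P<rpar>\))
      | (?P<word>[A-Za-z_][A-Za-z0-9_:\-]*)
    )""",
    re.VERBOSE,
)


def _tokenize(text: str) -> list[str]:
    tokens: list[str] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m or m.end() == pos:
            if text[pos:].strip():
                raise ExpressionError(f"cannot tokenize expression at {text[pos:]!r}")
            break
        pos = m.end()
        tokens.append(m.group().strip())
    return tokens


class _Parser:
    """Recursive-descent parser for the expression grammar::

        expr     := primary ('and' primary)*
        primary  := '(' expr ')' | name ['some' primary] | slot
    """

    def __init__(self, tokens, classes, relations, var_queue):
        self.tokens = tokens
        self.pos = 0
        self.classes = classes
        self.relations = relations
        self.var_queue = var_queue

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self):
        tok = self.peek()
        if tok is None:
            raise ExpressionError("unexpected end of expression")
        self.pos += 1
        return tok

    def expect(self, tok):
        got = self.take()
        if got != tok:
            raise ExpressionError(f"expected {tok!r}, got {got!r}")

    def parse(self) -> Expression:
        expr = self.parse_expr()
        if self.peek() is not None:
            raise ExpressionError(f"trailing tokens starting at {self.peek()!r}")
        return expr

    def parse_expr(self) -> Expression:
        parts = [self.parse_primary()]
        while self.peek() == "and":
            self.take()
            parts.append(self.parse_primary())
        return intersection(parts) if len(parts) > 1 else parts[0]

    def parse_primary(self) -> Expression:
        tok = self.take()
        if tok == "(":
            expr = self.parse_expr()
            self.expect(")")
            return expr
        if tok == "%s":
            if not self.var_queue:
                raise ExpressionError("more %s slots than variable references")
            return Var(self.var_queue.pop(0))
        name = tok[1:-1] if tok.startswith("'") else tok
        if self.peek() == "some":
            self.take()
            if name not in self.relations:
                raise ExpressionError(f"unknown relation {name!r}")
            return Some(name, self.parse_primary())
        if name not in self.classes:
            raise ExpressionError(f"unknown class name {name!r}")
        return Atom(self.classes[name])


def parse_expression(
    text: str,
    var_refs: list[str],
    classes: dict[str, str],
    relations: dict[str, str],
) -> Expression:
    """Parse an equivalence-schema string.

    ``var_refs`` pairs with the ``%s`` slots positionally; ``classes`` maps
    class names to CURIEs and ``relations`` declares the legal relation
    names.
    """
    queue = list(var_refs)
    expr = _Parser(_tokenize(text), classes, relations, queue).parse()
    if queue:
        raise ExpressionError(
            f"variable references {queue!r} have no matching %s slot"
        )
    return expr
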