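"""Structural subsumption over logical definitions.

Computes the complete is_a hierarchy of the generated phenotype classes
purely from their logical definitions — no manually asserted parents. The
expression fragment is EL-style: named classes, existential restrictions,
intersections. The rules are:

* class atoms: X is subsumed by Y when Y lies in X's closure — over
  ``is_a`` and ``part_of`` for entity (anatomy) atoms, over ``is_a`` for
  quality/process atoms. Folding ``part_of`` into the entity closure is
  what makes "abnormal eye" a kind of "abnormal visual system" when the
  eye is part of the visual system, while ``develops_from`` edges never
  contribute;
* existential restrictions: same relation, fillers entail;
* intersections: the subsumer's conjuncts must each be entailed; any one
  conjunct of the subsumee may do the entailing;
* pattern lattice: a declared parent-pattern link entails the mapped
  parent instance, covering cross-pattern subsumptions the structural
  rules alone cannot see (e.g. a process-in-location class under the
  plain "abnormal X" class).

This is deliberately not a general EL reasoner: completeness holds for
the schema shapes the shipped patterns use, and that restriction is a
documented limitation.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import networkx as nx

from .errors import ExpressionError, PatternValidationError
from .expressions import And, Atom, Expression, Some, atoms, render, substitute, unify
from .model import OntologyGraph
from .patterns import DesignPattern, PhenotypeClass

ENTITY_CLOSURE_RELATIONS = frozenset({"is_a", "part_of"})
QUALITY_CLOSURE_RELATIONS = frozenset({"is_a"})


class EntailmentEngine:
    """Decides subsumption between ground logical definitions."""

    def __init__(
        self,
        entity_graph: OntologyGraph,
        quality_graph: OntologyGraph,
        patterns: dict[str, DesignPattern] | None = None,
    ):
        self.entity_graph = entity_graph
        self.quality_graph = quality_graph
        self.patterns = patterns or {}
        self._entity_dg = entity_graph.relation_digraph(ENTITY_CLOSURE_RELATIONS)
        self._quality_dg = quality_graph.relation_digraph(QUALITY_CLOSURE_RELATIONS)
        self._validate_lattice()
        self._subsumers = lru_cache(maxsize=None)(self._subsumers_uncached)
        self._checked: set[Expression] = set()
        # memoization: pairwise decisions and per-expression lattice parents
        self._decision_cache: dict[tuple[Expression, Expression], bool] = {}
        self._lattice_parents_cache: dict[Expression, tuple[Expression, ...]] = {}

    def _validate_lattice(self) -> None:
        lattice = nx.DiGraph()
        lattice.add_nodes_from(self.patterns)
        for p in self.patterns.values():
            for link in p.parent_patterns:
                if link.parent_id not in self.patterns:
                    raise PatternValidationError(
                        f"{p.pattern_id}: unknown parent pattern {link.parent_id!r}"
                    )
                parent = self.patterns[link.parent_id]
                mapped = {pv for pv, _ in link.var_map}
                if mapped != set(parent.variables):
                    raise PatternValidationError(
                        f"{p.pattern_id} -> {link.parent_id}: variable mapping "
                        f"must cover exactly the parent's variables"
                    )
                lattice.add_edge(p.pattern_id, link.parent_id)
        if not nx.is_directed_acyclic_graph(lattice):
            raise PatternValidationError("parent_patterns declarations form a cycle")

    # -- atoms ---------------------------------------------------------------
    def _subsumers_uncached(self, curie: str) -> frozenset[str]:
        """Reflexive closure of atom subsumers (entity: is_a+part_of; else is_a)."""
        if curie in self.entity_graph.terms:
            dg = self._entity_dg
        elif curie in self.quality_graph.terms:
            dg = self._quality_dg
        else:
            raise ExpressionError(f"unknown class {curie} in logical definition")
        return frozenset({curie} | nx.descendants(dg, curie))

    def atom_entails(self, x: str, y: str) -> bool:
        return y in self._subsumers(x)

    def _check(self, expr: Expression) -> None:
        if expr in self._checked:
            return
        for curie in atoms(expr):
            self._subsumers(curie)  # raises on unknown CURIEs
        self._checked.add(expr)

    # -- expressions ---------------------------------------------------------
    def entails(self, a: Expression, b: Expression) -> bool:
        """True iff ``a`` is subsumed by ``b``.

        Raises :class:`ExpressionError` when either expression mentions a
        class unknown to both source ontologies.
        """
        self._check(a)
        self._check(b)
        return self._entails(a, b)

    def _entails(self, a: Expression, b: Expression) -> bool:
        key = (a, b)
        cached = self._decision_cache.get(key)
        if cached is None:
            cached = self._entails_uncached(a, b)
            self._decision_cache[key] = cached
        return cached

    def _entails_uncached(self, a: Expression, b: Expression) -> bool:
        if a == b:
            return True
        if isinstance(b, And):
            return all(self._entails(a, part) for part in b.parts)
        if isinstance(a, And):
            if any(self._entails(part, b) for part in a.parts):
                return True
        elif isinstance(a, Atom) and isinstance(b, Atom):
            if self.atom_entails(a.curie, b.curie):
                return True
        elif isinstance(a, Some) and isinstance(b, Some):
            if a.relation == b.relation and self._entails(a.filler, b.filler):
                return True
        return self._entails_via_lattice(a, b)

    def _entails_via_lattice(self, a: Expression, b: Expression) -> bool:
        return any(self._entails(p, b) for p in self._lattice_parents(a))

    def _lattice_parents(self, a: Expression) -> tuple[Expression, ...]:
        """Parent-pattern instances of ``a``, for every pattern schema that
        unifies with it (cached per expression)."""
        cached = self._lattice_parents_cache.get(a)
        if cached is not None:
            return cached
        parents: list[Expression] = []
        for pattern in self.patterns.values():
            if not pattern.parent_patterns:
                continue
            bindings = unify(pattern.schema, a)
            if bindings is None:
                continue
            for link in pattern.parent_patterns:
                parent = self.patterns[link.parent_id]
                try:
                    parent_bindings = {
                        pv: bindings[cv] for pv, cv in link.var_map
                    }
                except KeyError:
                    continue
                parents.append(substitute(parent.schema, parent_bindings))
        result = tuple(parents)
        self._lattice_parents_cache[a] = result
        return result


@dataclass(frozen=True)
class SubsumptionResult:
    """Direct is_a assertions (transitive reduction) plus root attachment."""

    edges: tuple[tuple[str, str], ...]  # (child, parent)
    root: str
    equivalences: tuple[tuple[str, str], ...] = ()

    def parents(self, cid: str) -> list[str]:
        return [p for c, p in self.edges if c == cid]


def all_pairs_entailment(
    classes: list[PhenotypeClass], engine: EntailmentEngine
) -> set[tuple[str, str]]:
    """Brute-force subsumption closure over every ordered pair (child, parent)."""
    active = [c for c in classes if not c.obsolete and c.logical_definition is not None]
    pairs: set[tuple[str, str]] = set()
    for a in active:
        for b in active:
            if a.id != b.id and engine.entails(a.logical_definition, b.logical_definition):
                pairs.add((a.id, b.id))
    return pairs


def classify(
    classes: list[PhenotypeClass],
    engine: EntailmentEngine,
    root: str,
) -> SubsumptionResult:
    """Derive the direct is_a hierarchy of the generated classes.

    Edges are the transitive reduction of the entails-induced strict
    order; classes with no derived parent attach to ``root``. Mutually
    entailing distinct classes (logically equivalent duplicates) are
    reported, kept, and tie-broken to no edge between them; both fall
    through to whatever other parents they have.
    """
    active = [c for c in classes if not c.obsolete and c.logical_definition is not None]
    ids = [c.id for c in active]
    if len(set(ids)) != len(ids):
        raise PatternValidationError("duplicate class ids passed to classify")

    pairs = all_pairs_entailment(classes, engine)
    equivalences = tuple(
        sorted({tuple(sorted((a, b))) for a, b in pairs if (b, a) in pairs})
    )
    strict = {(a, b) for a, b in pairs if (b, a) not in pairs}

    order = nx.DiGraph()
    order.add_nodes_from(ids)
    order.add_edges_from(strict)
    reduced = nx.transitive_reduction(order)

    edges = set(reduced.edges())
    for cid in ids:
        if cid != root and reduced.out_degree(cid) == 0:
            edges.add((cid, root))
    return SubsumptionResult(
        edges=tuple(sorted(edges)), root=root, equivalences=equivalences
    )


def closure(edges: tuple[tuple[str, str], ...] | set) -> set[tuple[str, str]]:
    """Transitive closure of an edge set, as (child, ancestor) pairs."""
    g = nx.DiGraph(list(edges))
    return {
        (child, ancestor)
        for child in g
        for ancestor in nx.descendants(g, child)
    }


def expression_key(expr: Expression) -> str:
    """Canonical identity key for duplicate-definition detection."""
    return render(expr)
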