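"""In-memory ontology graph: terms, typed relationships, and structural invariants.

The graph is deliberately simple: a term table plus a flat list of typed
directed edges. Relationship predicates are plain relation *names*
(``is_a``, ``part_of``, ``develops_from``, ...); mapping names to relation
CURIEs/IRIs is a serialization-time concern, configured elsewhere.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx

from .errors import GraphStructureError

CURIE_PATTERN = re.compile(r"^[A-Za-z]+:\d+$")

SYNONYM_SCOPES = ("EXACT", "RELATED", "BROAD", "NARROW")


def is_curie(value: str) -> bool:
    return bool(CURIE_PATTERN.match(value))


@dataclass(frozen=True)
class Synonym:
    text: str
    scope: str = "EXACT"

    def __post_init__(self):
        if self.scope not in SYNONYM_SCOPES:
            raise ValueError(f"unknown synonym scope {self.scope!r}")


@dataclass
class Term:
    """A single ontology class.

    ``extras`` holds raw tag lines the parser did not interpret; they are
    round-tripped verbatim so that unknown annotations survive a
    parse/serialize cycle.
    """

    id: str
    label: str = ""
    definition: str | None = None
    xrefs: tuple[str, ...] = ()
    synonyms: tuple[Synonym, ...] = ()
    obsolete: bool = False
    replaced_by: str | None = None
    extras: tuple[str, ...] = ()

    def validate(self) -> None:
        if not is_curie(self.id):
            raise GraphStructureError(f"term id {self.id!r} is not a CURIE")
        if self.replaced_by is not None and not self.obsolete:
            raise GraphStructureError(
                f"{self.id}: replaced_by set on a non-obsolete term"
            )


@dataclass(frozen=True)
class Relationship:
    """A typed directed edge ``subject --predicate--> object``."""

    subject: str
    predicate: str
    object: str

    def validate(self) -> None:
        if self.subject == self.object:
            raise GraphStructureError(
                f"self-referential {self.predicate} edge on {self.subject}"
            )


@dataclass
class OntologyGraph:
    terms: dict[str, Term] = field(default_factory=dict)
    relationships: list[Relationship] = field(default_factory=list)
    header: dict[str, str] = field(default_factory=dict)
    header_extras: tuple[str, ...] = ()
    typedef_stanzas: tuple[str, ...] = ()

    # -- construction helpers -------------------------------------------------
    def add_term(self, term: Term) -> Term:
        if term.id in self.terms:
            raise GraphStructureError(f"duplicate term id {term.id}")
        self.terms[term.id] = term
        return term

    def add_relationship(self, subject: str, predicate: str, object: str) -> None:
        self.relationships.append(Relationship(subject, predicate, object))

    # -- queries --------------------------------------------------------------
    def labels(self) -> dict[str, str]:
        return {tid: t.label for tid, t in self.terms.items()}

    def relation_digraph(self, relations: set[str] | frozenset[str]) -> nx.DiGraph:
        """Subject->object digraph restricted to the given relation names."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for rel in self.relationships:
            if rel.predicate in relations:
                g.add_edge(rel.subject, rel.object)
        return g

    def sorted_relationships(self) -> list[Relationship]:
        return sorted(
            self.relationships, key=lambda r: (r.subject, r.predicate, r.object)
        )

    # -- invariants -----------------------------------------------------------
    def validate(self) -> None:
        for term in self.terms.values():
            term.validate()
            if term.replaced_by is not None and term.replaced_by not in self.terms:
                raise GraphStructureError(
                    f"{term.id}: dangling reference in replaced_by: {term.replaced_by}"
                )
        for rel in self.relationships:
            rel.validate()
            for endpoint in (rel.subject, rel.object):
                if endpoint not in self.terms:
                    raise GraphStructureError(
                        f"dangling reference: {endpoint} in "
                        f"{rel.subject} {rel.predicate} {rel.object}"
                    )
        isa = self.relation_digraph({"is_a"})
        try:
            cycle = nx.find_cycle(isa)
        except nx.NetworkXNoCycle:
            return
        path = " -> ".join(edge[0] for edge in cycle)
        raise GraphStructureError(f"is_a cycle: {path}")

    def __eq__(self, other) -> bool:  # relationship order is not semantic
        if not isinstance(other, OntologyGraph):
            return NotImplemented
        return (
            self.terms == other.terms
            and sorted(self.relationships, key=lambda r: (r.subject, r.predicate, r.object))
            == sorted(other.relationships, key=lambda r: (r.subject, r.predicate, r.object))
            and self.header == other.header
            and self.header_extras == other.header_extras
            and self.typedef_stanzas == other.typedef_stanzas
        )
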