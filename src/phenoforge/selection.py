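"""Entity selection: which anatomy terms receive generated phenotype classes.

Selection walks the source ontology downward from per-pattern inclusion
roots using only the configured traversal relations — by default ``is_a``
and ``part_of``, never ``develops_from``. A phenotype in a developed
structure does not imply a phenotype in its developmental precursor, so
developmental-lineage edges must not propagate pattern application.
Exclusion lists (single terms, whole branches) and per-pattern
applicability filters then prune terms where the phenotype would be
biologically meaningless (e.g. cell proliferation inside an acellular
anatomical space).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import yaml

from .errors import SelectionError
from .model import OntologyGraph
from .patterns import DesignPattern, InstanceTable, ID_COLUMN, LABEL_COLUMN

DEFAULT_TRAVERSAL = ("is_a", "part_of")


@dataclass
class SelectionConfig:
    inclusion_roots: dict[str, tuple[str, ...]] = field(default_factory=dict)
    excluded_terms: tuple[str, ...] = ()
    excluded_branches: tuple[str, ...] = ()
    traversal_relations: tuple[str, ...] = DEFAULT_TRAVERSAL
    applicability_filters: tuple[tuple[str, str], ...] = ()  # (pattern_id, branch)
    auto_patterns: tuple[str, ...] = ()

    def __post_init__(self):
        if "develops_from" in self.traversal_relations:
            raise SelectionError(
                "develops_from as a traversal relation (inverse propagation of "
                "phenotypes to developmental precursors) is not supported"
            )

    @classmethod
    def from_yaml(cls, text: str) -> "SelectionConfig":
        doc = yaml.safe_load(text) or {}
        patterns = doc.get("patterns") or {}
        exclusions = doc.get("exclusions") or {}
        return cls(
            inclusion_roots={
                pid: tuple(block.get("roots") or ())
                for pid, block in patterns.items()
            },
            excluded_terms=tuple(exclusions.get("terms") or ()),
            excluded_branches=tuple(exclusions.get("branches") or ()),
            traversal_relations=tuple(
                doc.get("traversal_relations") or DEFAULT_TRAVERSAL
            ),
            applicability_filters=tuple(
                (f["pattern"], f["forbid_branch"]) for f in doc.get("filters") or ()
            ),
            auto_patterns=tuple(doc.get("auto_patterns") or ()),
        )

    def validate_against(self, graph: OntologyGraph) -> None:
        referenced = set(self.excluded_terms) | set(self.excluded_branches)
        referenced |= {b for _, b in self.applicability_filters}
        for roots in self.inclusion_roots.values():
            referenced |= set(roots)
        unknown = sorted(c for c in referenced if c not in graph.terms)
        if unknown:
            raise SelectionError(f"config references unknown term(s): {unknown}")


def descendants(
    graph: OntologyGraph, root: str, relations: set[str] | tuple[str, ...]
) -> list[str]:
    """All terms reaching ``root`` via chains of the given relations.

    Reflexive (always contains ``root``), returned in CURIE order. Cycles
    across the chosen relations make the closure ill-defined and are
    rejected.
    """
    if root not in graph.terms:
        raise SelectionError(f"unknown root {root}")
    digraph = graph.relation_digraph(set(relations))
    if not nx.is_directed_acyclic_graph(digraph):
        cycle = nx.find_cycle(digraph)
        path = " -> ".join(edge[0] for edge in cycle)
        raise SelectionError(f"cycle over relations {sorted(relations)}: {path}")
    return sorted({root} | nx.ancestors(digraph, root))


def select_entities(
    graph: OntologyGraph, config: SelectionConfig, pattern_id: str
) -> list[str]:
    """Entity terms the pattern applies to, in CURIE order.

    Union of the pattern's inclusion-root closures, minus excluded terms,
    excluded branches, applicability-filter branches bound to this pattern,
    and obsolete terms. Exclusion always beats inclusion.
    """
    roots = config.inclusion_roots.get(pattern_id)
    if not roots:
        raise SelectionError(f"pattern {pattern_id!r} has no inclusion roots")
    relations = config.traversal_relations
    selected: set[str] = set()
    for root in roots:
        selected |= set(descendants(graph, root, relations))
    for term in config.excluded_terms:
        selected.discard(term)
    for branch in config.excluded_branches:
        selected -= set(descendants(graph, branch, relations))
    for pid, branch in config.applicability_filters:
        if pid == pattern_id:
            selected -= set(descendants(graph, branch, relations))
    selected = {t for t in selected if not graph.terms[t].obsolete}
    return sorted(selected)


@dataclass
class SyncReport:
    """Per-pattern record of table changes proposed by a sync run."""

    added: dict[str, list[str]] = field(default_factory=dict)
    flagged: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    @property
    def n_added(self) -> int:
        return sum(len(v) for v in self.added.values())

    @property
    def n_flagged(self) -> int:
        return sum(len(v) for v in self.flagged.values())


def sync_tables(
    graph: OntologyGraph,
    config: SelectionConfig,
    tables: dict[str, InstanceTable],
    patterns: dict[str, DesignPattern],
) -> tuple[dict[str, InstanceTable], SyncReport]:
    """Bring auto-pattern tables in step with the source ontology.

    For each auto pattern, a row (id left blank for minting) is added for
    every selected entity absent from its table; rows whose entity is no
    longer selected are flagged for obsoletion, never deleted. Idempotent:
    re-running on unchanged inputs adds nothing.
    """
    labels = graph.labels()
    report = SyncReport()
    out = {pid: t for pid, t in tables.items()}
    for pid in config.auto_patterns:
        if pid not in patterns:
            raise SelectionError(f"auto pattern {pid!r} is not a known pattern")
        pattern = patterns[pid]
        if len(pattern.variables) != 1:
            raise SelectionError(
                f"auto pattern {pid!r} has {len(pattern.variables)} variables; "
                f"auto-application requires exactly one"
            )
        var = next(iter(pattern.variables))
        table = out.get(pid) or InstanceTable.empty(pid, [var])
        selected = set(select_entities(graph, config, pid))
        present = {row.get(var, "") for row in table.rows}

        flagged: list[tuple[str, str]] = []
        for row in table.rows:
            entity = row.get(var, "")
            if entity not in graph.terms:
                flagged.append((entity, "entity absent from source ontology"))
            elif graph.terms[entity].obsolete:
                flagged.append((entity, "entity obsoleted in source ontology"))
            elif entity not in selected:
                flagged.append((entity, "entity no longer selected"))

        added = sorted(selected - present)
        new_rows = [
            {
                ID_COLUMN: "",
                LABEL_COLUMN: "",
                var: entity,
                f"{var}_label": labels.get(entity, ""),
            }
            for entity in added
        ]
        rows = sorted(table.rows + new_rows, key=lambda r: r.get(var, ""))
        out[pid] = InstanceTable(pid, table.columns, rows)
        if added:
            report.added[pid] = added
        if flagged:
            report.flagged[pid] = flagged
    return out, report
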