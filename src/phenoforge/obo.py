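"""OBO 1.4 dialect parser and deterministic serializer.

Supported tags are exactly the release dialect this pipeline emits:
header ``format-version``, ``ontology``, ``data-version``; term tags
``id``, ``name``, ``def`` (with trailing dbxref list), ``synonym`` (quoted
text plus scope), ``is_a``, ``relationship``, ``is_obsolete``,
``replaced_by``. Any other tag line is preserved opaquely on the term and
written back verbatim, so foreign annotations survive a round trip.

Serialization is deterministic: terms sorted by CURIE, tags in a fixed
order, UTF-8, LF line endings. ``parse_obo(write_obo(g)) == g`` for every
graph that satisfies its invariants.
"""
from __future__ import annotations

import json
import re

from .errors import OboParseError
from .expressions import Expression, render
from .model import OntologyGraph, Relationship, Synonym, Term, SYNONYM_SCOPES

HEADER_TAGS = ("format-version", "ontology", "data-version")

_DEF_RE = re.compile(r'^"((?:[^"\\]|\\.)*)"\s*(?:\[([^\]]*)\])?\s*$')
_SYN_RE = re.compile(r'^"((?:[^"\\]|\\.)*)"\s+([A-Z]+)\s*(?:\[[^\]]*\])?\s*$')


def _unescape(text: str) -> str:
    return text.replace('\\"', '"').replace("\\\\", "\\")


def _escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def _strip_comment(value: str) -> str:
    """Drop a trailing ``! label`` comment from a tag value."""
    idx = value.find(" ! ")
    if idx >= 0:
        return value[:idx].rstrip()
    return value


def parse_obo(text: str) -> OntologyGraph:
    """Parse an OBO document into an :class:`OntologyGraph`.

    Raises :class:`OboParseError` with a line number on malformed input and
    :class:`GraphStructureError` on dangling references or is_a cycles.
    """
    graph = OntologyGraph()
    lines = text.splitlines()
    i = 0
    n = len(lines)

    # header: everything before the first stanza
    while i < n and not lines[i].startswith("["):
        line = lines[i].strip()
        if line:
            if ":" not in line:
                raise OboParseError(f"malformed header line {line!r}", i + 1)
            tag, _, value = line.partition(":")
            tag, value = tag.strip(), value.strip()
            if tag in HEADER_TAGS:
                graph.header[tag] = value
            else:
                graph.header_extras = graph.header_extras + (line,)
        i += 1

    while i < n:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if line == "[Term]":
            i = _parse_term_stanza(graph, lines, i + 1)
        elif line.startswith("[") and line.endswith("]"):
            # opaque stanza (e.g. [Typedef]): preserve raw
            start = i
            i += 1
            while i < n and not lines[i].startswith("[") :
                i += 1
            raw = "\n".join(l.rstrip() for l in lines[start:i]).rstrip()
            graph.typedef_stanzas = graph.typedef_stanzas + (raw,)
        else:
            raise OboParseError(f"unexpected content outside stanza: {line!r}", i + 1)

    graph.validate()
    return graph


def _parse_term_stanza(graph: OntologyGraph, lines: list[str], i: int) -> int:
    fields: dict = {
        "id": None,
        "label": "",
        "definition": None,
        "xrefs": (),
        "synonyms": [],
        "obsolete": False,
        "replaced_by": None,
        "extras": [],
    }
    rels: list[tuple[str, str, int]] = []
    isa: list[str] = []
    n = len(lines)
    while i < n and not lines[i].startswith("["):
        line = lines[i].strip()
        lineno = i + 1
        i += 1
        if not line:
            continue
        if ":" not in line:
            raise OboParseError(f"malformed tag line {line!r}", lineno)
        tag, _, value = line.partition(":")
        tag, value = tag.strip(), value.strip()
        if tag == "id":
            fields["id"] = value
        elif tag == "name":
            fields["label"] = value
        elif tag == "def":
            m = _DEF_RE.match(value)
            if not m:
                raise OboParseError(f"malformed def line {value!r}", lineno)
            fields["definition"] = _unescape(m.group(1))
            xrefs = m.group(2) or ""
            fields["xrefs"] = tuple(
                x.strip() for x in xrefs.split(",") if x.strip()
            )
        elif tag == "synonym":
            m = _SYN_RE.match(value)
            if not m or m.group(2) not in SYNONYM_SCOPES:
                raise OboParseError(f"malformed synonym line {value!r}", lineno)
            fields["synonyms"].append(Synonym(_unescape(m.group(1)), m.group(2)))
        elif tag == "is_a":
            isa.append(_strip_comment(value))
        elif tag == "relationship":
            value = _strip_comment(value)
            parts = value.split()
            if len(parts) != 2:
                raise OboParseError(f"malformed relationship line {value!r}", lineno)
            rels.append((parts[0], parts[1], lineno))
        elif tag == "is_obsolete":
            fields["obsolete"] = value == "true"
        elif tag == "replaced_by":
            fields["replaced_by"] = _strip_comment(value)
        else:
            fields["extras"].append(line)
    if fields["id"] is None:
        raise OboParseError("[Term] stanza without an id tag", i)
    term = Term(
        id=fields["id"],
        label=fields["label"],
        definition=fields["definition"],
        xrefs=fields["xrefs"],
        synonyms=tuple(fields["synonyms"]),
        obsolete=fields["obsolete"],
        replaced_by=fields["replaced_by"],
        extras=tuple(fields["extras"]),
    )
    graph.add_term(term)
    for parent in isa:
        graph.add_relationship(term.id, "is_a", parent)
    for predicate, obj, _ in rels:
        graph.add_relationship(term.id, predicate, obj)
    return i


def write_obo(graph: OntologyGraph) -> str:
    """Serialize deterministically (terms by CURIE, fixed tag order, LF)."""
    graph.validate()
    out: list[str] = []
    for tag in HEADER_TAGS:
        if tag in graph.header:
            out.append(f"{tag}: {graph.header[tag]}")
    out.extend(graph.header_extras)

    by_subject: dict[str, list[Relationship]] = {}
    for rel in graph.sorted_relationships():
        by_subject.setdefault(rel.subject, []).append(rel)

    for tid in sorted(graph.terms):
        term = graph.terms[tid]
        out.append("")
        out.append("[Term]")
        out.append(f"id: {term.id}")
        if term.label:
            out.append(f"name: {term.label}")
        if term.definition is not None:
            xrefs = ", ".join(term.xrefs)
            out.append(f'def: "{_escape(term.definition)}" [{xrefs}]')
        for syn in term.synonyms:
            out.append(f'synonym: "{_escape(syn.text)}" {syn.scope} []')
        for rel in by_subject.get(tid, []):
            if rel.predicate == "is_a":
                out.append(f"is_a: {rel.object}")
        for rel in by_subject.get(tid, []):
            if rel.predicate != "is_a":
                out.append(f"relationship: {rel.predicate} {rel.object}")
        if term.obsolete:
            out.append("is_obsolete: true")
        if term.replaced_by is not None:
            out.append(f"replaced_by: {term.replaced_by}")
        out.extend(term.extras)

    for stanza in graph.typedef_stanzas:
        out.append("")
        out.append(stanza)
    return "\n".join(out) + "\n"


def write_json_graph(
    graph: OntologyGraph,
    logical_definitions: dict[str, Expression] | None = None,
    relation_curies: dict[str, str] | None = None,
) -> str:
    """Serialize to the graph-structured JSON release format.

    ``logical_definitions`` (class id -> ground expression) are rendered as
    expression strings on the nodes; relation names are mapped to CURIEs at
    this point if a ``relation_curies`` map is supplied.
    """
    graph.validate()
    nodes = []
    for tid in sorted(graph.terms):
        term = graph.terms[tid]
        node: dict = {
            "id": tid,
            "label": term.label,
            "definition": term.definition,
            "synonyms": [{"text": s.text, "scope": s.scope} for s in term.synonyms],
            "obsolete": term.obsolete,
        }
        if term.replaced_by is not None:
            node["replaced_by"] = term.replaced_by
        if logical_definitions and tid in logical_definitions:
            node["logical_definition"] = render(
                logical_definitions[tid], relation_map=relation_curies
            )
        nodes.append(node)
    edges = [
        {"subject": r.subject, "predicate": r.predicate, "object": r.object}
        for r in graph.sorted_relationships()
    ]
    doc = {"graphs": [{"id": graph.header.get("ontology", ""), "nodes": nodes, "edges": edges}]}
    return json.dumps(doc, indent=2, ensure_ascii=False) + "\n"
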