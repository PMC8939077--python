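"""Deterministic synthetic source ontologies and pattern suites.

These generators emulate the *shape* of a real anatomy/quality ontology
pair — a rooted anatomy DAG with ``is_a``, ``part_of`` and
``develops_from`` edges plus an acellular "anatomical space" branch, and
an ``is_a`` tree of qualities and processes — without reproducing any real
ontology's content. CURIE prefixes are TOYA/TOYQ/TOYR/TOYP so fixtures can
never collide with real ontology identifiers.

The handcrafted skeleton plants the structures the selection and
classification rules are exercised on: an eye that is part of the visual
system (subsumption must propagate) and an optic vesicle connected to the
eye only by developmental lineage (subsumption must not propagate).
"""
from __future__ import annotations

import random
from dataclasses import dataclass

import yaml

from .errors import PhenoforgeError
from .model import OntologyGraph, Term

ANATOMY_PREFIX = "TOYA"
QUALITY_PREFIX = "TOYQ"
RELATION_PREFIX = "TOYR"
PHENOTYPE_PREFIX = "TOYP"

RELATION_CURIES = {
    "has part": f"{RELATION_PREFIX}:0000001",
    "inheres in": f"{RELATION_PREFIX}:0000002",
    "has modifier": f"{RELATION_PREFIX}:0000003",
    "occurs in": f"{RELATION_PREFIX}:0000004",
}


def _a(n: int) -> str:
    return f"{ANATOMY_PREFIX}:{n:07d}"


def _q(n: int) -> str:
    return f"{QUALITY_PREFIX}:{n:07d}"


# well-known fixture ids
ROOT = _a(1)
STRUCTURE = _a(2)
SPACE = _a(3)
WHOLE_ORGANISM = _a(4)
VISUAL_SYSTEM = _a(5)
EYE = _a(6)
OPTIC_VESICLE = _a(7)
RETINA = _a(8)
LENS = _a(9)
CARDIOVASCULAR_SYSTEM = _a(10)
HEART = _a(11)
BRAIN_VENTRICLE = _a(12)
COELOMIC_CAVITY = _a(13)

QUALITY_ROOT = _q(1)
QUALITY = _q(2)
PROCESS = _q(3)
SIZE = _q(10)
DECREASED_SIZE = _q(11)
INCREASED_SIZE = _q(12)
MORPHOLOGY = _q(13)
AMOUNT = _q(14)
DECREASED_AMOUNT = _q(15)
INCREASED_AMOUNT = _q(16)
ABSENT = _q(17)
POSITION = _q(18)
MISLOCALISED = _q(19)
STRUCTURE_QUALITY = _q(20)
NECROTIC = _q(21)
QUALITATIVE = _q(22)
ABNORMAL = _q(23)
OCCURRENCE = _q(24)
INCREASED_OCCURRENCE = _q(25)
DECREASED_OCCURRENCE = _q(26)
APOPTOSIS = _q(30)
PROLIFERATION = _q(31)
DEVELOPMENT = _q(32)


@dataclass(frozen=True)
class FixtureSpec:
    """Conditions for a synthetic anatomy ontology.

    ``relation_mix`` gives the is_a/part_of share of the single-parent
    backbone and the develops_from share that sizes the extra
    developmental-lineage edge count (always at least one, so the
    traversal restriction is always exercised).
    """

    seed: int = 1
    n_entities: int = 30
    relation_mix: tuple[float, float, float] = (0.6, 0.3, 0.1)
    include_space_branch: bool = True
    n_quality_terms: int = 0

    def validate(self) -> None:
        if self.n_entities < 3:
            raise PhenoforgeError("n_entities must be >= 3")
        if abs(sum(self.relation_mix) - 1.0) > 1e-9:
            raise PhenoforgeError("relation_mix proportions must sum to 1")
        if any(p < 0 for p in self.relation_mix):
            raise PhenoforgeError("relation_mix proportions must be non-negative")
        if self.relation_mix[0] + self.relation_mix[1] <= 0:
            raise PhenoforgeError(
                "infeasible relation_mix: the backbone needs is_a/part_of edges"
            )


_SKELETON: list[tuple[str, str, str | None, str]] = [
    # (id, label, parent, relation)
    (ROOT, "anatomical entity", None, ""),
    (STRUCTURE, "anatomical structure", ROOT, "is_a"),
    (SPACE, "anatomical space", ROOT, "is_a"),
    (WHOLE_ORGANISM, "whole organism", STRUCTURE, "is_a"),
    (VISUAL_SYSTEM, "visual system", WHOLE_ORGANISM, "part_of"),
    (EYE, "eye", VISUAL_SYSTEM, "part_of"),
    (OPTIC_VESICLE, "optic vesicle", STRUCTURE, "is_a"),
    (RETINA, "retina", EYE, "part_of"),
    (LENS, "lens", EYE, "part_of"),
    (CARDIOVASCULAR_SYSTEM, "cardiovascular system", WHOLE_ORGANISM, "part_of"),
    (HEART, "heart", CARDIOVASCULAR_SYSTEM, "part_of"),
    (BRAIN_VENTRICLE, "brain ventricle", SPACE, "is_a"),
    (COELOMIC_CAVITY, "coelomic cavity", SPACE, "is_a"),
]


def make_toy_anatomy(spec: FixtureSpec = FixtureSpec()) -> OntologyGraph:
    """Rooted anatomy DAG: single-parent backbone of ``n_entities - 1``
    is_a/part_of edges plus extra develops_from edges, deterministic for a
    fixed seed."""
    spec.validate()
    rng = random.Random(spec.seed)
    graph = OntologyGraph()
    graph.header["format-version"] = "1.4"
    graph.header["ontology"] = "toy-anatomy"

    skeleton = [
        row for row in _SKELETON
        if spec.include_space_branch or row[0] not in (SPACE, BRAIN_VENTRICLE, COELOMIC_CAVITY)
    ][: spec.n_entities]
    structure_branch: list[str] = []
    for tid, label, parent, rel in skeleton:
        graph.add_term(Term(id=tid, label=label, definition=f"The {label} of the toy organism."))
        if parent is not None:
            graph.add_relationship(tid, rel, parent)
        if tid not in (ROOT, SPACE, BRAIN_VENTRICLE, COELOMIC_CAVITY):
            structure_branch.append(tid)

    p_isa, p_part, p_df = spec.relation_mix
    p_isa_backbone = p_isa / (p_isa + p_part)
    next_num = 100
    while len(graph.terms) < spec.n_entities:
        tid = _a(next_num)
        next_num += 1
        label = f"generated structure {next_num - 100:03d}"
        parent = rng.choice(sorted(structure_branch))
        rel = "is_a" if rng.random() < p_isa_backbone else "part_of"
        graph.add_term(Term(id=tid, label=label, definition=f"The {label}."))
        graph.add_relationship(tid, rel, parent)
        structure_branch.append(tid)

    # developmental-lineage edges: never traversed by selection/classification
    n_extra = max(1, round(p_df * (spec.n_entities - 1)))
    existing = {(r.subject, r.object) for r in graph.relationships}
    existing |= {(b, a) for a, b in existing}
    if EYE in graph.terms and OPTIC_VESICLE in graph.terms:
        graph.add_relationship(EYE, "develops_from", OPTIC_VESICLE)
        existing.add((EYE, OPTIC_VESICLE))
        n_extra -= 1
    candidates = sorted(structure_branch)
    attempts = 0
    while n_extra > 0 and attempts < 1000 and len(candidates) >= 2:
        a, b = rng.sample(candidates, 2)
        attempts += 1
        if (a, b) in existing or (b, a) in existing:
            continue
        graph.add_relationship(a, "develops_from", b)
        existing.add((a, b))
        n_extra -= 1

    graph.validate()
    return graph


_QUALITY_TREE: list[tuple[str, str, str | None]] = [
    (QUALITY_ROOT, "phenotype basis", None),
    (QUALITY, "quality", QUALITY_ROOT),
    (PROCESS, "biological process", QUALITY_ROOT),
    (SIZE, "size", QUALITY),
    (DECREASED_SIZE, "decreased size", SIZE),
    (INCREASED_SIZE, "increased size", SIZE),
    (MORPHOLOGY, "morphology", QUALITY),
    (AMOUNT, "amount", QUALITY),
    (DECREASED_AMOUNT, "decreased amount", AMOUNT),
    (INCREASED_AMOUNT, "increased amount", AMOUNT),
    (ABSENT, "absent", AMOUNT),
    (POSITION, "position", QUALITY),
    (MISLOCALISED, "mislocalised", POSITION),
    (STRUCTURE_QUALITY, "structure", QUALITY),
    (NECROTIC, "necrotic", STRUCTURE_QUALITY),
    (QUALITATIVE, "qualitative", QUALITY),
    (ABNORMAL, "abnormal", QUALITATIVE),
    (OCCURRENCE, "occurrence", QUALITY),
    (INCREASED_OCCURRENCE, "increased occurrence", OCCURRENCE),
    (DECREASED_OCCURRENCE, "decreased occurrence", OCCURRENCE),
    (APOPTOSIS, "apoptotic process", PROCESS),
    (PROLIFERATION, "cell population proliferation", PROCESS),
    (DEVELOPMENT, "developmental process", PROCESS),
]


def make_quality_ontology(spec: FixtureSpec = FixtureSpec()) -> OntologyGraph:
    """is_a-only tree of quality and process classes.

    Contains the abnormal modifier and the decreased/increased-size pair
    under a size quality; ``n_quality_terms`` extra leaf qualities pad the
    tree when requested.
    """
    graph = OntologyGraph()
    graph.header["format-version"] = "1.4"
    graph.header["ontology"] = "toy-quality"
    for tid, label, parent in _QUALITY_TREE:
        graph.add_term(Term(id=tid, label=label, definition=f"The quality {label!r}."))
        if parent is not None:
            graph.add_relationship(tid, "is_a", parent)
    for i in range(spec.n_quality_terms):
        tid = _q(100 + i)
        graph.add_term(Term(id=tid, label=f"extra quality {i + 1:03d}"))
        graph.add_relationship(tid, "is_a", QUALITY)
    graph.validate()
    return graph


# --- the auto-applied pattern suite ----------------------------------------

_VAR = "anatomical_entity"

#: the quality-style patterns: (pattern_id, quality label, quality CURIE,
#: label template, definition template, exact synonym template or None)
_QUALITY_PATTERNS = [
    ("abnormal_anatomical_entity", "quality", QUALITY,
     "abnormal %s", "Any abnormality of the %s.", None),
    ("absent_anatomical_entity", "absent", ABSENT,
     "absent %s", "Absence of the %s.", "missing %s"),
    ("abnormal_morphology_of_anatomical_entity", "morphology", MORPHOLOGY,
     "abnormal morphology of the %s", "Abnormal morphology of the %s.", None),
    ("mislocalized_anatomical_entity", "mislocalised", MISLOCALISED,
     "mislocalized %s", "Abnormal location of the %s.", "mislocalised %s"),
    ("necrotic_anatomical_entity", "necrotic", NECROTIC,
     "necrotic %s", "Necrosis of the %s.", None),
    ("abnormally_increased_size_of_anatomical_entity", "increased size", INCREASED_SIZE,
     "increased size of the %s", "Abnormally increased size of the %s.", "enlarged %s"),
    ("abnormally_decreased_size_of_anatomical_entity", "decreased size", DECREASED_SIZE,
     "decreased size of the %s", "Abnormally decreased size of the %s.", "small %s"),
    ("abnormally_increased_number_of_anatomical_entity", "increased amount", INCREASED_AMOUNT,
     "increased number of %s", "Abnormally increased number of %s.", None),
    ("abnormally_decreased_number_of_anatomical_entity", "decreased amount", DECREASED_AMOUNT,
     "decreased number of %s", "Abnormally decreased number of %s.", None),
]

#: the process-in-location patterns: (pattern_id, occurrence label,
#: occurrence CURIE, process label, process CURIE, label template,
#: definition template)
_PROCESS_PATTERNS = [
    ("abnormal_development_of_anatomical_entity", "quality", QUALITY,
     "developmental process", DEVELOPMENT,
     "abnormal development of the %s", "Abnormal development of the %s."),
    ("increased_apoptosis_in_anatomical_entity", "increased occurrence", INCREASED_OCCURRENCE,
     "apoptotic process", APOPTOSIS,
     "increased apoptosis in %s", "Abnormally increased apoptosis in the %s."),
    ("decreased_apoptosis_in_anatomical_entity", "decreased occurrence", DECREASED_OCCURRENCE,
     "apoptotic process", APOPTOSIS,
     "decreased apoptosis in %s", "Abnormally decreased apoptosis in the %s."),
    ("increased_cell_population_proliferation_in_anatomical_entity",
     "increased occurrence", INCREASED_OCCURRENCE,
     "cell population proliferation", PROLIFERATION,
     "increased cell population proliferation in %s",
     "Abnormally increased cell population proliferation in the %s."),
    ("decreased_cell_population_proliferation_in_anatomical_entity",
     "decreased occurrence", DECREASED_OCCURRENCE,
     "cell population proliferation", PROLIFERATION,
     "decreased cell population proliferation in %s",
     "Abnormally decreased cell population proliferation in the %s."),
]

ABNORMAL_PATTERN = "abnormal_anatomical_entity"

#: acellular-space filters: proliferation and apoptosis make no sense in
#: anatomical spaces, so those branches are filtered out for the four
#: process-rate patterns
SPACE_FILTERED_PATTERNS = (
    "increased_apoptosis_in_anatomical_entity",
    "decreased_apoptosis_in_anatomical_entity",
    "increased_cell_population_proliferation_in_anatomical_entity",
    "decreased_cell_population_proliferation_in_anatomical_entity",
)


def _pattern_doc(pid, classes, schema_text, label, definition, synonym):
    doc = {
        "pattern_name": pid,
        "classes": classes,
        "relations": dict(RELATION_CURIES),
        "vars": {_VAR: ROOT},
        "name": {"text": label, "vars": [_VAR]},
        "def": {"text": definition, "vars": [_VAR]},
        "equivalentTo": {"text": schema_text, "vars": [_VAR]},
    }
    if synonym:
        doc["exact_synonym"] = [{"text": synonym, "vars": [_VAR]}]
    if pid != ABNORMAL_PATTERN:
        doc["parent_patterns"] = [
            {"pattern": ABNORMAL_PATTERN, "vars": {_VAR: _VAR}}
        ]
    return doc


def make_pattern_suite(include_space_filters: bool = True) -> tuple[dict[str, str], str]:
    """The 14 auto-applied design patterns plus a matching selection config.

    Returns ``(pattern YAML texts keyed by pattern id, config YAML text)``.
    Every quality-specific pattern declares the plain "abnormal X" pattern
    as its parent, so generated classes always classify under the abnormal
    branch even where the structural rules alone cannot derive it.
    """
    suite: dict[str, str] = {}
    for pid, qlabel, qcurie, label, definition, synonym in _QUALITY_PATTERNS:
        classes = {"abnormal": ABNORMAL, qlabel: qcurie}
        schema = (
            f"'has part' some ('{qlabel}' and ('inheres in' some %s) "
            f"and ('has modifier' some abnormal))"
        )
        suite[pid] = yaml.safe_dump(
            _pattern_doc(pid, classes, schema, label, definition, synonym),
            sort_keys=False,
        )
    for pid, olabel, ocurie, plabel, pcurie, label, definition in _PROCESS_PATTERNS:
        classes = {"abnormal": ABNORMAL, olabel: ocurie, plabel: pcurie}
        schema = (
            f"'has part' some ('{olabel}' and ('inheres in' some "
            f"('{plabel}' and ('occurs in' some %s))) "
            f"and ('has modifier' some abnormal))"
        )
        suite[pid] = yaml.safe_dump(
            _pattern_doc(pid, classes, schema, label, definition, None),
            sort_keys=False,
        )

    config = {
        "ontology_id": "toy-phenotype",
        "data_version": "fixture/1.0",
        "root_class": {
            "id": f"{PHENOTYPE_PREFIX}:0000001",
            "label": "abnormal phenotype",
            "definition": "Any phenotypic abnormality of the toy organism.",
        },
        "traversal_relations": ["is_a", "part_of"],
        "auto_patterns": sorted(suite),
        "patterns": {pid: {"roots": [ROOT]} for pid in suite},
        "exclusions": {"terms": [], "branches": []},
        "filters": [
            {"pattern": pid, "forbid_branch": SPACE}
            for pid in SPACE_FILTERED_PATTERNS
        ]
        if include_space_filters
        else [],
        "relation_curies": dict(RELATION_CURIES),
    }
    return suite, yaml.safe_dump(config, sort_keys=False)
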