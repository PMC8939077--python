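"""Full release build: select/sync -> mint -> compile -> obsolete -> classify
-> QC -> serialize -> diff.

Every stage is logged (stage name, input/output counts) to the package
logger; identical inputs produce byte-identical OBO and JSON artifacts.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import yaml

from .classify import EntailmentEngine, SubsumptionResult, classify
from .errors import BuildError, PhenoforgeError
from .model import OntologyGraph, Term
from .obo import write_json_graph, write_obo
from .patterns import DesignPattern, InstanceTable, PhenotypeClass, compile_table
from .qc import (
    QcViolation,
    ReleaseDiff,
    diff_releases,
    has_errors,
    run_qc,
)
from .registry import IdRegistry, ObsoletionTable, apply_obsoletions, mint_ids
from .selection import SelectionConfig, SyncReport, sync_tables

log = logging.getLogger("phenoforge")


@dataclass
class BuildConfig:
    """Build-level settings on top of the selection configuration.

    The root phenotype class comes from the editors' side of the project,
    not from any pattern, so it is declared here.
    """

    selection: SelectionConfig
    root_id: str = "PHENO:0000001"
    root_label: str = "abnormal phenotype"
    root_definition: str | None = None
    ontology_id: str = "pheno"
    data_version: str | None = None
    relation_curies: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, text: str) -> "BuildConfig":
        doc = yaml.safe_load(text) or {}
        root = doc.get("root_class") or {}
        return cls(
            selection=SelectionConfig.from_yaml(text),
            root_id=root.get("id", "PHENO:0000001"),
            root_label=root.get("label", "abnormal phenotype"),
            root_definition=root.get("definition"),
            ontology_id=doc.get("ontology_id", "pheno"),
            data_version=doc.get("data_version"),
            relation_curies=dict(doc.get("relation_curies") or {}),
        )


@dataclass
class BuildResult:
    obo: str
    json: str
    classes: list[PhenotypeClass]
    subsumption: SubsumptionResult
    qc: list[QcViolation]
    diff: ReleaseDiff | None
    tables: dict[str, InstanceTable]
    registry: IdRegistry
    sync_report: SyncReport
    release_graph: OntologyGraph

    @property
    def exit_code(self) -> int:
        if has_errors(self.qc):
            return 1
        if self.diff is not None and not self.diff.ok:
            return 2
        return 0


def _stage(name: str, n_in: int, n_out: int, started: float) -> None:
    log.info(
        "stage=%s in=%d out=%d elapsed=%.3fs", name, n_in, n_out, time.monotonic() - started
    )


def build_release(
    config: BuildConfig,
    anatomy: OntologyGraph,
    quality: OntologyGraph,
    patterns: dict[str, DesignPattern],
    tables: dict[str, InstanceTable],
    registry: IdRegistry,
    obsoletions: ObsoletionTable | None = None,
    previous: OntologyGraph | None = None,
) -> BuildResult:
    """Run the whole pipeline and return every artifact of the release.

    Any stage failure aborts with a :class:`BuildError` carrying the stage
    name and cause.
    """
    return _build(config, anatomy, quality, patterns, tables, registry,
                  obsoletions, previous)


def _run(stage: str, fn):
    started = time.monotonic()
    try:
        result = fn()
    except Exception as exc:
        raise BuildError(stage, exc) from exc
    return result, started


def _build(config, anatomy, quality, patterns, tables, registry,
           obsoletions, previous) -> BuildResult:
    sel = config.selection

    (_, t0) = _run("parse_sources", lambda: (anatomy.validate(), quality.validate()))
    sel.validate_against(anatomy)
    _stage("parse_sources", len(anatomy.terms) + len(quality.terms),
           len(anatomy.terms) + len(quality.terms), t0)

    (synced, t0) = _run("sync", lambda: sync_tables(anatomy, sel, tables, patterns))
    synced_tables, sync_report = synced
    _stage("sync", len(tables), sync_report.n_added, t0)

    (minted, t0) = _run("mint", lambda: mint_ids(synced_tables, registry))
    _stage("mint", sum(len(t.rows) for t in minted.values()),
           len(registry.issued), t0)

    labels = {**quality.labels(), **anatomy.labels()}

    def _compile():
        out: list[PhenotypeClass] = []
        for pid in sorted(minted):
            if pid not in patterns:
                raise PhenoforgeError(f"table {pid!r} has no matching pattern")
            out.extend(compile_table(patterns[pid], minted[pid], labels))
        return out

    (classes, t0) = _run("compile", _compile)
    _stage("compile", sum(len(t.rows) for t in minted.values()), len(classes), t0)

    (classes, t0) = _run(
        "obsolete",
        lambda: apply_obsoletions(classes, obsoletions or ObsoletionTable()),
    )
    _stage("obsolete", len(classes), sum(1 for c in classes if c.obsolete), t0)

    engine = EntailmentEngine(anatomy, quality, patterns)
    (result, t0) = _run("classify", lambda: classify(classes, engine, config.root_id))
    _stage("classify", len(classes), len(result.edges), t0)

    (violations, t0) = _run(
        "qc", lambda: run_qc(classes, result.edges, [anatomy, quality])
    )
    # mutually entailing distinct classes are the "duplicate equivalent
    # classes" case even when their definitions differ textually
    dup_ids = {
        ids for v in violations if v.rule == "duplicate_logical_definition"
        for ids in [v.ids]
    }
    for a, b in result.equivalences:
        if (a, b) not in dup_ids:
            violations.append(
                QcViolation(
                    "duplicate_logical_definition",
                    (a, b),
                    "classes are mutually entailing (logically equivalent)",
                )
            )
    _stage("qc", len(classes), len(violations), t0)

    (release, t0) = _run(
        "serialize", lambda: _assemble_release(config, classes, result)
    )
    release_graph, obo_text, json_text = release
    _stage("serialize", len(classes), len(release_graph.terms), t0)

    diff = None
    if previous is not None:
        (diff, t0) = _run("diff", lambda: diff_releases(previous, release_graph))
        _stage("diff", len(previous.terms), len(diff.added) + len(diff.removed), t0)

    return BuildResult(
        obo=obo_text,
        json=json_text,
        classes=classes,
        subsumption=result,
        qc=violations,
        diff=diff,
        tables=minted,
        registry=registry,
        sync_report=sync_report,
        release_graph=release_graph,
    )


def _assemble_release(
    config: BuildConfig,
    classes: list[PhenotypeClass],
    result: SubsumptionResult,
) -> tuple[OntologyGraph, str, str]:
    graph = OntologyGraph()
    graph.header["format-version"] = "1.4"
    graph.header["ontology"] = config.ontology_id
    if config.data_version:
        graph.header["data-version"] = config.data_version
    graph.add_term(
        Term(
            id=config.root_id,
            label=config.root_label,
            definition=config.root_definition,
        )
    )
    for c in classes:
        graph.add_term(
            Term(
                id=c.id,
                label=c.label,
                definition=c.definition,
                synonyms=c.synonyms,
                obsolete=c.obsolete,
                replaced_by=c.replaced_by,
            )
        )
    for child, parent in result.edges:
        graph.add_relationship(child, "is_a", parent)
    logical = {
        c.id: c.logical_definition
        for c in classes
        if c.logical_definition is not None
    }
    obo_text = write_obo(graph)
    json_text = write_json_graph(
        graph, logical_definitions=logical, relation_curies=config.relation_curies
    )
    return graph, obo_text, json_text
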