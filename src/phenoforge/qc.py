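"""Quality control checks and release diffing."""
from __future__ import annotations

from dataclasses import dataclass, field

from .classify import expression_key
from .expressions import atoms
from .model import OntologyGraph
from .patterns import PhenotypeClass

ERROR_RULES = ("duplicate_label", "duplicate_logical_definition", "dangling_reference")
WARNING_RULES = ("missing_definition", "obsolete_with_logic")


@dataclass(frozen=True)
class QcViolation:
    rule: str
    ids: tuple[str, ...]
    message: str
    severity: str = "error"


def run_qc(
    classes: list[PhenotypeClass],
    edges: tuple[tuple[str, str], ...],
    sources: list[OntologyGraph],
) -> list[QcViolation]:
    """Run all QC rules; reports, never throws.

    Errors: case-insensitive duplicate labels among non-obsolete classes,
    structurally identical logical definitions under distinct ids, and
    dangling references (logical-definition atoms absent from every source
    ontology, replaced_by pointing outside the build). Warnings: missing
    text definitions, obsolete classes still carrying logic.
    """
    violations: list[QcViolation] = []
    live = [c for c in classes if not c.obsolete]
    class_ids = {c.id for c in classes}
    known: set[str] = set(class_ids)
    for src in sources:
        known |= set(src.terms)

    by_label: dict[str, list[str]] = {}
    for c in live:
        by_label.setdefault(c.label.lower(), []).append(c.id)
    for label, ids in sorted(by_label.items()):
        if len(ids) > 1:
            violations.append(
                QcViolation(
                    "duplicate_label",
                    tuple(sorted(ids)),
                    f"label {label!r} shared by {len(ids)} classes",
                )
            )

    by_def: dict[str, list[str]] = {}
    for c in live:
        if c.logical_definition is not None:
            by_def.setdefault(expression_key(c.logical_definition), []).append(c.id)
    for key, ids in sorted(by_def.items()):
        if len(ids) > 1:
            violations.append(
                QcViolation(
                    "duplicate_logical_definition",
                    tuple(sorted(ids)),
                    f"logical definition {key} shared by {len(ids)} classes",
                )
            )

    for c in sorted(classes, key=lambda c: c.id):
        if c.logical_definition is not None:
            missing = sorted(a for a in atoms(c.logical_definition) if a not in known)
            if missing:
                violations.append(
                    QcViolation(
                        "dangling_reference",
                        (c.id,),
                        f"logical definition references unknown term(s) {missing}",
                    )
                )
        if c.replaced_by is not None and c.replaced_by not in class_ids:
            violations.append(
                QcViolation(
                    "dangling_reference",
                    (c.id,),
                    f"replaced_by references unknown id {c.replaced_by}",
                )
            )
        if not c.obsolete and not c.definition:
            violations.append(
                QcViolation(
                    "missing_definition",
                    (c.id,),
                    "class has no text definition",
                    severity="warning",
                )
            )
        if c.obsolete and c.logical_definition is not None:
            violations.append(
                QcViolation(
                    "obsolete_with_logic",
                    (c.id,),
                    "obsolete class still carries a logical definition",
                )
            )
    return violations


def has_errors(violations: list[QcViolation]) -> bool:
    return any(v.severity == "error" for v in violations)


@dataclass(frozen=True)
class ReleaseDiff:
    """Term-level changes between two release graphs.

    A non-empty ``removed`` set (ids deleted outright rather than
    obsoleted in place) marks the diff as failing: terms must never
    silently disappear from a release.
    """

    added: frozenset[str] = frozenset()
    removed: frozenset[str] = frozenset()
    newly_obsoleted: frozenset[str] = frozenset()
    label_changed: frozenset[str] = frozenset()
    definition_changed: frozenset[str] = frozenset()

    @property
    def ok(self) -> bool:
        return not self.removed


def diff_releases(old: OntologyGraph, new: OntologyGraph) -> ReleaseDiff:
    old_ids = set(old.terms)
    new_ids = set(new.terms)
    common = old_ids & new_ids
    return ReleaseDiff(
        added=frozenset(new_ids - old_ids),
        removed=frozenset(old_ids - new_ids),
        newly_obsoleted=frozenset(
            t for t in common
            if new.terms[t].obsolete and not old.terms[t].obsolete
        ),
        label_changed=frozenset(
            t for t in common if old.terms[t].label != new.terms[t].label
        ),
        definition_changed=frozenset(
            t for t in common if old.terms[t].definition != new.terms[t].definition
        ),
    )


@dataclass
class Report:
    """Tabular QC / diff report rows for TSV output."""

    rows: list[dict[str, str]] = field(default_factory=list)
    columns: tuple[str, ...] = ()

    def to_tsv(self) -> str:
        import pandas as pd

        df = pd.DataFrame(self.rows, columns=list(self.columns))
        return df.to_csv(sep="\t", index=False)


def qc_report(violations: list[QcViolation]) -> Report:
    return Report(
        rows=[
            {"rule": v.rule, "ids": "|".join(v.ids), "message": v.message}
            for v in violations
        ],
        columns=("rule", "ids", "message"),
    )


def diff_report(diff: ReleaseDiff) -> Report:
    rows = []
    for change, ids in (
        ("added", diff.added),
        ("removed", diff.removed),
        ("newly_obsoleted", diff.newly_obsoleted),
        ("label_changed", diff.label_changed),
        ("definition_changed", diff.definition_changed),
    ):
        for tid in sorted(ids):
            rows.append({"change": change, "id": tid, "detail": ""})
    return Report(rows=rows, columns=("change", "id", "detail"))
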