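"""Design patterns: YAML templates that mint pre-composed phenotype classes.

A pattern declares variables (each ranging over a branch of a source
ontology), text templates for the label/definition/synonyms, and an
equivalence schema — the EL expression that becomes the logical definition
once variables are bound. Instantiating the pattern for one entity term
("heart", "eye", ...) produces one named, defined, logically-defined
phenotype class.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .errors import BindingError, PatternValidationError
from .expressions import (
    Expression,
    is_ground,
    parse_expression,
    substitute,
)
from .model import Synonym


@dataclass(frozen=True)
class TextTemplate:
    """A ``%s``-slotted text template with a parallel variable-reference list."""

    text: str
    var_refs: tuple[str, ...]

    def validate(self, declared: set[str], context: str) -> None:
        slots = self.text.count("%s")
        if slots != len(self.var_refs):
            raise PatternValidationError(
                f"{context}: {slots} slot(s) but {len(self.var_refs)} "
                f"variable reference(s)"
            )
        for var in self.var_refs:
            if var not in declared:
                raise PatternValidationError(
                    f"{context}: undeclared variable {var!r}"
                )

    def fill(self, values: list[str]) -> str:
        parts = self.text.split("%s")
        out = [parts[0]]
        for value, tail in zip(values, parts[1:]):
            out.append(value)
            out.append(tail)
        return "".join(out)


@dataclass(frozen=True)
class ParentPatternLink:
    """Declares that every instance of this pattern is subsumed by the
    mapped instance of ``parent_id`` (``var_map``: parent var -> child var)."""

    parent_id: str
    var_map: tuple[tuple[str, str], ...]


@dataclass
class DesignPattern:
    pattern_id: str
    classes: dict[str, str]
    relations: dict[str, str]
    variables: dict[str, str]  # name -> range CURIE (insertion-ordered)
    name_template: TextTemplate
    def_template: TextTemplate | None
    synonym_templates: tuple[TextTemplate, ...]
    schema: Expression
    parent_patterns: tuple[ParentPatternLink, ...] = ()


@dataclass
class PhenotypeClass:
    """A generated pre-composed phenotype term."""

    id: str
    label: str
    definition: str | None
    synonyms: tuple[Synonym, ...]
    logical_definition: Expression | None
    provenance: tuple[str, tuple[tuple[str, str], ...]]  # (pattern_id, bindings)
    obsolete: bool = False
    replaced_by: str | None = None


def parse_pattern(yaml_text: str, pattern_id: str | None = None) -> DesignPattern:
    """Parse and validate a design-pattern YAML document.

    Template/variable mismatches (slot-count errors, undeclared variables)
    are rejected with :class:`PatternValidationError`.
    """
    try:
        doc = yaml.safe_load(yaml_text)
    except yaml.YAMLError as exc:
        raise PatternValidationError(f"invalid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise PatternValidationError("pattern document is not a mapping")

    pid = doc.get("pattern_name") or pattern_id
    if not pid:
        raise PatternValidationError("pattern_name is required")
    variables = dict(doc.get("vars") or {})
    if not variables:
        raise PatternValidationError(f"{pid}: no variables declared")
    classes = dict(doc.get("classes") or {})
    relations = dict(doc.get("relations") or {})
    declared = set(variables)

    def template(section, context, required=False) -> TextTemplate | None:
        block = doc.get(section)
        if block is None:
            if required:
                raise PatternValidationError(f"{pid}: missing {section!r} block")
            return None
        t = TextTemplate(str(block["text"]), tuple(block.get("vars") or ()))
        t.validate(declared, f"{pid}.{context}")
        return t

    name_template = template("name", "name", required=True)
    def_template = template("def", "def")
    synonym_templates = []
    for i, block in enumerate(doc.get("exact_synonym") or []):
        t = TextTemplate(str(block["text"]), tuple(block.get("vars") or ()))
        t.validate(declared, f"{pid}.exact_synonym[{i}]")
        synonym_templates.append(t)

    eq = doc.get("equivalentTo")
    if not eq:
        raise PatternValidationError(f"{pid}: missing equivalentTo block")
    eq_vars = tuple(eq.get("vars") or ())
    for var in eq_vars:
        if var not in declared:
            raise PatternValidationError(
                f"{pid}.equivalentTo: undeclared variable {var!r}"
            )
    try:
        schema = parse_expression(str(eq["text"]), list(eq_vars), classes, relations)
    except Exception as exc:
        raise PatternValidationError(f"{pid}.equivalentTo: {exc}") from exc

    parents = []
    for block in doc.get("parent_patterns") or []:
        var_map = tuple(sorted((block.get("vars") or {}).items()))
        for _, child_var in var_map:
            if child_var not in declared:
                raise PatternValidationError(
                    f"{pid}.parent_patterns: undeclared variable {child_var!r}"
                )
        parents.append(ParentPatternLink(block["pattern"], var_map))

    return DesignPattern(
        pattern_id=pid,
        classes=classes,
        relations=relations,
        variables=variables,
        name_template=name_template,
        def_template=def_template,
        synonym_templates=tuple(synonym_templates),
        schema=schema,
        parent_patterns=tuple(parents),
    )


def instantiate(
    pattern: DesignPattern,
    bindings: dict[str, str],
    labels: dict[str, str],
    id: str,
) -> PhenotypeClass:
    """Fill a pattern's templates and schema for one binding tuple.

    Pure function: identical inputs yield an identical class.
    """
    missing = [v for v in pattern.variables if v not in bindings]
    if missing:
        raise BindingError(
            f"{pattern.pattern_id}: missing binding(s) for {missing}"
        )
    for var, curie in bindings.items():
        if var not in pattern.variables:
            raise BindingError(f"{pattern.pattern_id}: unknown variable {var!r}")
        if curie not in labels:
            raise BindingError(
                f"{pattern.pattern_id}: no label for bound term {curie}"
            )

    def fill(t: TextTemplate) -> str:
        return t.fill([labels[bindings[v]] for v in t.var_refs])

    logical = substitute(pattern.schema, bindings)
    assert is_ground(logical)
    return PhenotypeClass(
        id=id,
        label=fill(pattern.name_template),
        definition=fill(pattern.def_template) if pattern.def_template else None,
        synonyms=tuple(Synonym(fill(t), "EXACT") for t in pattern.synonym_templates),
        logical_definition=logical,
        provenance=(pattern.pattern_id, tuple(sorted(bindings.items()))),
    )


# --- instance tables --------------------------------------------------------

ID_COLUMN = "defined_class"
LABEL_COLUMN = "defined_class_label"


@dataclass
class InstanceTable:
    """A TSV table binding one pattern's variables to entity terms.

    Rows are dicts keyed by column name; ``defined_class`` holds the minted
    CURIE (blank until minting).
    """

    pattern_id: str
    columns: tuple[str, ...]
    rows: list[dict[str, str]] = field(default_factory=list)

    @classmethod
    def empty(cls, pattern_id: str, variables: list[str]) -> "InstanceTable":
        cols = [ID_COLUMN, LABEL_COLUMN]
        for v in variables:
            cols.extend([v, f"{v}_label"])
        return cls(pattern_id, tuple(cols))

    @classmethod
    def from_tsv(cls, text: str, pattern_id: str) -> "InstanceTable":
        df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str, keep_default_na=False)
        if ID_COLUMN not in df.columns:
            raise PatternValidationError(
                f"table {pattern_id}: missing {ID_COLUMN!r} column"
            )
        return cls(pattern_id, tuple(df.columns), df.to_dict(orient="records"))

    def to_tsv(self) -> str:
        df = pd.DataFrame(self.rows, columns=list(self.columns), dtype=str)
        return df.fillna("").to_csv(sep="\t", index=False)

    def variable_columns(self) -> tuple[str, ...]:
        return tuple(
            c
            for c in self.columns
            if c not in (ID_COLUMN, LABEL_COLUMN) and not c.endswith("_label")
        )

    def bindings(self, row: dict[str, str]) -> dict[str, str]:
        return {c: row[c] for c in self.variable_columns()}


def compile_table(
    pattern: DesignPattern,
    table: InstanceTable,
    labels: dict[str, str],
) -> list[PhenotypeClass]:
    """Instantiate the pattern for every table row, in row order.

    Every row must carry a minted id; duplicate binding tuples and columns
    that name no declared pattern variable are rejected.
    """
    unknown = [c for c in table.variable_columns() if c not in pattern.variables]
    if unknown:
        raise PatternValidationError(
            f"table {table.pattern_id}: column(s) {unknown} name no "
            f"variable of pattern {pattern.pattern_id}"
        )
    missing = [v for v in pattern.variables if v not in table.columns]
    if missing:
        raise PatternValidationError(
            f"table {table.pattern_id}: missing column(s) for variable(s) {missing}"
        )
    seen: dict[tuple, str] = {}
    out: list[PhenotypeClass] = []
    for idx, row in enumerate(table.rows):
        cid = row.get(ID_COLUMN, "")
        if not cid:
            raise BindingError(
                f"table {table.pattern_id} row {idx}: id not minted"
            )
        bindings = table.bindings(row)
        key = tuple(sorted(bindings.items()))
        if key in seen:
            raise BindingError(
                f"table {table.pattern_id}: rows for {seen[key]} and {cid} "
                f"bind identical terms {dict(bindings)}"
            )
        seen[key] = cid
        out.append(instantiate(pattern, bindings, labels, cid))
    return out
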