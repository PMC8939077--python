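# phenoforge

`phenoforge` compiles **pre-composed phenotype ontologies**. Given an
anatomy/quality ontology, a library of design-pattern templates, and TSV
tables binding pattern variables to entity terms, it produces a fully
classified, QC-checked ontology release — with deterministic identifier
minting, obsoletion management, and release-to-release diffing.

It is aimed at model-organism ontology engineers who maintain phenotype
ontologies built almost entirely by template: instead of hand-curating a
class for "abnormal *X*" every time a new anatomy term *X* appears, the
pipeline scans the source ontology, applies a configured set of design
patterns, and regenerates the release.

## The model

Phenotype curation pairs an **entity** E (an anatomy or process term) with
a **quality** Q ("decreased size", "absent", ...). A *pre-composed*
phenotype ontology names each useful (E, Q) pair as its own class, with a
logical definition in an EL-style fragment:

```
'decreased size of the heart' EquivalentTo
    has_part some (decreased_size
                   and (inheres_in some heart)
                   and (has_modifier some abnormal))
```

A **design pattern** is a YAML template declaring variables, text templates
for the label/definition/synonyms, and the equivalence schema above with a
variable slot in place of `heart`. Instantiating the pattern over every
selected anatomy term generates the ontology.

Three rules give the compiler its semantics:

* **Selection** walks the anatomy downward from configured roots using only
  `is_a` and `part_of` — never `develops_from`, because a phenotype in a
  developed structure does not imply a phenotype in its precursor. Exclusion
  lists and per-pattern applicability filters prune biologically
  meaningless combinations (e.g. cell proliferation inside an acellular
  anatomical space).
* **Classification** derives the entire is_a hierarchy from the logical
  definitions alone — structural subsumption over atoms (closed under
  `is_a` + `part_of` for entities, `is_a` for qualities), existential
  restrictions, intersections, and declared parent-pattern links. The
  released hierarchy contains only `is_a` edges and reflects, without
  duplicating, the source anatomy.
* **Identity**: every generated class id is minted once for its
  (pattern, bindings) tuple and recorded in a TSV ledger; terms are retired
  by obsoletion with `replaced_by`, never deleted, and the release diff
  fails if any id disappears outright.

## Worked example

```bash
python examples/build_toy_release.py
```

```
anatomy terms:       30
phenotype classes:   408
release terms:       409 (classes + root)
direct is_a edges:   773
QC violations:       0
exit code:           0

first release stanza:
[Term]
id: TOYP:0000001
name: abnormal phenotype
def: "Any phenotypic abnormality of the toy organism." []
```

The synthetic anatomy has 30 terms and the shipped suite has 14
auto-applied patterns, so the count law predicts 14 × 30 = 420 classes;
the applicability filters remove the four proliferation/apoptosis patterns
from the 3-term anatomical-space branch (−12), leaving 408. Every class
reaches the root purely through derived `is_a` edges. The other example
scripts show single-pattern instantiation (`instantiate_pattern.py`),
table syncing and id minting (`sync_and_mint.py`), and the obsoletion
workflow with release diffing (`obsolete_and_diff.py`).

A thin CLI wraps the same library:

```bash
phenoforge build --anatomy anatomy.obo --quality quality.obo \
    --patterns patterns/ --tables tables/ --config config.yaml \
    --registry registry.tsv --out-obo release.obo --out-json release.json
phenoforge sync ... ; phenoforge qc ... ; phenoforge diff --old a.obo --new b.obo
```

Exit codes: 0 clean, 1 QC error, 2 failing diff, 3 input error.

## Layout

```
src/phenoforge/
  model.py        in-memory ontology graph and invariants
  obo.py          OBO 1.4 dialect parser/serializer + JSON release writer
  expressions.py  EL-style class expressions: grammar, substitution, unification
  patterns.py     design patterns, instantiation, TSV instance tables
  selection.py    relation-restricted traversal, exclusions, table sync
  registry.py     id minting ledger and obsoletion handling
  classify.py     structural subsumption and is_a hierarchy derivation
  qc.py           QC rules and release diffing
  pipeline.py     full build orchestration
  fixtures.py     synthetic anatomy/quality ontologies and the 14-pattern suite
  cli.py          command-line interface
```

See `docs/methods.md` for the method description, numerical choices, and
known limitations.
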