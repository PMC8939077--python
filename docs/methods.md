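# Methods

## Overview

`phenoforge` is a compiler from *(source ontologies, design patterns,
instantiation tables, selection config)* to a classified phenotype
ontology release. The pipeline runs in a fixed order — parse sources →
select/sync → mint → compile → obsolete → classify → QC → serialize →
diff — and each stage is a pure function of its inputs, so identical
inputs yield byte-identical OBO and JSON artifacts.

## Ontology model and OBO dialect

The in-memory graph is a term table plus a flat list of typed edges whose
predicates are relation *names* (`is_a`, `part_of`, `develops_from`, ...);
relation-name-to-CURIE mapping is applied only when serializing logical
definitions, via the `relation_curies` config map. Invariants enforced on
every parse and before every write: ids are CURIEs (`PREFIX:digits`), the
`is_a` subgraph is acyclic, no edge references an unknown term,
`replaced_by` appears only on obsolete terms.

The OBO reader/writer supports a closed dialect: header tags
`format-version`/`ontology`/`data-version`; term tags `id`, `name`, `def`
(with dbxref list), `synonym` (quoted text + scope), `is_a`,
`relationship`, `is_obsolete`, `replaced_by`. Unknown tag lines round-trip
opaquely, unknown stanzas (e.g. `[Typedef]`) are preserved verbatim.
Serialization is deterministic — terms sorted by CURIE, tags in fixed
order, edges sorted by (subject, predicate, object), UTF-8, LF — which
makes releases diffable at the byte level and gives the round-trip law
`parse(write(g)) == g`. Logical definitions are not emitted as OBO
`intersection_of` lines; they live in the JSON release (as rendered
expression strings on nodes) and in class provenance.

## Expressions and patterns

Logical definitions use an EL-style fragment: class atoms, existential
restrictions over named relations, and intersections. Intersections are
kept canonical (flattened, deduplicated, sorted by rendered form), so
structural equality of expressions is textual equality of their canonical
rendering — this is what the duplicate-definition QC rule and the
classifier's equivalence detection compare.

A design pattern declares an ordered variable list (each with a range
class), `%s`-slotted text templates paired with positional
variable-reference lists, and an equivalence schema written as a
parenthesized expression string over quoted class/relation names with
`%s` slots. Validation rejects slot-count mismatches and undeclared
variables at parse time. No inflection logic is applied: articles such as
"the" are written into template text, generated labels are used verbatim,
and generated synonyms are scoped EXACT.

Patterns may declare `parent_patterns` links — (parent pattern, variable
mapping) pairs asserting that every instance is subsumed by the mapped
parent instance. The shipped suite wires every quality-specific pattern
under the plain "abnormal X" pattern.

## Selection

`descendants(graph, root, relations)` is the reflexive set of terms that
reach `root` through chains of the chosen relations (cycles over the
chosen relation set are rejected). Per-pattern selection is the union of
the pattern's inclusion-root closures minus excluded terms, excluded
branches, applicability-filter branches bound to that pattern, and
obsolete terms; exclusion always beats inclusion in multi-parent DAGs.

The default traversal set is `{is_a, part_of}`. `develops_from` is
structurally banned from traversal: configuring it raises an error rather
than silently propagating phenotypes onto developmental precursors.
Whether the *inverse* direction (abnormal development of a precursor
implying abnormal development of the derivative) should ever propagate is
left as this explicit config-level refusal.

Table sync adds a blank-id row for every newly selected entity of every
auto pattern and flags — never deletes — rows whose entity is gone,
obsolete, or no longer selected. Rows are kept sorted by entity CURIE and
tables are visited in pattern-id order, which fixes the minting order.
Auto patterns must have exactly one variable; multi-variable patterns are
populated by explicit table rows instead.

## Identifier minting

Ids are `PREFIX:` plus a zero-padded number (width 7 by default,
configurable). The registry is a TSV ledger of (id, pattern, bindings,
issued_on). Minting fills blank ids consecutively in deterministic table
order; a (pattern, bindings) tuple that was ever issued an id gets the
same id back even if its row was deleted and re-added, and an id is never
reused. Rows carrying an id are checked against the ledger and a
provenance mismatch (same id, different bindings) aborts the build. The
`issued_on` column defaults to the empty string so ledger files are
byte-reproducible; callers may stamp a date.

Obsoletion is driven by a TSV of (id, replaced_by, reason). Obsoleted
classes keep their id, get an `obsolete `-prefixed label, lose their
logical definition, gain `replaced_by`, and remain in the release.
Replacement targets must be live in the same build — no transitive
resolution of replacement chains.

## Classification

The hierarchy is derived entirely from logical definitions by structural
subsumption, `entails(a, b)`:

1. atoms: `X ⊑ Y` iff `Y` is in `X`'s closure — over `{is_a, part_of}`
   when `X` is an entity (anatomy) atom, over `is_a` when it is a
   quality/process atom. Folding `part_of` into the entity closure is what
   propagates "abnormal eye" under "abnormal visual system";
   `develops_from` edges never enter any closure;
2. existential restrictions: same relation and filler entailment;
3. intersections: `a ⊑ b1 ⊓ ... ⊓ bk` iff `a` entails every conjunct; a
   conjunction entails a non-conjunction if any conjunct does;
4. pattern lattice: if `a` unifies with a pattern schema, `a` entails the
   schema of each declared parent pattern instantiated through the
   variable mapping. This covers cross-pattern subsumptions rules 1–3
   cannot see, such as "increased apoptosis in X" under "abnormal X",
   where the process nests inside an `occurs_in` restriction.

`classify()` computes all-pairs entailment among non-obsolete classes,
reports mutually-entailing pairs as equivalences (tie-broken to no edge
between them, both classes kept, routed to QC), takes the transitive
reduction of the remaining strict order, and attaches parentless classes
to the configured root. The output therefore contains only `is_a` edges,
is acyclic, and every class reaches the root.

Entailment decisions and per-expression lattice parents are memoized, and
expression nodes cache their hashes; a 420-class build classifies in
roughly two seconds on one CPU. This is *not* a general EL reasoner:
there is no role chaining beyond the fixed `part_of` folding, no
axiom-level reasoning over the source ontologies, and completeness is
claimed only for the schema shapes the shipped patterns use — a
deliberate, documented restriction.

## QC and diffing

Five rules, reported rather than thrown: `duplicate_label`
(case-insensitive, non-obsolete classes), `duplicate_logical_definition`
(canonical-form identity, plus mutually-entailing pairs found during
classification), `dangling_reference` (definition atoms unknown to every
source; `replaced_by` pointing outside the build) — all errors that fail
the build — and `missing_definition` (warning), `obsolete_with_logic`.

`diff_releases(old, new)` partitions term ids into added / removed /
newly-obsoleted / label-changed / definition-changed. A non-empty
`removed` set (ids deleted outright rather than obsoleted in place) marks
the diff as failing; the build exit codes are 0 clean, 1 QC error, 2
failing diff, 3 input error.

## Synthetic fixtures

`make_toy_anatomy` emulates the shape of a real anatomy ontology: a
handcrafted 13-term skeleton (root "anatomical entity", structure and
space branches, whole organism, visual system ⊃ eye ⊃ retina/lens,
cardiovascular system ⊃ heart, an optic vesicle linked to the eye only by
`develops_from`) grown to `n_entities` with a seeded single-parent
backbone whose `is_a`/`part_of` split follows `relation_mix`; the
`develops_from` share sizes the count of extra lineage edges (always
≥ 1). Randomness comes from an explicit `random.Random(seed)` — never
global state — so fixtures are identical across platforms for a fixed
seed.

`make_quality_ontology` is a fixed `is_a` tree. Because four shipped
patterns need process classes (apoptosis, proliferation, development) as
well as qualities, both live in one single-rooted support tree
("phenotype basis" → quality, biological process); this is a fixture
simplification, not a claim about real quality ontologies.

`make_pattern_suite` ships the 14 auto-applied patterns (abnormal,
absent, abnormal morphology, abnormal development, mislocalized,
necrotic, increased/decreased size, increased/decreased number,
increased/decreased apoptosis, increased/decreased proliferation), all
over a single anatomical-entity variable, each non-base pattern declaring
"abnormal X" as its parent, plus a config whose applicability filters
remove the four process-rate patterns from the anatomical-space branch.
No published ontology prints its schemas verbatim, so the suite adopts
the common convention `has_part some (Q and (inheres_in some E) and
(has_modifier some abnormal))`, nesting `(P and occurs_in some E)` inside
`inheres_in` for process patterns; the suite documents this shape rather
than claiming token-level fidelity to any released ontology.

What the fixtures do **not** emulate: realistic anatomy topology (branch
widths, depth distributions), multi-parent entity terms at scale,
multi-variable pattern tables, real label vocabularies, or source-ontology
obsoletion churn. Passing tests demonstrate the compiler's laws
(count conservation, determinism, id stability, traversal restrictions,
oracle-equivalent classification) on inputs with the right structure, not
performance or curation quality on a production-sized ontology.

## Problem sizes and numerical choices

Tests and the acceptance script use 15–40-term anatomies, 14 patterns
(~200–420 classes per build), 20-seed oracle comparisons capped at 50
classes each — sizes chosen so the brute-force all-pairs oracle stays
exact and the whole suite runs in well under a minute of pure
computation per build. There are no floating-point tolerances anywhere:
every check in this package is exact (string, set, or integer equality).
Tie-breaks are all lexicographic by CURIE (term order in releases, row
order in tables, edge order in results); degenerate inputs (empty
documents, empty tables, empty obsoletion lists) are identities, and
infeasible fixture specs (backbone proportions summing to zero, fewer
than 3 entities) are rejected rather than repaired.

## Known limitations

* The classifier's completeness is relative to the shipped schema shapes;
  arbitrary EL expressions may be under-classified (never
  over-classified — every derived edge is sound under the stated rules).
* OBO coverage is the release dialect only: no `intersection_of`,
  typedef semantics, or OWL emission.
* Auto-application handles single-variable patterns; multi-variable
  patterns require curated tables.
* Merging two anatomy terms is handled as obsoletion-with-replacement of
  the affected phenotype classes, not as id rewriting.
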