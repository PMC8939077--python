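"""Structural subsumption: entailment rules, classification, oracle equivalence."""
import copy
import random

import pytest

from phenoforge import (
    EntailmentEngine,
    FixtureSpec,
    all_pairs_entailment,
    classify,
    instantiate,
    make_quality_ontology,
    make_toy_anatomy,
    parse_pattern,
)
from phenoforge.classify import closure
from phenoforge.errors import ExpressionError
from phenoforge.fixtures import (
    EYE,
    HEART,
    OPTIC_VESICLE,
    RETINA,
    VISUAL_SYSTEM,
)

ROOT_CLASS = "TOYP:0000001"
ABNORMAL = "abnormal_anatomical_entity"
DECREASED_SIZE = "abnormally_decreased_size_of_anatomical_entity"
APOPTOSIS_IN = "increased_apoptosis_in_anatomical_entity"


def _instances(patterns, anatomy, pattern_entities):
    """Instantiate (pattern_id, entity) pairs with sequential ids."""
    labels = anatomy.labels()
    out = []
    n = 10
    for pid, entity in pattern_entities:
        out.append(
            instantiate(patterns[pid], {"anatomical_entity": entity}, labels, f"TOYP:{n:07d}")
        )
        n += 1
    return out


def test_part_of_propagates_subsumption(patterns, anatomy, engine):
    eye, visual = _instances(patterns, anatomy, [(ABNORMAL, EYE), (ABNORMAL, VISUAL_SYSTEM)])
    assert engine.entails(eye.logical_definition, visual.logical_definition)
    assert not engine.entails(visual.logical_definition, eye.logical_definition)


def test_develops_from_does_not_propagate(patterns, anatomy, engine):
    eye, vesicle = _instances(patterns, anatomy, [(ABNORMAL, EYE), (ABNORMAL, OPTIC_VESICLE)])
    assert not engine.entails(eye.logical_definition, vesicle.logical_definition)
    assert not engine.entails(vesicle.logical_definition, eye.logical_definition)


def test_every_expression_entails_itself(patterns, anatomy, engine):
    for cls in _instances(
        patterns, anatomy, [(pid, EYE) for pid in sorted(patterns)]
    ):
        assert engine.entails(cls.logical_definition, cls.logical_definition)


def test_quality_specific_pattern_under_abnormal(patterns, anatomy, engine):
    small, abnormal = _instances(patterns, anatomy, [(DECREASED_SIZE, EYE), (ABNORMAL, EYE)])
    assert engine.entails(small.logical_definition, abnormal.logical_definition)
    assert not engine.entails(abnormal.logical_definition, small.logical_definition)


def test_process_pattern_under_abnormal_via_parent_link(patterns, anatomy, engine):
    apo, abnormal = _instances(patterns, anatomy, [(APOPTOSIS_IN, EYE), (ABNORMAL, EYE)])
    assert engine.entails(apo.logical_definition, abnormal.logical_definition)
    # and the lattice composes with the entity closure: eye part_of visual system
    (abn_vs,) = _instances(patterns, anatomy, [(ABNORMAL, VISUAL_SYSTEM)])
    assert engine.entails(apo.logical_definition, abn_vs.logical_definition)


def test_unknown_curie_in_expression_rejected(patterns, anatomy, engine):
    (cls,) = _instances(patterns, anatomy, [(ABNORMAL, EYE)])
    from phenoforge.expressions import Atom

    with pytest.raises(ExpressionError, match="unknown class"):
        engine.entails(Atom("ZZZ:0000001"), cls.logical_definition)


def test_single_class_attaches_to_root(patterns, anatomy, engine):
    classes = _instances(patterns, anatomy, [(ABNORMAL, EYE)])
    result = classify(classes, engine, ROOT_CLASS)
    assert result.edges == ((classes[0].id, ROOT_CLASS),)


def test_direct_edge_reflects_part_of(patterns, anatomy, engine):
    classes = _instances(
        patterns, anatomy, [(ABNORMAL, EYE), (ABNORMAL, VISUAL_SYSTEM), (ABNORMAL, RETINA)]
    )
    result = classify(classes, engine, ROOT_CLASS)
    by_entity = {dict(c.provenance[1])["anatomical_entity"]: c.id for c in classes}
    assert (by_entity[EYE], by_entity[VISUAL_SYSTEM]) in result.edges
    assert (by_entity[RETINA], by_entity[EYE]) in result.edges
    # transitive reduction: no shortcut edge retina -> visual system
    assert (by_entity[RETINA], by_entity[VISUAL_SYSTEM]) not in result.edges


def _random_classes(seed, patterns, anatomy, max_classes=50):
    rng = random.Random(seed)
    pattern_ids = rng.sample(sorted(patterns), rng.randint(2, 5))
    entities = sorted(anatomy.terms)
    pairs = []
    for pid in pattern_ids:
        chosen = rng.sample(entities, rng.randint(3, min(10, len(entities))))
        pairs.extend((pid, e) for e in chosen)
    return _instances(patterns, anatomy, pairs[:max_classes])


@pytest.mark.parametrize("seed", range(5))
def test_classify_closure_matches_brute_force_oracle(seed, patterns):
    anatomy = make_toy_anatomy(FixtureSpec(seed=seed + 100, n_entities=20))
    quality = make_quality_ontology()
    engine = EntailmentEngine(anatomy, quality, patterns)
    classes = _random_classes(seed, patterns, anatomy)
    result = classify(classes, engine, ROOT_CLASS)
    derived = {(a, b) for a, b in closure(result.edges) if b != ROOT_CLASS}
    oracle = all_pairs_entailment(classes, engine)
    assert derived == oracle


def test_output_is_acyclic_and_every_class_reaches_root(patterns, anatomy, engine):
    classes = _random_classes(3, patterns, anatomy)
    result = classify(classes, engine, ROOT_CLASS)
    reach = closure(result.edges)
    for cls in classes:
        assert (cls.id, ROOT_CLASS) in reach
        assert (cls.id, cls.id) not in reach  # acyclicity


def test_develops_from_independence_of_classification(patterns, quality):
    anatomy = make_toy_anatomy(FixtureSpec(seed=11, n_entities=25))
    stripped = copy.deepcopy(anatomy)
    stripped.relationships = [
        r for r in stripped.relationships if r.predicate != "develops_from"
    ]
    classes = _random_classes(7, {k: v for k, v in _suite_patterns().items()}, anatomy)
    full = classify(classes, EntailmentEngine(anatomy, quality, _suite_patterns()), ROOT_CLASS)
    less = classify(classes, EntailmentEngine(stripped, quality, _suite_patterns()), ROOT_CLASS)
    assert full.edges == less.edges


def _suite_patterns():
    from phenoforge import make_pattern_suite

    suite, _ = make_pattern_suite()
    return {pid: parse_pattern(text) for pid, text in suite.items()}


def test_equivalent_duplicates_reported_and_tie_broken(patterns, anatomy, engine):
    a, b = _instances(patterns, anatomy, [(ABNORMAL, EYE), (ABNORMAL, EYE)])
    assert a.id != b.id and a.logical_definition == b.logical_definition
    result = classify([a, b], engine, ROOT_CLASS)
    assert result.equivalences == (tuple(sorted((a.id, b.id))),)
    assert (a.id, b.id) not in result.edges
    assert (b.id, a.id) not in result.edges
    assert (a.id, ROOT_CLASS) in result.edges
    assert (b.id, ROOT_CLASS) in result.edges


def test_quality_swap_in_schema_reclassifies_on_rebuild(anatomy, quality):
    """Swapping the quality atom of a pattern re-derives subsumption with
    no manual edits (the pattern-update workflow)."""
    size_pattern = """\
pattern_name: size_of_anatomical_entity
classes:
  abnormal: TOYQ:0000023
  size: TOYQ:0000010
relations: {has part: TOYR:0000001, inheres in: TOYR:0000002, has modifier: TOYR:0000003}
vars: {anatomical_entity: TOYA:0000001}
name: {text: size phenotype of %s, vars: [anatomical_entity]}
equivalentTo:
  text: "'has part' some (size and ('inheres in' some %s) and ('has modifier' some abnormal))"
  vars: [anatomical_entity]
"""
    child_template = """\
pattern_name: changed_quality_of_anatomical_entity
classes:
  abnormal: TOYQ:0000023
  the quality: {quality}
relations: {{has part: TOYR:0000001, inheres in: TOYR:0000002, has modifier: TOYR:0000003}}
vars: {{anatomical_entity: TOYA:0000001}}
name: {{text: changed quality of %s, vars: [anatomical_entity]}}
equivalentTo:
  text: "'has part' some ('the quality' and ('inheres in' some %s) and ('has modifier' some abnormal))"
  vars: [anatomical_entity]
"""

    def build(quality_curie):
        patterns = {
            "size_of_anatomical_entity": parse_pattern(size_pattern),
            "changed_quality_of_anatomical_entity": parse_pattern(
                child_template.format(quality=quality_curie)
            ),
        }
        labels = anatomy.labels()
        classes = [
            instantiate(patterns["size_of_anatomical_entity"],
                        {"anatomical_entity": HEART}, labels, "TOYP:0000020"),
            instantiate(patterns["changed_quality_of_anatomical_entity"],
                        {"anatomical_entity": HEART}, labels, "TOYP:0000021"),
        ]
        engine = EntailmentEngine(anatomy, quality, patterns)
        return classify(classes, engine, ROOT_CLASS)

    with_size_quality = build("TOYQ:0000011")  # decreased size: under the size pattern
    assert ("TOYP:0000021", "TOYP:0000020") in with_size_quality.edges
    with_position_quality = build("TOYQ:0000019")  # mislocalised: not a size
    assert ("TOYP:0000021", "TOYP:0000020") not in with_position_quality.edges
    assert ("TOYP:0000021", ROOT_CLASS) in with_position_quality.edges
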