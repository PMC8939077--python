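"""Instantiate one design pattern by hand.

Parses the "abnormally decreased size" pattern from the shipped suite and
fills it for the fixture heart term, printing the generated label,
definition, and logical definition.
"""
from phenoforge import make_pattern_suite, make_toy_anatomy, parse_pattern, instantiate
from phenoforge.expressions import render
from phenoforge.fixtures import HEART, RELATION_CURIES

suite, _ = make_pattern_suite()
pattern = parse_pattern(suite["abnormally_decreased_size_of_anatomical_entity"])
anatomy = make_toy_anatomy()

cls = instantiate(
    pattern, {"anatomical_entity": HEART}, anatomy.labels(), "TOYP:0103343"
)
print("id:        ", cls.id)
print("label:     ", cls.label)
print("definition:", cls.definition)
print("logic:     ", render(cls.logical_definition))
print("logic/CURIE:", render(cls.logical_definition, relation_map=RELATION_CURIES))
# The label is the pattern's text template with the bound term's name
# substituted; the logical definition is the equivalence schema with the
# variable slot replaced by the heart's CURIE — the class is fully defined
# by (pattern, binding), no manual curation involved.
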