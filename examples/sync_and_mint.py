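"""Keep the phenotype ontology in step with a growing anatomy ontology.

Syncs the auto-pattern tables against the anatomy, adds one new anatomy
term, re-syncs, and mints identifiers for the new rows.
"""
import copy

from phenoforge import (
    BuildConfig,
    IdRegistry,
    make_pattern_suite,
    make_toy_anatomy,
    mint_ids,
    parse_pattern,
    sync_tables,
)
from phenoforge.fixtures import HEART
from phenoforge.model import Term

anatomy = make_toy_anatomy()
suite, config_yaml = make_pattern_suite()
patterns = {pid: parse_pattern(text) for pid, text in suite.items()}
config = BuildConfig.from_yaml(config_yaml)
registry = IdRegistry(prefix="TOYP", width=7, next_id=2)

tables, first = sync_tables(anatomy, config.selection, {}, patterns)
tables = mint_ids(tables, registry)
print("initial sync added rows:", first.n_added)

grown = copy.deepcopy(anatomy)
grown.add_term(Term(id="TOYA:0008000", label="left cardiac valve"))
grown.add_relationship("TOYA:0008000", "part_of", HEART)
tables, second = sync_tables(grown, config.selection, tables, patterns)
tables = mint_ids(tables, registry)
print("rows added for the new term:", second.n_added)

row = [r for r in tables["abnormal_anatomical_entity"].rows
       if r["anatomical_entity"] == "TOYA:0008000"][0]
print("minted id for 'abnormal left cardiac valve':", row["defined_class"])
# One new anatomy term yields exactly one row per auto pattern (14 total);
# each blank row received a fresh, never-reused identifier recorded in the
# registry ledger together with its (pattern, binding) provenance.
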