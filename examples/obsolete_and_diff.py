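"""Retire a term through the obsoletion workflow and diff the releases.

Terms are never deleted: they stay in the release flagged obsolete with a
"replaced by" pointer, and the release diff proves nothing disappeared.
"""
from phenoforge import (
    BuildConfig,
    IdRegistry,
    ObsoletionTable,
    build_release,
    make_pattern_suite,
    make_quality_ontology,
    make_toy_anatomy,
    parse_pattern,
)

anatomy = make_toy_anatomy()
quality = make_quality_ontology()
suite, config_yaml = make_pattern_suite()
patterns = {pid: parse_pattern(text) for pid, text in suite.items()}
config = BuildConfig.from_yaml(config_yaml)
registry = IdRegistry(prefix="TOYP", width=7, next_id=2)

first = build_release(config, anatomy, quality, patterns, {}, registry)
victim, successor = first.classes[0].id, first.classes[1].id
obsoletions = ObsoletionTable([(victim, successor, "duplicate of successor")])

second = build_release(
    config, anatomy, quality, patterns, first.tables, registry,
    obsoletions=obsoletions, previous=first.release_graph,
)
diff = second.diff
print("obsoleted:", sorted(diff.newly_obsoleted))
print("removed:  ", sorted(diff.removed), "(must stay empty)")
print("diff ok:  ", diff.ok, "| exit code:", second.exit_code)
stanza = [s for s in second.obo.split("\n\n") if f"id: {victim}" in s][0]
print()
print(stanza)
# The obsoleted class keeps its id, gets an "obsolete "-prefixed label,
# loses its logical definition, and points consumers at its replacement —
# so downstream annotations never dangle.
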