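"""QC rules, release diffing, and the end-to-end build pipeline."""
import copy
import json

import pytest
from click.testing import CliRunner

from phenoforge import (
    IdRegistry,
    ObsoletionTable,
    build_release,
    diff_releases,
    instantiate,
    parse_obo,
    run_qc,
    write_obo,
)
from phenoforge.cli import main as cli_main
from phenoforge.fixtures import (
    EYE,
    HEART,
    RETINA,
    SPACE,
    make_pattern_suite,
    make_toy_anatomy,
    make_quality_ontology,
    FixtureSpec,
)
from phenoforge.model import OntologyGraph, Term
from phenoforge.qc import has_errors
from phenoforge.selection import SelectionConfig, descendants

ABNORMAL = "abnormal_anatomical_entity"


def _registry():
    return IdRegistry(prefix="TOYP", width=7, next_id=2)


def _abnormal_classes(patterns, anatomy, entities, start=10):
    labels = anatomy.labels()
    return [
        instantiate(patterns[ABNORMAL], {"anatomical_entity": e}, labels, f"TOYP:{start + i:07d}")
        for i, e in enumerate(entities)
    ]


def test_clean_single_pattern_build_has_no_violations(patterns, anatomy, quality):
    classes = _abnormal_classes(patterns, anatomy, [EYE, HEART])
    assert run_qc(classes, (), [anatomy, quality]) == []


def test_planted_duplicate_labels_detected_exactly(patterns, anatomy, quality):
    classes = _abnormal_classes(patterns, anatomy, [EYE, HEART, RETINA])
    k = 2
    classes[1].label = "Abnormal eye"  # case-insensitive clash with classes[0]
    classes[2].label = classes[2].label  # untouched
    extra = _abnormal_classes(patterns, anatomy, [SPACE], start=90)[0]
    extra.label = "necrotic lens"
    twin = _abnormal_classes(patterns, anatomy, [RETINA], start=91)[0]
    twin.label = "necrotic lens"
    violations = run_qc(classes + [extra, twin], (), [anatomy, quality])
    dup_label = [v for v in violations if v.rule == "duplicate_label"]
    assert len(dup_label) == k
    assert {tuple(sorted(v.ids)) for v in dup_label} == {
        (classes[0].id, classes[1].id),
        (extra.id, twin.id),
    }


def test_duplicate_logical_definitions_detected(patterns, anatomy, quality):
    a, b = _abnormal_classes(patterns, anatomy, [EYE, EYE])
    b.label = "a different label"
    violations = run_qc([a, b], (), [anatomy, quality])
    dup = [v for v in violations if v.rule == "duplicate_logical_definition"]
    assert len(dup) == 1
    assert dup[0].ids == tuple(sorted((a.id, b.id)))


def test_obsolete_class_with_logic_flagged(patterns, anatomy, quality):
    (cls,) = _abnormal_classes(patterns, anatomy, [EYE])
    cls.obsolete = True  # but logical_definition was not cleared
    violations = run_qc([cls], (), [anatomy, quality])
    assert [v.rule for v in violations] == ["obsolete_with_logic"]


def test_missing_definition_is_a_warning(patterns, anatomy, quality):
    (cls,) = _abnormal_classes(patterns, anatomy, [EYE])
    cls.definition = None
    violations = run_qc([cls], (), [anatomy, quality])
    assert [(v.rule, v.severity) for v in violations] == [("missing_definition", "warning")]
    assert not has_errors(violations)


def _graph(term_ids, obsolete=()):
    g = OntologyGraph()
    for tid in term_ids:
        g.add_term(Term(id=tid, label=f"class {tid}", obsolete=tid in obsolete))
    return g


def test_diff_added_terms():
    old = _graph(["TOYP:0000002"])
    new = _graph(["TOYP:0000002", "TOYP:0000003", "TOYP:0000004", "TOYP:0000005"])
    diff = diff_releases(old, new)
    assert len(diff.added) == 3
    assert not diff.removed
    assert diff.ok


def test_diff_obsoleted_term_is_not_removed():
    old = _graph(["TOYP:0000002", "TOYP:0000003"])
    new = _graph(["TOYP:0000002", "TOYP:0000003"], obsolete={"TOYP:0000003"})
    diff = diff_releases(old, new)
    assert diff.newly_obsoleted == {"TOYP:0000003"}
    assert not diff.removed
    assert diff.ok


def test_diff_outright_deletion_fails():
    old = _graph(["TOYP:0000002", "TOYP:0000003"])
    new = _graph(["TOYP:0000002"])
    diff = diff_releases(old, new)
    assert diff.removed == {"TOYP:0000003"}
    assert not diff.ok


# --- end-to-end builds ------------------------------------------------------


def _no_exclusion_config(build_config):
    config = copy.deepcopy(build_config)
    sel = build_config.selection
    config.selection = SelectionConfig(
        inclusion_roots=sel.inclusion_roots,
        traversal_relations=sel.traversal_relations,
        auto_patterns=sel.auto_patterns,
    )
    return config


def test_build_count_law(anatomy, quality, patterns, build_config):
    config = _no_exclusion_config(build_config)
    result = build_release(config, anatomy, quality, patterns, {}, _registry())
    e = len(anatomy.terms)
    assert len(result.classes) == 14 * e
    assert len(result.release_graph.terms) == 14 * e + 1  # plus the root
    assert result.exit_code == 0


def test_applicability_filter_reduces_count_by_branch_size(anatomy, quality, patterns, build_config):
    base = _no_exclusion_config(build_config)
    baseline = build_release(base, anatomy, quality, patterns, {}, _registry())
    filtered_config = copy.deepcopy(base)
    filtered_config.selection = SelectionConfig(
        inclusion_roots=base.selection.inclusion_roots,
        auto_patterns=base.selection.auto_patterns,
        applicability_filters=((ABNORMAL, SPACE),),
    )
    filtered = build_release(filtered_config, anatomy, quality, patterns, {}, _registry())
    b = len(descendants(anatomy, SPACE, ("is_a", "part_of")))
    assert b > 0
    assert len(baseline.classes) - len(filtered.classes) == b


def test_rebuild_is_byte_identical(anatomy, quality, patterns, build_config):
    def run():
        return build_release(build_config, anatomy, quality, patterns, {}, _registry())

    first, second = run(), run()
    assert first.obo == second.obo
    assert first.json == second.json


def test_json_carries_logical_definitions(anatomy, quality, patterns, build_config):
    result = build_release(build_config, anatomy, quality, patterns, {}, _registry())
    doc = json.loads(result.json)
    nodes = {n["id"]: n for n in doc["graphs"][0]["nodes"]}
    with_defs = [n for n in nodes.values() if "logical_definition" in n]
    assert len(with_defs) == len(result.classes)
    # relation names are CURIE-mapped at serialization time
    assert "TOYR:0000001 some" in with_defs[0]["logical_definition"]
    assert all(e["predicate"] == "is_a" for e in doc["graphs"][0]["edges"])


def test_obsoletion_workflow_keeps_terms(anatomy, quality, patterns, build_config):
    registry = _registry()
    first = build_release(build_config, anatomy, quality, patterns, {}, registry)
    target = first.classes[0].id
    replacement = first.classes[1].id
    obsoletions = ObsoletionTable([(target, replacement, "retired in test")])
    second = build_release(
        build_config, anatomy, quality, patterns, first.tables, registry,
        obsoletions=obsoletions, previous=first.release_graph,
    )
    assert second.diff is not None
    assert target in second.diff.newly_obsoleted
    assert not second.diff.removed
    assert second.exit_code == 0
    stanza = [s for s in second.obo.split("\n\n") if f"id: {target}" in s][0]
    assert "is_obsolete: true" in stanza
    assert f"replaced_by: {replacement}" in stanza


def test_silent_row_deletion_fails_diff(anatomy, quality, patterns, build_config):
    registry = _registry()
    first = build_release(build_config, anatomy, quality, patterns, {}, registry)
    # drop one synced row without obsoleting it, and stop sync re-adding it
    broken_config = copy.deepcopy(build_config)
    sel = build_config.selection
    tables = {pid: copy.deepcopy(t) for pid, t in first.tables.items()}
    victim_table = tables[ABNORMAL]
    victim_entity = victim_table.rows[0]["anatomical_entity"]
    del victim_table.rows[0]
    broken_config.selection = SelectionConfig(
        inclusion_roots=sel.inclusion_roots,
        traversal_relations=sel.traversal_relations,
        auto_patterns=sel.auto_patterns,
        applicability_filters=sel.applicability_filters,
        excluded_terms=(victim_entity,),
    )
    second = build_release(
        broken_config, anatomy, quality, patterns, tables, registry,
        previous=first.release_graph,
    )
    assert second.diff is not None and not second.diff.ok
    assert second.exit_code == 2


def test_qc_error_sets_exit_code(anatomy, quality, patterns, build_config):
    result = build_release(build_config, anatomy, quality, patterns, {}, _registry())
    result.classes[0].label = result.classes[1].label
    violations = run_qc(result.classes, result.subsumption.edges, [anatomy, quality])
    assert has_errors(violations)


# --- CLI --------------------------------------------------------------------


@pytest.fixture
def workspace(tmp_path):
    spec = FixtureSpec(seed=5, n_entities=15)
    anatomy = make_toy_anatomy(spec)
    quality = make_quality_ontology(spec)
    suite, config_yaml = make_pattern_suite()
    (tmp_path / "anatomy.obo").write_text(write_obo(anatomy))
    (tmp_path / "quality.obo").write_text(write_obo(quality))
    patterns_dir = tmp_path / "patterns"
    patterns_dir.mkdir()
    for pid, text in suite.items():
        (patterns_dir / f"{pid}.yaml").write_text(text)
    tables_dir = tmp_path / "tables"
    tables_dir.mkdir()
    (tmp_path / "config.yaml").write_text(config_yaml)
    return tmp_path


def _build_args(ws, extra=()):
    return [
        "build",
        "--anatomy", str(ws / "anatomy.obo"),
        "--quality", str(ws / "quality.obo"),
        "--patterns", str(ws / "patterns"),
        "--tables", str(ws / "tables"),
        "--config", str(ws / "config.yaml"),
        "--registry", str(ws / "registry.tsv"),
        "--out-obo", str(ws / "release.obo"),
        "--out-json", str(ws / "release.json"),
        "--qc-report", str(ws / "qc.tsv"),
        "--prefix", "TOYP",
        *extra,
    ]


def test_cli_build_round_trips(workspace):
    runner = CliRunner()
    result = runner.invoke(cli_main, _build_args(workspace))
    assert result.exit_code == 0, result.output
    release = parse_obo((workspace / "release.obo").read_text())
    assert len(release.terms) > 1
    assert (workspace / "registry.tsv").exists()
    # tables were written back with minted ids
    table_text = (workspace / "tables" / f"{ABNORMAL}.tsv").read_text()
    assert "TOYP:" in table_text


def test_cli_diff_detects_deletion(workspace, tmp_path):
    runner = CliRunner()
    assert runner.invoke(cli_main, _build_args(workspace)).exit_code == 0
    release = parse_obo((workspace / "release.obo").read_text())
    victim = sorted(release.terms)[1]
    del release.terms[victim]
    release.relationships = [
        r for r in release.relationships if victim not in (r.subject, r.object)
    ]
    (tmp_path / "new.obo").write_text(write_obo(release))
    result = runner.invoke(
        cli_main,
        ["diff", "--old", str(workspace / "release.obo"), "--new", str(tmp_path / "new.obo")],
    )
    assert result.exit_code == 2
    assert victim in result.output


def test_cli_missing_input_is_input_error(workspace):
    runner = CliRunner()
    args = _build_args(workspace)
    args[args.index("--config") + 1] = str(workspace / "nope.yaml")
    result = runner.invoke(cli_main, args)
    assert result.exit_code == 2  # click's own usage error for a missing path
    bad_yaml = workspace / "config.yaml"
    bad_yaml.write_text("patterns: {ghost_pattern: {roots: [TOYA:0000001]}}\nauto_patterns: [ghost_pattern]\n")
    result = runner.invoke(cli_main, _build_args(workspace))
    assert result.exit_code == 3
    assert "input error" in result.output
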