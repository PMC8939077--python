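import pytest

from phenoforge import (
    BuildConfig,
    EntailmentEngine,
    FixtureSpec,
    IdRegistry,
    make_pattern_suite,
    make_quality_ontology,
    make_toy_anatomy,
    parse_pattern,
)


@pytest.fixture(scope="session")
def fixture_spec():
    return FixtureSpec(seed=1, n_entities=30)


@pytest.fixture(scope="session")
def anatomy(fixture_spec):
    return make_toy_anatomy(fixture_spec)


@pytest.fixture(scope="session")
def quality(fixture_spec):
    return make_quality_ontology(fixture_spec)


@pytest.fixture(scope="session")
def suite_yaml():
    return make_pattern_suite()


@pytest.fixture(scope="session")
def patterns(suite_yaml):
    suite, _ = suite_yaml
    return {pid: parse_pattern(text) for pid, text in suite.items()}


@pytest.fixture(scope="session")
def build_config(suite_yaml):
    _, config_yaml = suite_yaml
    return BuildConfig.from_yaml(config_yaml)


@pytest.fixture(scope="session")
def engine(anatomy, quality, patterns):
    return EntailmentEngine(anatomy, quality, patterns)


@pytest.fixture
def registry():
    return IdRegistry(prefix="TOYP", width=7, next_id=2)


THREE_STANZA_OBO = """\
format-version: 1.4
ontology: toy

[Term]
id: TOYA:0000001
name: organ
def: "A discrete anatomical unit." [FIX:0000001]

[Term]
id: TOYA:0000002
name: visual system
synonym: "seeing apparatus" RELATED []

[Term]
id: TOYA:0000003
name: eye
is_a: TOYA:0000001
relationship: part_of TOYA:0000002
"""


@pytest.fixture
def three_stanza_text():
    return THREE_STANZA_OBO
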