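"""Shared fixtures: toy ontologies and annotation tables generated in
memory, plus a parsed end-to-end build of the default synthetic set."""

import pytest

from slcontology.ontology import parse_obo
from slcontology.pipeline import build_reduced_ontology
from slcontology.synthetic import (
    FixtureSpec,
    make_annotation_fixture,
    make_toy_obo,
)


def parse_obo_text(text: str, tmp_path, name: str = "toy.obo"):
    path = tmp_path / name
    path.write_text(text)
    return parse_obo(path)


@pytest.fixture(scope="session")
def default_spec():
    return FixtureSpec(seed=11)


@pytest.fixture(scope="session")
def toy_build(default_spec, tmp_path_factory):
    """Parsed toy ontology, its truth record, the synthetic annotation,
    and the complete reduction pipeline output."""
    tmp = tmp_path_factory.mktemp("toy")
    obo_text, truth = make_toy_obo(default_spec)
    (tmp / "toy.obo").write_text(obo_text)
    raw = parse_obo(tmp / "toy.obo")
    table, ann_truth = make_annotation_fixture(default_spec, truth)
    result = build_reduced_ontology(raw, table)
    return {
        "spec": default_spec,
        "truth": truth,
        "raw": raw,
        "table": table,
        "ann_truth": ann_truth,
        "result": result,
    }


MINI_OBO = """format-version: 1.2

[Term]
id: T:0001
name: thing

[Term]
id: T:0002
name: amino acid
is_a: T:0001

[Term]
id: T:0003
name: glycine
is_a: T:0002
synonym: "aminoacetic acid" EXACT []
synonym: "gly" RELATED []

[Term]
id: T:0004
name: nutrient role

[Term]
id: T:0005
name: serine
is_a: T:0002
relationship: has_role T:0004
relationship: has_part T:0001

[Term]
id: T:0006
name: retired compound
is_obsolete: true
"""


@pytest.fixture
def mini_graph(tmp_path):
    return parse_obo_text(MINI_OBO, tmp_path, "mini.obo")
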