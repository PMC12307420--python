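"""Tests for the model-description dialect, validation, and graph comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pupilsim.dynamics import GainAdaptation
from pupilsim.modelspec import (
    ConnectionDecl,
    ModelSpec,
    ModelSpecError,
    compare_to_reference,
    parse_model_spec,
    read_edge_list,
    serialize_model_spec,
    validate_spec,
)
from pupilsim.network import build_network
from pupilsim.pupil import load_pupil_spec

TWO_NODE_DOC = """
components:
  A: {external: [light]}
  B: {}
connections:
  - {source: A, target: B, kind: excitatory}
"""


def test_parse_minimal_document_applies_defaults():
    spec = parse_model_spec(TWO_NODE_DOC)
    assert set(spec.components()) == {"A", "B"}
    (conn,) = spec.connections
    assert conn.weight == 1.0 and conn.delay_ticks == 1 and not conn.plastic


def test_empty_document_is_an_empty_spec():
    spec = parse_model_spec("")
    assert spec.components() == {} and spec.connections == []


def test_nested_groups_flatten_to_dotted_paths():
    spec = parse_model_spec(
        """
groups:
  brainstem:
    components:
      EWpg: {}
"""
    )
    assert list(spec.components()) == ["brainstem.EWpg"]


def test_syntax_errors_carry_line_diagnostics():
    with pytest.raises(ModelSpecError, match="line"):
        parse_model_spec("components:\n  A: {kind: nucleus\n")
    with pytest.raises(ModelSpecError, match="unknown"):
        parse_model_spec("components:\n  A: {flavor: salty}\n")


# ---------------------------------------------------------------------------
# round-tripping
# ---------------------------------------------------------------------------

def test_pupil_fixture_round_trips():
    spec = load_pupil_spec()
    assert parse_model_spec(serialize_model_spec(spec)) == spec


_names = st.sampled_from(["A", "B", "C", "R", "PTA", "EWpg", "nucleus_1"])


@st.composite
def random_specs(draw):
    n = draw(st.integers(1, 5))
    names = draw(
        st.lists(_names, min_size=n, max_size=n, unique=True)
    )
    grouped = draw(st.booleans())
    doc: dict = {"components": {}, "connections": []}
    paths = []
    for i, name in enumerate(names):
        if grouped and i % 2 == 0:
            doc.setdefault("groups", {}).setdefault("deep", {}).setdefault(
                "components", {}
            )[name] = {}
            paths.append(f"deep.{name}")
        else:
            doc["components"][name] = {
                "params": {"alpha": {"value": draw(st.floats(0, 0.5)), "class": "scaling"}}
            }
            paths.append(name)
    n_conn = draw(st.integers(0, 6))
    for _ in range(n_conn):
        doc["connections"].append(
            {
                "source": draw(st.sampled_from(paths)),
                "target": draw(st.sampled_from(paths)),
                "kind": draw(st.sampled_from(["excitatory", "inhibitory", "shunting"])),
                "delay": draw(st.integers(1, 4)),
            }
        )
    return ModelSpec.from_dict(doc)


@given(spec=random_specs())
@settings(derandomize=True, max_examples=40, deadline=None)
def test_random_specs_round_trip_and_flatten_bijectively(spec):
    assert parse_model_spec(serialize_model_spec(spec)) == spec
    paths = list(spec.components())
    assert len(paths) == len(set(paths))


@given(spec=random_specs())
@settings(derandomize=True, max_examples=10, deadline=None)
def test_validated_specs_build_and_run_finitely(spec):
    """Anything that validates must run >= 1000 ticks producing finite signals."""
    assert validate_spec(spec) == []
    net = build_network(spec, dt=0.01)
    for _ in range(1000):
        net.tick({"light": 1.0})
    for path in net.components:
        assert np.isfinite(net.output(path))


# ---------------------------------------------------------------------------
# validation diagnostics
# ---------------------------------------------------------------------------

def test_dangling_endpoint_is_reported():
    spec = parse_model_spec(TWO_NODE_DOC)
    spec.connections.append(ConnectionDecl(source="A", target="PTA2"))
    (diag,) = validate_spec(spec)
    assert diag.code == "dangling-endpoint" and "PTA2" in diag.message


def test_sub_tick_delay_is_reported():
    spec = parse_model_spec(TWO_NODE_DOC)
    spec.connections[0].delay_ticks = 0
    assert [d.code for d in validate_spec(spec)] == ["bad-delay"]


def test_non_plastic_weight_must_be_one():
    spec = parse_model_spec(TWO_NODE_DOC)
    spec.connections[0].weight = 0.5
    assert [d.code for d in validate_spec(spec)] == ["nonplastic-weight"]


def test_pupil_fixture_validates_cleanly():
    assert validate_spec(load_pupil_spec()) == []


# ---------------------------------------------------------------------------
# building and scheduling
# ---------------------------------------------------------------------------

def test_downstream_nucleus_lags_its_source_by_one_tick():
    net = build_network(parse_model_spec(TWO_NODE_DOC), dt=0.01)
    net.tick({"light": 1.0})
    assert net.output("A") > 0 and net.output("B") == 0
    net.tick({"light": 1.0})
    assert net.output("B") > 0


def test_self_loop_with_unit_delay_is_recurrent():
    doc = """
components:
  A: {external: [light]}
connections:
  - {source: A, target: A, kind: excitatory}
"""
    net = build_network(parse_model_spec(doc), dt=0.01)
    for _ in range(300):
        net.tick({"light": 1.0})
    assert 0 < net.output("A") < 2


def test_duplicate_connections_are_averaged_by_default_beta():
    """Two identical edges with beta = 1/N give the same equilibrium as one."""
    single = parse_model_spec(TWO_NODE_DOC)
    double = parse_model_spec(TWO_NODE_DOC)
    double.connections.append(ConnectionDecl(source="A", target="B"))
    gain = GainAdaptation(enabled=False)
    outs = []
    for spec in (single, double):
        net = build_network(spec, dt=0.01, gain=gain)
        for _ in range(3000):
            net.tick({"light": 1.0})
        outs.append(net.output("B"))
    assert outs[0] == pytest.approx(outs[1], abs=1e-12)


# ---------------------------------------------------------------------------
# structural comparison
# ---------------------------------------------------------------------------

def _chain_spec(*edges):
    names = sorted({n for e in edges for n in e})
    doc = {"components": {n: {} for n in names},
           "connections": [{"source": s, "target": t} for s, t in edges]}
    return ModelSpec.from_dict(doc)


def test_identical_graphs_have_unit_jaccard():
    spec = _chain_spec(("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("e", "a"))
    cmp = compare_to_reference(spec, [(s, t) for s, t in spec.edge_labels()])
    assert cmp.edge_jaccard == 1.0 and cmp.identical
    assert cmp.degree_agreement == 1.0


def test_partial_overlap_jaccard_is_set_arithmetic():
    spec = _chain_spec(("a", "b"), ("b", "c"))
    cmp = compare_to_reference(spec, [("a", "b"), ("c", "d")])
    assert cmp.edge_jaccard == pytest.approx(1 / 3)
    assert cmp.missing_edges == [("c", "d")]
    assert cmp.extra_edges == [("b", "c")]


def test_empty_model_has_zero_jaccard_against_anything():
    cmp = compare_to_reference(ModelSpec(), [("a", "b")])
    assert cmp.edge_jaccard == 0.0


def test_jaccard_is_symmetric_in_model_and_reference():
    spec1 = _chain_spec(("a", "b"), ("b", "c"), ("x", "y"))
    spec2 = _chain_spec(("a", "b"), ("c", "d"))
    j12 = compare_to_reference(spec1, spec2.edge_labels()).edge_jaccard
    j21 = compare_to_reference(spec2, spec1.edge_labels()).edge_jaccard
    assert j12 == j21


def test_unmapped_model_nodes_are_reported_not_dropped():
    spec = _chain_spec(("a", "b"), ("q", "r"))
    cmp = compare_to_reference(spec, [("a", "b")])
    assert set(cmp.unmapped_nodes) == {"q", "r"}


def test_pupil_model_matches_its_shipped_reference_exactly():
    from importlib import resources

    ref = read_edge_list(
        resources.files("pupilsim.data") / "pupil_edges_reference.tsv"
    )
    cmp = compare_to_reference(load_pupil_spec(), ref)
    assert cmp.edge_jaccard == 1.0
    assert cmp.missing_edges == [] and cmp.extra_edges == []
    assert cmp.degree_agreement == 1.0
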