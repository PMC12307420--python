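"""Tests for the pupil network: anatomy, functional components, and the plant."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pupilsim.protocols import make_conditioning_protocol
from pupilsim.pupil import (
    AMYGDALA_PATH,
    AmygdalaState,
    CerebellumState,
    PupilPlant,
    amygdala_step,
    build_pupil_network,
    cerebellum_step,
    cortex_step,
    pupil_plant_step,
)
from pupilsim.experiments import run_simulation


# ---------------------------------------------------------------------------
# anatomy
# ---------------------------------------------------------------------------

def test_network_has_fifteen_nuclei_and_three_functional_units(base_network):
    assert base_network.component_count() == 18
    kinds = [c.decl.kind for c in base_network.components.values()]
    assert kinds.count("nucleus") == 15
    assert kinds.count("functional") == 3
    assert kinds.count("actuator") == 1  # the iris plant is not a model component


def test_all_non_plastic_weights_are_exactly_one(base_network):
    non_plastic = [c for c in base_network.connections if not c.decl.plastic]
    plastic = [c for c in base_network.connections if c.decl.plastic]
    assert all(c.decl.weight == 1.0 for c in non_plastic)
    # learning is confined to the cerebellar and amygdalar afferents
    assert {(c.source_path, c.target_path) for c in plastic} == {
        ("cortex.Cortex", "cerebellum.CB"),
        ("thalamus.PULV", "amygdala.AMY"),
    }


def test_constriction_chain_is_one_hop_shorter_than_dilation_chain(base_network):
    para = base_network.shortest_hops("eye.R", "plant.sphincter")
    symp = base_network.shortest_hops("amygdala.AMY", "plant.dilator")
    assert para == 4
    assert symp == 5
    # any light-driven route to the dilator is longer still
    assert base_network.shortest_hops("eye.R", "plant.dilator") >= 5


def test_robot_variant_builds_with_tapped_cerebellar_line():
    net = build_pupil_network(cb_taps=(2, 4, 6, 8, 10))
    (cb_conn,) = [
        c for c in net.connections if c.target_path == "cerebellum.CB"
    ]
    assert cb_conn.decl.taps == (2, 4, 6, 8, 10)
    for _ in range(20):
        net.tick({"identity": 3})
    assert np.isfinite(net.output("cerebellum.CB"))


def test_non_plastic_weights_survive_conditioning_run(pupil_network):
    proto = make_conditioning_protocol(3, cs_id=0, isi_s=0.04, dt=pupil_network.dt)
    run_simulation(pupil_network, proto, learning=True)
    pupil_network.check_non_plastic_weights()
    cb = pupil_network.components["cerebellum.CB"]
    assert cb.state.weights.max() > 0  # plastic path did learn


# ---------------------------------------------------------------------------
# pupil plant
# ---------------------------------------------------------------------------

def test_plant_rest_and_constriction_clipping():
    plant = PupilPlant()
    assert pupil_plant_step(0.0, 0.0, plant) == 4.0
    # g_s * 1 = 3 mm of constriction requests 1.0 mm; clipped at d_min
    assert pupil_plant_step(1.0, 0.0, plant) == 2.0


@given(
    s=st.floats(0, 3, allow_nan=False),
    d=st.floats(0, 3, allow_nan=False),
    extra=st.floats(0, 1, allow_nan=False),
)
@settings(derandomize=True, max_examples=50, deadline=None)
def test_plant_is_monotone_and_bounded(s, d, extra):
    plant = PupilPlant()
    base = pupil_plant_step(s, d, plant)
    assert plant.d_min <= base <= plant.d_max
    assert pupil_plant_step(s + extra, d, plant) <= base
    assert pupil_plant_step(s, d + extra, plant) >= base


# ---------------------------------------------------------------------------
# cortex: identity and surprise
# ---------------------------------------------------------------------------

def test_first_exposure_is_maximally_surprising():
    out, fam = cortex_step(3, np.zeros(8))
    assert out.surprise == 1.0
    assert out.identity.argmax() == 3 and out.identity.sum() == 1.0
    assert fam[3] == 1


def test_surprise_decays_geometrically_with_familiarity():
    fam = np.zeros(8)
    for _ in range(19):
        _, fam = cortex_step(5, fam, decay=0.6)
    out, _ = cortex_step(5, fam, decay=0.6)
    assert out.surprise == pytest.approx(0.6**19)
    assert out.surprise < 1e-4  # effectively habituated


def test_blank_frame_is_neither_identified_nor_surprising():
    out, fam = cortex_step(-1, np.zeros(4))
    assert out.identity.sum() == 0 and out.surprise == 0.0
    assert fam.sum() == 0


def test_identity_outside_capacity_is_rejected():
    with pytest.raises(ValueError):
        cortex_step(9, np.zeros(4))


# ---------------------------------------------------------------------------
# cerebellum: delta-rule conditioning
# ---------------------------------------------------------------------------

def test_untrained_cerebellum_predicts_nothing():
    state = CerebellumState.zeros(4, taps=(2, 4))
    traces = np.zeros((2, 4))
    traces[0, 1] = 1.0
    pred, _ = cerebellum_step(traces, us=1.0, state=state, learning=False)
    assert pred == 0.0


def test_single_pairing_moves_weight_by_learning_rate():
    state = CerebellumState.zeros(4, taps=(2,), eta=0.1)
    traces = np.zeros((1, 4))
    traces[0, 2] = 1.0
    _, state = cerebellum_step(traces, us=1.0, state=state)
    assert state.weights[0, 2] == pytest.approx(0.1)
    assert state.weights.sum() == pytest.approx(0.1)  # credit stays on the active tap


def test_repeated_pairings_follow_delta_rule_closed_form():
    # oracle: w_n = 1 - (1 - eta)^n for unit trace and unit teaching signal
    state = CerebellumState.zeros(2, taps=(2,), eta=0.1)
    traces = np.zeros((1, 2))
    traces[0, 0] = 1.0
    preds = []
    for _ in range(10):
        pred, state = cerebellum_step(traces, us=1.0, state=state)
        preds.append(pred)
    assert state.weights[0, 0] == pytest.approx(1 - 0.9**10, abs=1e-12)
    assert preds == sorted(preds)  # prediction error shrinks monotonically


def test_weights_never_go_negative():
    state = CerebellumState.zeros(1, taps=(1,), eta=0.5)
    trace = np.ones((1, 1))
    _, state = cerebellum_step(trace, us=1.0, state=state)
    for _ in range(20):  # extinction
        _, state = cerebellum_step(trace, us=0.0, state=state)
    assert state.weights.min() >= 0.0


# ---------------------------------------------------------------------------
# amygdala: polarity-independent arousal
# ---------------------------------------------------------------------------

def _one_hot(i, n=8):
    v = np.zeros(n)
    v[i] = 1.0
    return v


def test_neutral_unfamiliar_state_is_unaroused():
    arousal, _ = amygdala_step(_one_hot(0), 0.0, 0.0, AmygdalaState.zeros(8))
    assert arousal == 0.0


def test_novelty_alone_arouses_fully():
    arousal, _ = amygdala_step(_one_hot(0), 1.0, 0.0, AmygdalaState.zeros(8))
    assert arousal == 1.0


def test_opposite_valences_arouse_equally_after_equal_training():
    state = AmygdalaState.zeros(8)
    for _ in range(6):
        _, state = amygdala_step(_one_hot(2), 0.0, +1.0, state)
        _, state = amygdala_step(_one_hot(5), 0.0, -1.0, state)
    a_pos, _ = amygdala_step(_one_hot(2), 0.0, 0.0, state, learning=False)
    a_neg, _ = amygdala_step(_one_hot(5), 0.0, 0.0, state, learning=False)
    assert a_pos == pytest.approx(a_neg, rel=1e-12)
    assert a_pos > 0


@given(valences=st.lists(st.floats(-1, 1, allow_nan=False), min_size=1, max_size=20))
@settings(derandomize=True, max_examples=30, deadline=None)
def test_arousal_is_invariant_under_global_valence_sign_flip(valences):
    states = [AmygdalaState.zeros(4), AmygdalaState.zeros(4)]
    for v in valences:
        for j, sign in enumerate((1.0, -1.0)):
            arousal, states[j] = amygdala_step(_one_hot(1, 4), 0.3, sign * v, states[j])
        a0, _ = amygdala_step(_one_hot(1, 4), 0.0, 0.0, states[0], learning=False)
        a1, _ = amygdala_step(_one_hot(1, 4), 0.0, 0.0, states[1], learning=False)
        assert a0 == pytest.approx(a1, rel=1e-12)


def test_out_of_range_valence_is_rejected():
    with pytest.raises(ValueError):
        amygdala_step(_one_hot(0), 0.0, 1.5, AmygdalaState.zeros(8))


def test_zero_learning_rate_ablates_emotional_conditioning():
    state = AmygdalaState.zeros(8, eta=0.0)
    for _ in range(10):
        _, state = amygdala_step(_one_hot(1), 0.0, -1.0, state)
    assert state.negative.sum() == 0.0


def test_emotional_arousal_reaches_the_amygdala_output(pupil_network):
    """A novel stimulus must raise amygdala arousal inside the running network."""
    for _ in range(5):
        pupil_network.tick({"identity": 2})
    assert pupil_network.output(AMYGDALA_PATH) >= 1.0
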