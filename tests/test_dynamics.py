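"""Unit and property tests for the single-nucleus dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pupilsim.dynamics import (
    OUTPUT_BOUND,
    PHI,
    DelayBuffer,
    NucleusParams,
    NucleusState,
    adapt_gain,
    compute_drive,
    euler_step,
    nucleus_output,
    update_input_average,
)

finite = st.floats(-10, 10, allow_nan=False, allow_infinity=False)


# ---------------------------------------------------------------------------
# drive term
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "params, excit, inhib, shunt, expected",
    [
        # one unit input, unit scaling: drive equals the input
        (NucleusParams(alpha=0.0, beta=1.0), [(1, 1, 1)], [], 0.0, 1.0),
        # no inputs: the resting level alone
        (NucleusParams(alpha=0.2), [], [], 0.0, 0.2),
        # divisive inhibition scales excitation by 1/(1+S)
        (NucleusParams(alpha=0.0, beta=1.0), [(1, 1, 1)], [], 9.0, 0.1),
        # averaging beta with subtractive inhibition cancels exactly
        (NucleusParams(alpha=0.0, beta=0.5, gamma=1.0), [(1, 1, 1), (1, 1, 1)], [1.0], 0.0, 0.0),
    ],
)
def test_drive_term_closed_form(params, excit, inhib, shunt, expected):
    assert compute_drive(params, excit, inhib, shunt) == pytest.approx(expected, abs=1e-12)


def test_drive_averaging_defaults_resolve_per_input_count():
    params = NucleusParams()  # beta, gamma default to 1/N, 1/M
    excit = [(1.0, 1.0, 1.0)] * 4
    assert compute_drive(params, excit) == pytest.approx(1.0)
    # empty input classes contribute a zero term instead of dividing by zero
    assert compute_drive(params, [], []) == 0.0


def test_drive_rejects_corrupted_signals():
    params = NucleusParams()
    with pytest.raises(ValueError):
        compute_drive(params, [(math.nan, 1.0, 1.0)])
    with pytest.raises(ValueError):
        compute_drive(params, [(1.0, 1.0, 1.0)], shunt=-0.5)
    with pytest.raises(ValueError):
        compute_drive(params, [], [math.inf])


@given(
    s1=st.floats(0, 50, allow_nan=False),
    s2=st.floats(0, 50, allow_nan=False),
    e=st.floats(0, 1, allow_nan=False),
)
@settings(derandomize=True, max_examples=50, deadline=None)
def test_drive_non_increasing_in_shunting(s1, s2, e):
    lo, hi = sorted((s1, s2))
    params = NucleusParams(beta=1.0)
    assert compute_drive(params, [(e, 1, 1)], shunt=hi) <= compute_drive(
        params, [(e, 1, 1)], shunt=lo
    ) + 1e-12


@given(n=st.integers(1, 10))
@settings(derandomize=True, max_examples=10, deadline=None)
def test_input_averaging_keeps_unit_drive_bound(n):
    """With beta = 1/N the aggregated excitatory term never exceeds 1."""
    params = NucleusParams()
    drive = compute_drive(params, [(1.0, 1.0, 1.0)] * n)
    assert drive <= 1.0 + 1e-12


# ---------------------------------------------------------------------------
# output nonlinearity
# ---------------------------------------------------------------------------

def test_unit_activation_gives_unit_output():
    assert nucleus_output(1.0) == pytest.approx(1.0, abs=1e-15)
    assert nucleus_output(0.0) == 0.0
    assert nucleus_output(-1.0) == pytest.approx(-1.0, abs=1e-15)
    assert PHI == pytest.approx(4 / math.pi)


@given(x=st.floats(-1e9, 1e9, allow_nan=False), y=st.floats(-1e9, 1e9, allow_nan=False))
@settings(derandomize=True, max_examples=100, deadline=None)
def test_output_is_odd_monotone_and_bounded(x, y):
    ox, oy = nucleus_output(x), nucleus_output(y)
    assert abs(ox) < OUTPUT_BOUND
    assert nucleus_output(-x) == pytest.approx(-ox, abs=1e-12)
    if x < y:
        assert ox < oy


# ---------------------------------------------------------------------------
# Euler integration
# ---------------------------------------------------------------------------

def _run_euler(x0, drive, dt, epsilon, steps):
    params = NucleusParams(epsilon=epsilon)
    state = NucleusState(x=x0, o=nucleus_output(x0))
    for _ in range(steps):
        state = euler_step(state, drive, dt, params)
    return state


def test_single_euler_steps():
    assert _run_euler(0.0, 1.0, 0.1, 0.1, 1).x == pytest.approx(1.0)
    assert _run_euler(0.0, 1.0, 0.01, 0.1, 1).x == pytest.approx(0.1)


def test_euler_matches_geometric_closed_form():
    # oracle: x_k = D * (1 - (1 - dt/eps)^k) for x0 = 0
    state = _run_euler(0.0, 1.0, 0.01, 0.1, 10)
    assert state.x == pytest.approx(1 - 0.9**10, abs=1e-12)
    assert state.o == pytest.approx(nucleus_output(1 - 0.9**10), abs=1e-12)


@given(
    x0=finite,
    drive=finite,
    k=st.integers(1, 200),
    ratio=st.floats(0.05, 1.0),
)
@settings(derandomize=True, max_examples=50, deadline=None)
def test_fixed_point_error_follows_geometric_decay(x0, drive, k, ratio):
    """|x_k - D| = |x0 - D| * (1 - dt/eps)^k, monotone for dt <= eps."""
    epsilon = 0.1
    dt = ratio * epsilon
    state = _run_euler(x0, drive, dt, epsilon, k)
    expected = abs(x0 - drive) * (1 - dt / epsilon) ** k
    assert abs(state.x - drive) == pytest.approx(expected, abs=1e-9 * (1 + abs(x0 - drive)))


def test_oversized_step_is_rejected():
    params = NucleusParams(epsilon=0.1)
    with pytest.raises(ValueError):
        euler_step(NucleusState(), 1.0, 0.2, params)
    with pytest.raises(ValueError):
        euler_step(NucleusState(), 1.0, 0.0, params)


def test_halving_dt_keeps_equilibrium_and_halves_transient_error():
    # equilibrium is dt-independent; transient error scales ~linearly in dt
    eps, drive, t_end = 0.1, 1.0, 0.5
    exact = drive * (1 - math.exp(-t_end / eps))
    errors = []
    for dt in (0.01, 0.005):
        state = _run_euler(0.0, drive, dt, eps, int(round(t_end / dt)))
        errors.append(abs(state.x - exact))
    assert _run_euler(0.0, drive, 0.01, eps, 20000).x == pytest.approx(drive, abs=1e-12)
    assert 0.35 <= errors[1] / errors[0] <= 0.65


# ---------------------------------------------------------------------------
# gain adaptation
# ---------------------------------------------------------------------------

def test_gain_fixed_point_at_setpoint():
    assert adapt_gain(1.0, 1.0, 0.01, tau_u=600.0) == 1.0


def test_gain_rises_monotonically_under_silence():
    u, trail = 1.0, []
    for _ in range(5000):
        u = adapt_gain(u, 0.0, 1.0, tau_u=600.0, bounds=(0.25, 4.0))
        trail.append(u)
    assert all(b >= a for a, b in zip(trail, trail[1:]))
    assert trail[-1] <= 4.0
    assert trail[-1] > trail[0]


def test_infinite_timescale_freezes_gain():
    assert adapt_gain(1.3, 0.0, 0.01, tau_u=math.inf) == 1.3


def test_input_average_is_exponential_tracker():
    avg = 0.0
    for _ in range(100):
        avg = update_input_average(avg, 1.0, 0.01, 2.0)
    assert avg == pytest.approx(1 - (1 - 0.01 / 2.0) ** 100, abs=1e-12)


# ---------------------------------------------------------------------------
# delay buffers
# ---------------------------------------------------------------------------

def test_delay_is_a_pure_shift():
    buf = DelayBuffer(length=3)
    assert [buf.step(v) for v in [1, 0, 0, 0]] == [0, 0, 0, 1]


def test_tapped_buffer_reads_each_offset():
    buf = DelayBuffer(taps=(2, 4))
    outputs = [buf.step(1.0 if t == 0 else 0.0) for t in range(6)]
    assert [o[0] for o in outputs] == [0, 0, 1, 0, 0, 0]  # tap at 2
    assert [o[1] for o in outputs] == [0, 0, 0, 0, 1, 0]  # tap at 4


def test_unit_delay_returns_previous_tick():
    buf = DelayBuffer(length=1)
    assert [buf.step(v) for v in [5, 7, 9]] == [0, 5, 7]


def test_zero_delay_is_a_configuration_error():
    with pytest.raises(ValueError):
        DelayBuffer(length=0)
    with pytest.raises(ValueError):
        DelayBuffer(taps=(0, 2))


@given(
    d1=st.integers(1, 6),
    d2=st.integers(1, 6),
    xs=st.lists(st.integers(-5, 5), min_size=1, max_size=30),
)
@settings(derandomize=True, max_examples=50, deadline=None)
def test_delay_composition_equals_sum_of_delays(d1, d2, xs):
    """Chaining delays of d1 and d2 ticks equals one delay of d1 + d2."""
    a, b = DelayBuffer(length=d1), DelayBuffer(length=d2)
    chained = [b.step(a.step(x)) for x in xs]
    # oracle: brute-force shift by d1 + d2
    shifted = [0] * (d1 + d2) + list(xs)
    assert chained == shifted[: len(xs)]
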