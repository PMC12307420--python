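"""Leaky-integrator nucleus dynamics with shunting inhibition and slow gain adaptation.

A *nucleus* is the elementary dynamical unit of the simulator: a neural-mass
style rate unit standing in for an anatomically identified population (a
brainstem nucleus, a ganglion, a hypothalamic cell group).  Its internal
activation ``x`` follows

    eps * dx/dt = alpha + beta * (1 / (1 + S)) * sum_i E_i w_i u_i
                  - gamma * sum_j I_j - x

where the ``E_i`` are excitatory inputs with synaptic weights ``w_i`` and
slow input gains ``u_i``, the ``I_j`` are subtractive inhibitory inputs, and
``S`` is divisive (shunting) inhibition.  ``alpha`` sets the resting level;
``beta`` and ``gamma`` scale excitation and inhibition and default to input
averages (``1/N`` and ``1/M``), which keeps the aggregated excitatory drive
inside [0, 1] for inputs in [0, 1] however many connections converge on a
unit, so networks stay well-scaled as they grow.

The output nonlinearity is ``o = phi * atan(x)`` with ``phi = 1/atan(1)``:
normalized so a unit activation yields a unit output (no amplification at
this stage) and bounding every output magnitude strictly below
``phi * pi/2 = 2``.

Integration is first-order explicit Euler at a fixed step ``dt``.  Steps
larger than the time constant are rejected outright: explicit Euler with
``dt/eps > 1`` overshoots and can oscillate, and the input-averaging
stability argument presumes stable stepping.

The input gain ``u`` (typically 1) adapts slowly toward the reciprocal of
the running average input, modeling receptor up- and down-regulation: a
synapse that sees persistently weak input is up-regulated, a persistently
saturated one down-regulated.  The adaptation time constant is much longer
than any single behavioral episode, so within one trial ``u`` is
effectively constant.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "PHI",
    "OUTPUT_BOUND",
    "ConnectionKind",
    "GainAdaptation",
    "NucleusParams",
    "NucleusState",
    "DelayBuffer",
    "compute_drive",
    "nucleus_output",
    "euler_step",
    "update_input_average",
    "adapt_gain",
]

#: Output scale 4/pi, fixed so that ``nucleus_output(1.0) == 1.0``.
PHI: float = 1.0 / math.atan(1.0)

#: Strict bound on any nucleus output magnitude: ``PHI * pi/2 == 2`` exactly.
OUTPUT_BOUND: float = 2.0


class ConnectionKind(str, Enum):
    """Computational type of a connection between components."""

    EXCITATORY = "excitatory"
    INHIBITORY = "inhibitory"
    SHUNTING = "shunting"


@dataclass(frozen=True)
class GainAdaptation:
    """Configuration of the slow per-synapse input-gain control.

    Parameters
    ----------
    tau_e:
        Time constant (s) of the exponential moving average of the raw
        synaptic input.
    tau_u:
        Time constant (s) of the gain update itself; chosen well above the
        duration of any behavioral episode (training runs included), so
        receptor regulation is background drift, not trial dynamics.
    setpoint:
        Target for ``u * input_avg``; with the default 1 a synapse whose
        average input is 1 keeps its gain at exactly 1.
    u_min, u_max:
        Hard bounds on the gain; the interval must contain 1.
    enabled:
        Disable to freeze all gains at 1 (useful for ablations).
    """

    tau_e: float = 2.0
    tau_u: float = 600.0
    setpoint: float = 1.0
    u_min: float = 0.25
    u_max: float = 4.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if not (self.u_min <= 1.0 <= self.u_max):
            raise ValueError("gain bounds must contain 1")
        if self.tau_e <= 0 or self.tau_u <= 0:
            raise ValueError("gain time constants must be positive")


@dataclass(frozen=True)
class NucleusParams:
    """Static parameters of a single nucleus.

    ``beta`` / ``gamma`` of ``None`` select the input-averaging defaults
    ``1/N`` and ``1/M`` (resolved against the actual number of inputs at
    evaluation time; an empty input class contributes a zero term).  ``phi``
    is fixed by the unit-gain output convention and is not meant to be
    tuned.
    """

    alpha: float = 0.0
    epsilon: float = 0.1
    beta: float | None = None
    gamma: float | None = None
    phi: float = PHI

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")
        if not math.isclose(self.phi, PHI, rel_tol=0.0, abs_tol=1e-12):
            raise ValueError("phi is fixed to 1/atan(1) by the output convention")


@dataclass
class NucleusState:
    """Dynamic state of a nucleus: activation, output, and per-synapse gains."""

    x: float = 0.0
    o: float = 0.0
    gains: np.ndarray = field(default_factory=lambda: np.zeros(0))
    input_avg: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @classmethod
    def zeros(cls, n_excitatory: int, setpoint: float = 1.0) -> "NucleusState":
        """Fresh state with unit gains and the input average at its setpoint.

        Starting the running average at the adaptation setpoint makes
        ``u = 1`` an exact fixed point from the first tick (the synapse is
        assumed to start at its adapted equilibrium).
        """
        return cls(
            x=0.0,
            o=0.0,
            gains=np.ones(n_excitatory),
            input_avg=np.full(n_excitatory, setpoint, dtype=float),
        )


def compute_drive(
    params: NucleusParams,
    excit: Sequence[tuple[float, float, float]],
    inhib: Sequence[float] = (),
    shunt: float = 0.0,
) -> float:
    """Instantaneous drive term ``alpha + beta/(1+S) * sum(E w u) - gamma * sum(I)``.

    Parameters
    ----------
    excit:
        Sequence of ``(E, w, u)`` triples, one per excitatory synapse.
    inhib:
        Subtractive inhibitory input values (already weight-multiplied).
    shunt:
        Total shunting inhibition ``S >= 0``.

    Pure function; raises ``ValueError`` on non-finite inputs (a corrupted
    signal path) or negative shunting.
    """
    if not math.isfinite(shunt):
        raise ValueError("non-finite shunting input")
    if shunt < 0:
        raise ValueError(f"shunting inhibition must be non-negative, got {shunt}")

    total_exc = 0.0
    for e, w, u in excit:
        if not (math.isfinite(e) and math.isfinite(w) and math.isfinite(u)):
            raise ValueError("non-finite excitatory input")
        total_exc += e * w * u
    total_inh = 0.0
    for i in inhib:
        if not math.isfinite(i):
            raise ValueError("non-finite inhibitory input")
        total_inh += i

    n, m = len(excit), len(inhib)
    beta = params.beta if params.beta is not None else (1.0 / n if n else 0.0)
    gamma = params.gamma if params.gamma is not None else (1.0 / m if m else 0.0)
    return params.alpha + beta * total_exc / (1.0 + shunt) - gamma * total_inh


def nucleus_output(x: float) -> float:
    """Output nonlinearity ``o = phi * atan(x)``: odd, strictly increasing, |o| < 2."""
    if not math.isfinite(x):
        raise ValueError("non-finite activation")
    return PHI * math.atan(x)


def euler_step(
    state: NucleusState, drive: float, dt: float, params: NucleusParams
) -> NucleusState:
    """One explicit Euler step of the activation toward ``drive``.

    ``x' = x + (dt/eps) * (drive - x)``; the output is refreshed so that
    ``o == phi * atan(x)`` holds after every step.  Requires
    ``0 < dt <= eps``.
    """
    if not 0.0 < dt <= params.epsilon:
        raise ValueError(
            f"dt must satisfy 0 < dt <= epsilon (dt={dt}, epsilon={params.epsilon}); "
            "larger steps make explicit Euler unstable"
        )
    x = state.x + (dt / params.epsilon) * (drive - state.x)
    return replace(state, x=x, o=nucleus_output(x))


def update_input_average(avg: float, value: float, dt: float, tau_e: float) -> float:
    """Exponential moving average of a raw synaptic input."""
    return avg + (dt / tau_e) * (value - avg)


def adapt_gain(
    gain: float,
    input_avg: float,
    dt: float,
    tau_u: float,
    setpoint: float = 1.0,
    bounds: tuple[float, float] = (0.25, 4.0),
) -> float:
    """Slow gain update ``u' = clip(u + (dt/tau_u) * (setpoint - u * avg))``.

    Moves opposite to the average input: persistently weak input drives the
    gain up toward ``u_max``, saturated input drives it down.  With
    ``input_avg == setpoint`` and ``u == 1`` the gain is a fixed point.
    """
    u = gain + (dt / tau_u) * (setpoint - gain * input_avg)
    lo, hi = bounds
    return min(max(u, lo), hi)


class DelayBuffer:
    """Exact integer-tick delay line, optionally read at several taps.

    A plain buffer of ``length`` ticks returns, on each :meth:`step`, the
    value written ``length`` ticks earlier and then records the new value.
    A tapped buffer instead returns a tuple with one reading per tap
    offset.  Buffers are initialized with zeros (silent history) and the
    minimum delay is one tick — the synchronous schedule requires every
    component to read only previous-tick outputs.
    """

    def __init__(
        self,
        length: int | None = None,
        taps: Sequence[int] | None = None,
        fill: float = 0.0,
    ) -> None:
        if taps is not None:
            taps = tuple(sorted(int(t) for t in taps))
            if not taps or any(t < 1 for t in taps):
                raise ValueError("tap offsets must be integers >= 1")
            depth = taps[-1]
        else:
            if length is None or int(length) < 1:
                raise ValueError(
                    f"delay length must be an integer >= 1, got {length}"
                )
            length = int(length)
            depth = length
        self.length = length
        self.taps = taps
        self._depth = depth
        self._buf: deque = deque([fill] * depth, maxlen=depth)

    def read(self):
        """Value(s) written ``length`` (or each tap offset) ticks ago."""
        if self.taps is not None:
            return tuple(self._buf[self._depth - t] for t in self.taps)
        return self._buf[0]

    def write(self, value) -> None:
        """Record this tick's value (evicts the oldest entry)."""
        self._buf.append(value)

    def step(self, value):
        """Read the delayed value(s), then record ``value``; returns the reading."""
        out = self.read()
        self.write(value)
        return out

    def reset(self, fill: float = 0.0) -> None:
        self._buf = deque([fill] * self._depth, maxlen=self._depth)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.taps is not None:
            return f"DelayBuffer(taps={self.taps})"
        return f"DelayBuffer(length={self.length})"
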