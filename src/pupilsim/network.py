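"""Runtime networks: instantiation of a model spec and the synchronous tick loop.

Every connection carries at least one tick of delay, so on each tick a
component reads only outputs produced on previous ticks.  This gives a
deterministic synchronous schedule with no update-order ambiguity: the
loop reads every connection's delay buffer, steps every component, then
writes the fresh outputs back into the buffers.

Nuclei are integrated with the leaky-integrator dynamics from
:mod:`pupilsim.dynamics`.  Functional components (cortex, cerebellum,
amygdala, actuators) are algebraic units: their outputs are recomputed
from the delivered inputs each tick by an implementation registered under
the component's ``impl`` key.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Callable, Mapping

import networkx as nx
import numpy as np

from .dynamics import (
    ConnectionKind,
    DelayBuffer,
    GainAdaptation,
    NucleusParams,
    NucleusState,
    adapt_gain,
    compute_drive,
    euler_step,
    update_input_average,
)
from .modelspec import (
    ComponentDecl,
    ConnectionDecl,
    ModelSpec,
    ModelSpecError,
    validate_spec,
)

__all__ = [
    "ComponentRuntime",
    "NucleusRuntime",
    "FunctionalRuntime",
    "ConnectionRuntime",
    "Network",
    "build_network",
]

#: signature of a functional-implementation factory registered per ``impl`` key
Factory = Callable[[str, ComponentDecl], "FunctionalRuntime"]


class ComponentRuntime:
    """Base class for instantiated components."""

    def __init__(self, path: str, decl: ComponentDecl) -> None:
        self.path = path
        self.decl = decl

    def output(self, port: str | None = None):
        raise NotImplementedError

    def step(self, incoming, externals, dt: float, learning: bool) -> None:
        raise NotImplementedError

    def reset(self, full: bool = False) -> None:
        raise NotImplementedError


class NucleusRuntime(ComponentRuntime):
    """A nucleus: leaky integrator with typed inputs and per-synapse gain control.

    Excitatory synapses are ordered (declared connections first, then one
    slot for the summed external stimulus channels, if any); each keeps a
    running input average and a slow gain.  Shunting inputs are summed and
    rectified at zero before entering the divisive factor, since outputs of
    inhibited nuclei can be negative while divisive inhibition cannot.
    """

    def __init__(
        self,
        path: str,
        decl: ComponentDecl,
        params: NucleusParams,
        gain: GainAdaptation,
        n_excitatory: int,
    ) -> None:
        super().__init__(path, decl)
        self.params = params
        self.gain = gain
        self.n_excitatory = n_excitatory
        self.state = NucleusState.zeros(n_excitatory, setpoint=gain.setpoint)

    def output(self, port: str | None = None) -> float:
        if port is not None:
            raise KeyError(f"nucleus {self.path} has no port {port!r}")
        return self.state.o

    def step(self, incoming, externals, dt: float, learning: bool) -> None:
        values = incoming.get(None, ())
        excit: list[tuple[float, float]] = []
        inhib: list[float] = []
        shunt = 0.0
        for value, conn in values:
            v = float(value)
            if conn.decl.kind is ConnectionKind.EXCITATORY:
                excit.append((v, conn.decl.weight))
            elif conn.decl.kind is ConnectionKind.INHIBITORY:
                inhib.append(v * conn.decl.weight)
            else:
                shunt += v * conn.decl.weight
        if self.decl.external:
            ext = sum(float(externals.get(ch, 0.0)) for ch in self.decl.external)
            excit.append((ext, 1.0))
        if len(excit) != self.n_excitatory:  # pragma: no cover - wiring guard
            raise RuntimeError(
                f"{self.path}: expected {self.n_excitatory} excitatory inputs, "
                f"got {len(excit)}"
            )

        st = self.state
        gains, avgs = st.gains, st.input_avg
        if self.gain.enabled:
            for i, (e, _w) in enumerate(excit):
                avgs[i] = update_input_average(avgs[i], e, dt, self.gain.tau_e)
        triples = [(e, w, gains[i]) for i, (e, w) in enumerate(excit)]
        drive = compute_drive(self.params, triples, inhib, max(0.0, shunt))
        self.state = euler_step(st, drive, dt, self.params)
        self.state.gains, self.state.input_avg = gains, avgs
        if self.gain.enabled:
            for i in range(len(excit)):
                gains[i] = adapt_gain(
                    gains[i],
                    avgs[i],
                    dt,
                    self.gain.tau_u,
                    self.gain.setpoint,
                    (self.gain.u_min, self.gain.u_max),
                )

    def reset(self, full: bool = False) -> None:
        self.state = NucleusState.zeros(self.n_excitatory, setpoint=self.gain.setpoint)


class FunctionalRuntime(ComponentRuntime):
    """Base class for algebraic components (cortex, cerebellum, amygdala, plant).

    Subclasses set :attr:`outputs` — a dict keyed by port name (``None``
    for the default output) — inside :meth:`step`.
    """

    def __init__(self, path: str, decl: ComponentDecl) -> None:
        super().__init__(path, decl)
        self.outputs: dict[str | None, object] = {None: 0.0}

    def output(self, port: str | None = None):
        try:
            return self.outputs[port]
        except KeyError:
            raise KeyError(f"{self.path} has no output port {port!r}") from None


class ConnectionRuntime:
    """An instantiated connection: endpoints plus its delay buffer."""

    def __init__(
        self,
        decl: ConnectionDecl,
        source_path: str,
        source_port: str | None,
        target_path: str,
        target_port: str | None,
    ) -> None:
        self.decl = decl
        self.source_path = source_path
        self.source_port = source_port
        self.target_path = target_path
        self.target_port = target_port
        if decl.taps:
            self.buffer = DelayBuffer(taps=decl.taps)
        else:
            self.buffer = DelayBuffer(length=decl.delay_ticks)

    def read(self):
        return self.buffer.read()

    def write(self, value) -> None:
        self.buffer.write(value)


class Network:
    """A built, runnable network with a synchronous tick schedule."""

    def __init__(
        self,
        spec: ModelSpec,
        dt: float,
        components: dict[str, ComponentRuntime],
        connections: list[ConnectionRuntime],
    ) -> None:
        self.spec = spec
        self.dt = dt
        self.components = components
        self.connections = connections
        self.t = 0

    # -- stepping ----------------------------------------------------------
    def tick(self, externals: Mapping | None = None, learning: bool = True) -> None:
        """Advance the whole network by one step of ``dt`` seconds.

        ``externals`` maps stimulus-channel names to this tick's values;
        components only see the channels they declared.
        """
        externals = externals or {}
        per_target: dict[str, dict[str | None, list]] = defaultdict(lambda: defaultdict(list))
        for conn in self.connections:
            per_target[conn.target_path][conn.target_port].append((conn.read(), conn))
        for path, comp in self.components.items():
            comp.step(per_target.get(path, {}), externals, self.dt, learning)
        for conn in self.connections:
            conn.write(self.components[conn.source_path].output(conn.source_port))
        self.t += 1

    def output(self, path: str, port: str | None = None):
        return self.components[path].output(port)

    def reset(self, full: bool = False) -> None:
        """Zero all dynamic state (and, with ``full``, all learned state)."""
        for comp in self.components.values():
            comp.reset(full=full)
        for conn in self.connections:
            conn.buffer.reset()
        self.t = 0

    # -- introspection -----------------------------------------------------
    def component_count(self) -> int:
        """Number of model components (nuclei + functional units; actuators excluded)."""
        return sum(1 for c in self.components.values() if c.decl.kind != "actuator")

    def graph(self, split_actuator_ports: bool = True) -> nx.DiGraph:
        """Component-level directed graph (source ports merged into their component;
        actuator input ports kept as distinct sink nodes so the two iris
        muscles remain separate endpoints)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.components)
        for conn in self.connections:
            tgt = conn.target_path
            if (
                split_actuator_ports
                and conn.target_port is not None
                and self.components[tgt].decl.kind == "actuator"
            ):
                tgt = f"{tgt}.{conn.target_port}"
            g.add_edge(conn.source_path, tgt, kind=conn.decl.kind.value)
        return g

    def shortest_hops(self, source: str, target: str) -> int:
        """Number of connection hops on the shortest directed path."""
        return nx.shortest_path_length(self.graph(), source, target)

    def scalar_signals(self) -> list[tuple[str, str | None]]:
        """Recordable scalar outputs: ``(component path, port)`` pairs."""
        sigs: list[tuple[str, str | None]] = []
        for path, comp in self.components.items():
            if np.ndim(comp.output(None)) == 0:
                sigs.append((path, None))
            for port in comp.decl.ports:
                if comp.decl.ports[port].direction == "out":
                    if np.ndim(comp.output(port)) == 0:
                        sigs.append((path, port))
        return sigs

    def check_non_plastic_weights(self) -> None:
        """Assert the non-plastic weight convention (w == 1, bitwise) still holds."""
        for conn in self.connections:
            if not conn.decl.plastic and conn.decl.weight != 1.0:
                raise RuntimeError(
                    f"non-plastic weight mutated on {conn.source_path} -> "
                    f"{conn.target_path}: {conn.decl.weight!r}"
                )


def build_network(
    spec: ModelSpec,
    dt: float = 0.01,
    registry: Mapping[str, Factory] | None = None,
    gain: GainAdaptation | None = None,
) -> Network:
    """Instantiate a validated model spec into a runnable :class:`Network`.

    ``registry`` maps each functional/actuator ``impl`` key to a factory
    ``(path, decl) -> FunctionalRuntime``.  Nucleus parameters are taken
    from the component's declared params (``alpha``, ``epsilon``, ``beta``,
    ``gamma``), falling back to the module defaults.  Raises
    :class:`ModelSpecError` listing every diagnostic if validation fails.
    """
    diags = validate_spec(spec)
    if diags:
        raise ModelSpecError(
            "spec failed validation:\n" + "\n".join(str(d) for d in diags)
        )
    registry = dict(registry or {})
    gain = gain or GainAdaptation()
    comps = spec.components()

    resolved = [
        (conn, spec.resolve(conn.source), spec.resolve(conn.target))
        for conn in spec.connections
    ]

    n_excit: dict[str, int] = {path: 0 for path in comps}
    for conn, _src, (tpath, tport) in resolved:
        if tport is None and conn.kind is ConnectionKind.EXCITATORY:
            n_excit[tpath] += 1

    components: dict[str, ComponentRuntime] = {}
    for path, decl in comps.items():
        if decl.kind == "nucleus":
            p = {k: v.value for k, v in decl.params.items()}
            params = NucleusParams(
                alpha=p.get("alpha", 0.0),
                epsilon=p.get("epsilon", 0.1),
                beta=p.get("beta"),
                gamma=p.get("gamma"),
            )
            if dt > params.epsilon:
                raise ModelSpecError(
                    f"{path}: dt={dt} exceeds epsilon={params.epsilon}"
                )
            n = n_excit[path] + (1 if decl.external else 0)
            components[path] = NucleusRuntime(path, decl, params, gain, n)
        else:
            if decl.impl is None or decl.impl not in registry:
                raise ModelSpecError(
                    f"{path}: no implementation registered for "
                    f"{decl.kind} impl={decl.impl!r}"
                )
            components[path] = registry[decl.impl](path, decl)

    connections = [
        ConnectionRuntime(conn, spath, sport, tpath, tport)
        for conn, (spath, sport), (tpath, tport) in resolved
    ]
    return Network(spec, dt, components, connections)
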