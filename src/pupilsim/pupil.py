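"""The pupil-control network: anatomy, functional components, and the iris plant.

The shipped model (``data/pupil.model``) wires fifteen nuclei and three
functional components into the two antagonist pathways that set pupil
diameter:

* **Parasympathetic (constriction)** — retina (R) -> pretectal area (PTA)
  -> Edinger-Westphal nucleus, preganglionic part (EWpg) -> ciliary
  ganglion (CG) -> sphincter muscle.  Light drives this chain, producing
  the pupillary light reflex.
* **Sympathetic (dilation)** — hypothalamic relays (LH -> DMH -> IML, with
  the paraventricular nucleus PVN joining at the intermediolateral column
  IML) -> superior cervical ganglion (SCG) -> dilator muscle.  Arousal
  drives this chain; it is one hop longer than the parasympathetic one,
  which is the structural reason dilation is slower than constriction.
* **Modulation** — the amygdala (AMY) projects to the locus coeruleus
  (LC), which shunts EWpg: an aroused state divisively suppresses the
  light reflex (the fear-inhibited light reflex).  A circadian-flavoured
  branch (R -> SCN -> VLPO -| LC) keeps LC in check under bright light.
* **Recognition and learning** — the visual cortex reports a recognized
  stimulus identity (one-hot) plus a surprise signal that decays with
  repeated exposure; the cerebellum (CB) learns to predict an imminent
  brightness change from the identity trace (classical conditioning of
  the light response, with a connection delay tuned to the optimal
  inter-stimulus interval); the amygdala learns signed stimulus valence
  but reports arousal as the polarity-independent magnitude.

Stimulus identity is symbolic (an index into a fixed identity set), as is
its valence; both are injected through declared external channels rather
than through image processing, which keeps the recognition front-end out
of scope while exercising the full downstream circuitry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources

import numpy as np

from .dynamics import GainAdaptation
from .modelspec import ComponentDecl, ModelSpec, parse_model_spec
from .network import Factory, FunctionalRuntime, Network, build_network

__all__ = [
    "PupilPlant",
    "CortexOutput",
    "CerebellumState",
    "AmygdalaState",
    "PupilConfig",
    "pupil_plant_step",
    "cortex_step",
    "cerebellum_step",
    "amygdala_step",
    "load_pupil_spec",
    "pupil_registry",
    "build_pupil_network",
    "CORTEX_PATH",
    "CEREBELLUM_PATH",
    "AMYGDALA_PATH",
    "PLANT_PATH",
    "RETINA_PATH",
]

CORTEX_PATH = "cortex.Cortex"
CEREBELLUM_PATH = "cerebellum.CB"
AMYGDALA_PATH = "amygdala.AMY"
PLANT_PATH = "plant"
RETINA_PATH = "eye.R"


# ---------------------------------------------------------------------------
# pupil plant
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PupilPlant:
    """Static map from antagonist drives to pupil diameter.

    The model's outputs are neural drives; a plant is needed to express
    them in millimetres.  Diameter responds linearly to the sphincter
    (constriction) and dilator (dilation) drives and is clipped to the
    physiological range.  Zero drives give the resting diameter.
    """

    d_rest: float = 4.0
    d_min: float = 2.0
    d_max: float = 8.0
    g_s: float = 3.0
    g_d: float = 3.0

    def __post_init__(self) -> None:
        if not (self.d_min <= self.d_rest <= self.d_max):
            raise ValueError("need d_min <= d_rest <= d_max")


def pupil_plant_step(
    sphincter_drive: float, dilator_drive: float, plant: PupilPlant
) -> float:
    """Diameter (mm) for the given non-negative antagonist drives."""
    if not (math.isfinite(sphincter_drive) and math.isfinite(dilator_drive)):
        raise ValueError("non-finite plant drive")
    d = plant.d_rest - plant.g_s * sphincter_drive + plant.g_d * dilator_drive
    return min(max(d, plant.d_min), plant.d_max)


# ---------------------------------------------------------------------------
# visual cortex: identity + surprise
# ---------------------------------------------------------------------------

@dataclass
class CortexOutput:
    """One-hot recognized identity plus a scalar surprise in [0, 1]."""

    identity: np.ndarray
    surprise: float


def cortex_step(
    identity: int,
    familiarity: np.ndarray,
    decay: float = 0.6,
) -> tuple[CortexOutput, np.ndarray]:
    """Recognize one stimulus presentation and update its familiarity count.

    ``surprise = decay ** k`` where ``k`` is the number of prior exposures
    of this identity: 1.0 on first exposure, geometrically smaller on each
    repeat, never recovering (novelty is per-identity and is not
    forgotten).  Returns the cortical output and the incremented
    familiarity counter.  A negative identity means a blank frame: zero
    identity vector, zero surprise, no counting.
    """
    n = len(familiarity)
    one_hot = np.zeros(n)
    if identity < 0:
        return CortexOutput(identity=one_hot, surprise=0.0), familiarity
    if identity >= n:
        raise ValueError(f"identity {identity} outside capacity {n}")
    one_hot[identity] = 1.0
    surprise = float(decay ** familiarity[identity])
    new_familiarity = familiarity.copy()
    new_familiarity[identity] += 1
    return CortexOutput(identity=one_hot, surprise=surprise), new_familiarity


# ---------------------------------------------------------------------------
# cerebellum: tapped-delay-line conditioning
# ---------------------------------------------------------------------------

@dataclass
class CerebellumState:
    """Plastic weights of the conditioned light response.

    ``weights[k, i]`` associates tap ``k`` of the delayed identity trace of
    stimulus ``i`` with the brightness teaching signal.  All weights start
    at zero (no response before training) and stay non-negative, so the
    prediction is a non-negative combination of CS traces and weights.
    """

    weights: np.ndarray
    eta: float = 0.1
    taps: tuple[int, ...] = (1,)

    @classmethod
    def zeros(
        cls, n_identities: int, taps: tuple[int, ...] = (1,), eta: float = 0.1
    ) -> "CerebellumState":
        return cls(weights=np.zeros((len(taps), n_identities)), eta=eta, taps=taps)


def cerebellum_step(
    cs_traces: np.ndarray,
    us: float,
    state: CerebellumState,
    learning: bool = True,
) -> tuple[float, CerebellumState]:
    """Predict the brightness teaching signal from delayed CS traces.

    ``cs_traces`` has one row per tap (delayed one-hot identity vectors).
    Prediction is the weighted sum over all taps; with learning enabled the
    delta rule moves the weights of the *active* taps toward the teaching
    signal: ``dw = eta * trace * (us - prediction)``, clipped at zero.
    Credit therefore lands on whichever tap delay matches the CS-US
    inter-stimulus interval.
    """
    traces = np.atleast_2d(np.asarray(cs_traces, dtype=float))
    if traces.shape != state.weights.shape:
        raise ValueError(
            f"trace shape {traces.shape} does not match weights {state.weights.shape}"
        )
    if us < 0:
        raise ValueError("teaching signal must be non-negative")
    prediction = float(np.sum(state.weights * traces))
    if learning and traces.any():
        new_w = state.weights + state.eta * traces * (us - prediction)
        np.clip(new_w, 0.0, None, out=new_w)
        state = replace(state, weights=new_w)
    return prediction, state


# ---------------------------------------------------------------------------
# amygdala: polarity-independent emotional arousal
# ---------------------------------------------------------------------------

@dataclass
class AmygdalaState:
    """Per-identity valence weights (positive and negative channels).

    Both channels store magnitudes in [0, 1]; arousal is their sum, so a
    strongly positive and a strongly negative stimulus arouse equally.
    """

    positive: np.ndarray
    negative: np.ndarray
    eta: float = 0.1

    @classmethod
    def zeros(cls, n_identities: int, eta: float = 0.1) -> "AmygdalaState":
        return cls(
            positive=np.zeros(n_identities), negative=np.zeros(n_identities), eta=eta
        )


def amygdala_step(
    identity: np.ndarray,
    surprise: float,
    valence_input: float,
    state: AmygdalaState,
    learning: bool = True,
) -> tuple[float, AmygdalaState]:
    """Arousal output and (optionally) one step of valence learning.

    ``arousal = sum_i identity_i * (|w+_i| + |w-_i|) + surprise``: learned
    emotional charge regardless of polarity, plus novelty.  With learning
    enabled and a non-zero valence input, the matching channel of the
    active identity moves toward ``|valence|`` at rate ``eta``.
    """
    identity = np.asarray(identity, dtype=float)
    if abs(valence_input) > 1:
        raise ValueError("valence must lie in [-1, 1]")
    arousal = float(identity @ (np.abs(state.positive) + np.abs(state.negative)) + surprise)
    if learning and valence_input != 0.0 and identity.any():
        target = abs(valence_input)
        if valence_input > 0:
            w = state.positive + state.eta * identity * (target - state.positive)
            state = replace(state, positive=w)
        else:
            w = state.negative + state.eta * identity * (target - state.negative)
            state = replace(state, negative=w)
    return arousal, state


# ---------------------------------------------------------------------------
# runtime wrappers
# ---------------------------------------------------------------------------

class CortexUnit(FunctionalRuntime):
    """Symbolic recognition front-end.

    Holds a per-identity familiarity counter; an exposure episode is a
    contiguous run of ticks with the same identity on the ``identity``
    channel, counted once at its onset.  The afferent retinal signal (via
    LGN) is delivered but recognition itself is symbolic.  Outputs: the
    one-hot identity vector (default port) and ``surprise``.
    """

    def __init__(
        self, path: str, decl: ComponentDecl, n_identities: int = 16, decay: float = 0.6
    ) -> None:
        super().__init__(path, decl)
        self.n_identities = n_identities
        self.decay = decay
        self.familiarity = np.zeros(n_identities)
        self._prev_identity = -1
        self.outputs = {None: np.zeros(n_identities), "surprise": 0.0}

    def step(self, incoming, externals, dt, learning) -> None:
        ident = int(externals.get("identity", -1))
        if ident != self._prev_identity:
            out, fam = cortex_step(ident, self.familiarity, self.decay)
            self.familiarity = fam
            self.outputs = {None: out.identity, "surprise": out.surprise}
            self._prev_identity = ident

    def reset(self, full: bool = False) -> None:
        if full:
            self.familiarity = np.zeros(self.n_identities)
        self._prev_identity = -1
        self.outputs = {None: np.zeros(self.n_identities), "surprise": 0.0}


class CerebellumUnit(FunctionalRuntime):
    """Conditioned light response: delayed identity traces -> brightness prediction.

    The delay sits on the cortico-cerebellar connection (a single fixed
    delay in the simulation variant, a tapped delay line in the robot
    variant); the teaching signal is the brightness flash channel
    (``us_light``).  Output: the scalar prediction.
    """

    def __init__(
        self,
        path: str,
        decl: ComponentDecl,
        n_identities: int = 16,
        taps: tuple[int, ...] = (1,),
        eta: float = 0.1,
    ) -> None:
        super().__init__(path, decl)
        self.n_identities = n_identities
        self.state = CerebellumState.zeros(n_identities, taps=taps, eta=eta)
        self.outputs = {None: 0.0}

    def _traces(self, incoming) -> np.ndarray:
        n_taps = len(self.state.taps)
        traces = np.zeros((n_taps, self.n_identities))
        for value, _conn in incoming.get(None, ()):
            rows = value if isinstance(value, tuple) else (value,)
            for k, row in enumerate(rows[:n_taps]):
                if np.ndim(row) == 0:  # silent buffer prefill
                    continue
                traces[k] += np.asarray(row, dtype=float)
        return traces

    def step(self, incoming, externals, dt, learning) -> None:
        us = float(externals.get("us_light", 0.0))
        prediction, self.state = cerebellum_step(
            self._traces(incoming), us, self.state, learning
        )
        self.outputs = {None: prediction}

    def reset(self, full: bool = False) -> None:
        if full:
            self.state = replace(self.state, weights=np.zeros_like(self.state.weights))
        self.outputs = {None: 0.0}


class AmygdalaUnit(FunctionalRuntime):
    """Emotional arousal: learned valence magnitude plus surprise.

    Receives the cortical surprise signal on its ``surprise`` input port
    and the subcortical salience relay (via pulvinar) on its default port;
    the symbolic identity and its valence arrive on external channels.
    The ``arousal`` external channel is a direct probe input added to the
    output, used by timing experiments to inject a controlled arousal
    step.  Output: scalar arousal.
    """

    def __init__(
        self, path: str, decl: ComponentDecl, n_identities: int = 16, eta: float = 0.1
    ) -> None:
        super().__init__(path, decl)
        self.n_identities = n_identities
        self.state = AmygdalaState.zeros(n_identities, eta=eta)
        self.outputs = {None: 0.0}

    def step(self, incoming, externals, dt, learning) -> None:
        surprise = sum(
            float(v) * c.decl.weight for v, c in incoming.get("surprise", ())
        )
        ident = int(externals.get("identity", -1))
        one_hot = np.zeros(self.n_identities)
        if 0 <= ident < self.n_identities:
            one_hot[ident] = 1.0
        valence = float(externals.get("valence", 0.0))
        arousal, self.state = amygdala_step(
            one_hot, surprise, valence, self.state, learning
        )
        self.outputs = {None: arousal + float(externals.get("arousal", 0.0))}

    def reset(self, full: bool = False) -> None:
        if full:
            self.state = AmygdalaState.zeros(self.n_identities, eta=self.state.eta)
        self.outputs = {None: 0.0}


class PlantUnit(FunctionalRuntime):
    """The iris: maps delivered sphincter/dilator drives to diameter (mm).

    Negative delivered drives are rectified (a muscle cannot be pushed);
    the default output is the diameter.
    """

    def __init__(self, path: str, decl: ComponentDecl, plant: PupilPlant) -> None:
        super().__init__(path, decl)
        self.plant = plant
        self.outputs = {None: plant.d_rest}

    def step(self, incoming, externals, dt, learning) -> None:
        def drive(port: str) -> float:
            return sum(
                max(0.0, float(v)) * c.decl.weight for v, c in incoming.get(port, ())
            )

        self.outputs = {
            None: pupil_plant_step(drive("sphincter"), drive("dilator"), self.plant)
        }

    def reset(self, full: bool = False) -> None:
        self.outputs = {None: self.plant.d_rest}


# ---------------------------------------------------------------------------
# configuration and assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PupilConfig:
    """Tunable parameters of the pupil network build.

    ``delay_ticks`` is the uniform connection delay; the cortico-cerebellar
    path instead uses ``cb_delay_ticks`` (simulation variant) or the
    ``cb_taps`` tapped delay line (robot variant) to match the optimal
    conditioning inter-stimulus interval.  Learning rates apply per paired
    tick.  ``epsilon`` is the shared nucleus time constant; components with
    an explicit ``epsilon`` in the model file keep their declared value.
    """

    dt: float = 0.01
    delay_ticks: int = 1
    cb_delay_ticks: int = 4
    cb_taps: tuple[int, ...] | None = None
    eta_cb: float = 0.1
    eta_amy: float = 0.1
    surprise_decay: float = 0.6
    n_identities: int = 16
    epsilon: float = 0.1
    plant: PupilPlant = field(default_factory=PupilPlant)
    gain: GainAdaptation = field(default_factory=GainAdaptation)

    @property
    def optimal_isi_ticks(self) -> int:
        """CS-US interval (in ticks) at which conditioning credit is maximal."""
        if self.cb_taps is not None:
            return min(self.cb_taps)
        return self.cb_delay_ticks

    @property
    def hop_delay_s(self) -> float:
        return self.delay_ticks * self.dt


@lru_cache(maxsize=1)
def _pupil_model_text() -> str:
    return (resources.files("pupilsim.data") / "pupil.model").read_text()


def load_pupil_spec(config: PupilConfig | None = None) -> ModelSpec:
    """The shipped pupil model description, adjusted to a configuration.

    The edge set is data (the model file), so structural revisions need no
    code change; the configuration only rewrites delays, the identity-set
    size, and the learning/decay parameters it owns.
    """
    config = config or PupilConfig()
    spec = parse_model_spec(_pupil_model_text())
    comps = spec.components()
    for conn in spec.connections:
        src, _ = spec.resolve(conn.source)
        tgt, _ = spec.resolve(conn.target)
        if src == CORTEX_PATH and tgt == CEREBELLUM_PATH:
            if config.cb_taps is not None:
                conn.taps = tuple(config.cb_taps)
                conn.delay_ticks = max(config.cb_taps)
            else:
                conn.taps = None
                conn.delay_ticks = config.cb_delay_ticks
        else:
            conn.delay_ticks = config.delay_ticks
    cortex = comps[CORTEX_PATH]
    cortex.output_shape = f"vector({config.n_identities})"
    return spec


def pupil_registry(config: PupilConfig) -> dict[str, Factory]:
    """Functional-implementation factories for the pupil model."""

    def make_cortex(path: str, decl: ComponentDecl) -> FunctionalRuntime:
        return CortexUnit(
            path, decl, n_identities=config.n_identities, decay=config.surprise_decay
        )

    def make_cerebellum(path: str, decl: ComponentDecl) -> FunctionalRuntime:
        # a tapped cortico-cerebellar connection delivers one trace per
        # offset; the single-fixed-delay variant delivers exactly one
        taps = config.cb_taps if config.cb_taps is not None else (config.cb_delay_ticks,)
        return CerebellumUnit(
            path,
            decl,
            n_identities=config.n_identities,
            taps=tuple(taps),
            eta=config.eta_cb,
        )

    def make_amygdala(path: str, decl: ComponentDecl) -> FunctionalRuntime:
        return AmygdalaUnit(path, decl, n_identities=config.n_identities, eta=config.eta_amy)

    def make_plant(path: str, decl: ComponentDecl) -> FunctionalRuntime:
        p = {k: v.value for k, v in decl.params.items()}
        plant = replace(
            config.plant,
            **{k: p[k] for k in ("d_rest", "d_min", "d_max", "g_s", "g_d") if k in p},
        )
        return PlantUnit(path, decl, plant)

    return {
        "cortex": make_cortex,
        "cerebellum": make_cerebellum,
        "amygdala": make_amygdala,
        "pupil_plant": make_plant,
    }


def build_pupil_network(
    config: PupilConfig | None = None, **overrides
) -> Network:
    """Build the default pupil-control network.

    Keyword overrides are applied to :class:`PupilConfig`, e.g.
    ``build_pupil_network(dt=0.005, cb_taps=(2, 4, 6, 8, 10))``.  The
    built network carries its configuration as ``network.config``.
    """
    config = replace(config or PupilConfig(), **overrides)
    spec = load_pupil_spec(config)
    if config.epsilon != 0.1:
        for path, comp in spec.components().items():
            if comp.kind == "nucleus" and "epsilon" not in comp.params:
                from .modelspec import ParamDecl

                comp.params["epsilon"] = ParamDecl(
                    value=config.epsilon, param_class="empirical"
                )
    net = build_network(
        spec, dt=config.dt, registry=pupil_registry(config), gain=config.gain
    )
    net.config = config
    return net
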