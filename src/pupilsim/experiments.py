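"""Simulation harness: trace recording, response metrics, and the validation suite.

The behavioral experiments mirror the phenomena the pupil network is meant
to reproduce, as qualitative orderings rather than curve fits:

* **light reflex** — constriction amplitude grows, and latency does not
  grow, with stimulus intensity;
* **novelty** — dilation to a repeated stimulus habituates from its first
  exposure;
* **emotion** — positively and negatively conditioned stimuli dilate
  equally (arousal is polarity-independent);
* **conditioning** — after CS-US pairing a stimulus presented at equal
  luminance elicits constriction on its own, and learning is tuned to the
  inter-stimulus interval matching the cerebellar path delay;
* **fear inhibition** — a fear-conditioned stimulus preceding a light step
  reduces the light reflex;
* **asymmetry** — dilation is slower than constriction, because the
  sympathetic chain is one hop longer than the parasympathetic one.

Failed orderings are reported in each result's ``checks`` mapping (and in
the aggregate :func:`validation_suite` report), not raised as exceptions,
so a command-line run can always emit a complete report.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .network import Network
from .protocols import (
    StimulusProtocol,
    make_conditioning_protocol,
    make_fear_light_protocol,
    make_light_protocol,
    make_novelty_protocol,
)
from .pupil import AMYGDALA_PATH, PLANT_PATH, build_pupil_network

__all__ = [
    "TraceRecord",
    "ResponseMetrics",
    "run_simulation",
    "response_metrics",
    "time_to_fraction",
    "LightReflexResult",
    "light_reflex_curve",
    "HabituationResult",
    "habituation_curve",
    "EmotionResult",
    "emotion_experiment",
    "ConditioningResult",
    "conditioning_experiment",
    "FearInhibitionResult",
    "fear_inhibition_experiment",
    "AsymmetryResult",
    "asymmetry_experiment",
    "PopulationResult",
    "population_run",
    "validation_suite",
]


# ---------------------------------------------------------------------------
# running and recording
# ---------------------------------------------------------------------------

@dataclass
class TraceRecord:
    """Recorded per-tick series for every scalar signal in a run."""

    dt: float
    series: dict[str, np.ndarray]

    def __getitem__(self, key: str) -> np.ndarray:
        return self.series[key]

    @property
    def duration_ticks(self) -> int:
        return len(next(iter(self.series.values()))) if self.series else 0

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.series)
        df.insert(0, "time", np.arange(len(df)) * self.dt)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def run_simulation(
    network: Network,
    protocol: StimulusProtocol,
    seed: int | None = None,
    learning: bool = True,
) -> TraceRecord:
    """Drive ``network`` with ``protocol`` tick by tick, recording all outputs.

    Deterministic given the network state and protocol (``seed`` is
    accepted for interface uniformity and reserved for stochastic protocol
    options).  The network is advanced in place.  Raises if the protocol
    step size differs from the network's, if any signal goes non-finite
    (reporting the first bad tick), or if a non-plastic weight changed.
    """
    if abs(protocol.dt - network.dt) > 1e-12:
        raise ValueError(
            f"protocol dt={protocol.dt} does not match network dt={network.dt}"
        )
    signals = network.scalar_signals()
    names = [p if q is None else f"{p}.{q}" for p, q in signals]
    n = protocol.duration_ticks
    data = np.empty((len(signals), n))
    for t in range(n):
        network.tick(protocol.externals_at(t), learning=learning)
        for i, (path, port) in enumerate(signals):
            data[i, t] = network.output(path, port)
    bad = ~np.isfinite(data)
    if bad.any():
        i, t = np.argwhere(bad)[0]
        raise RuntimeError(f"non-finite signal {names[i]!r} at tick {t}")
    network.check_non_plastic_weights()
    return TraceRecord(dt=network.dt, series={k: data[i] for i, k in enumerate(names)})


# ---------------------------------------------------------------------------
# response metrics
# ---------------------------------------------------------------------------

@dataclass
class ResponseMetrics:
    """Shape descriptors of one evoked response.

    ``amplitude`` is the signed peak deviation from baseline (negative =
    constriction, positive = dilation).  ``latency_s`` is the interpolated
    time after onset at which the deviation first exceeds 10% of the peak;
    it is ``None`` for a flat response.  ``recovery_half_s`` is the time
    from the peak back to half the peak deviation (``None`` if the trace
    never recovers that far).
    """

    baseline: float
    amplitude: float
    latency_s: float | None
    time_to_peak_s: float | None
    recovery_half_s: float | None


def time_to_fraction(
    series: np.ndarray,
    dt: float,
    onset_tick: int,
    fraction: float,
    baseline: float,
    amplitude: float,
) -> float | None:
    """Interpolated time after onset at which |deviation| reaches ``fraction * |amplitude|``."""
    dev = np.abs(np.asarray(series[onset_tick:], dtype=float) - baseline)
    threshold = fraction * abs(amplitude)
    above = np.nonzero(dev >= threshold)[0]
    if len(above) == 0:
        return None
    i = int(above[0])
    if i == 0:
        return 0.0
    lo, hi = dev[i - 1], dev[i]
    frac = (threshold - lo) / (hi - lo) if hi > lo else 0.0
    return (i - 1 + frac) * dt


def response_metrics(
    series: np.ndarray,
    dt: float,
    onset_tick: int,
    baseline_window: tuple[int, int] | None = None,
    flat_tol: float = 1e-9,
) -> ResponseMetrics:
    """Extract baseline, amplitude, latency, time-to-peak, and half-recovery.

    The baseline is the mean over ``baseline_window`` (default: everything
    before onset).  Threshold crossings are linearly interpolated between
    ticks.
    """
    series = np.asarray(series, dtype=float)
    a, b = baseline_window if baseline_window is not None else (0, onset_tick)
    if b <= a or b > onset_tick:
        raise ValueError("baseline window must be non-empty and precede onset")
    baseline = float(series[a:b].mean())
    dev = series[onset_tick:] - baseline
    if len(dev) == 0 or np.abs(dev).max() <= flat_tol:
        return ResponseMetrics(baseline, 0.0, None, None, None)
    peak = int(np.argmax(np.abs(dev)))
    amplitude = float(dev[peak])
    latency = time_to_fraction(series, dt, onset_tick, 0.1, baseline, amplitude)
    half = np.nonzero(np.abs(dev[peak:]) <= abs(amplitude) / 2.0)[0]
    if len(half) == 0:
        recovery = None
    else:
        i = int(half[0])
        if i == 0:
            recovery = 0.0
        else:
            lo, hi = abs(dev[peak + i - 1]), abs(dev[peak + i])
            frac = (lo - abs(amplitude) / 2.0) / (lo - hi) if lo > hi else 0.0
            recovery = (i - 1 + frac) * dt
    return ResponseMetrics(
        baseline=baseline,
        amplitude=amplitude,
        latency_s=latency,
        time_to_peak_s=peak * dt,
        recovery_half_s=recovery,
    )


def _fresh(network: Network, full: bool = False) -> Network:
    """A copy of ``network`` with dynamic (and optionally learned) state cleared."""
    net = copy.deepcopy(network)
    net.reset(full=full)
    return net


def _diameter_metrics(
    network: Network,
    protocol: StimulusProtocol,
    onset_tick: int,
    learning: bool = False,
    baseline_window: tuple[int, int] | None = None,
) -> tuple[ResponseMetrics, TraceRecord]:
    trace = run_simulation(network, protocol, learning=learning)
    m = response_metrics(
        trace[PLANT_PATH], trace.dt, onset_tick, baseline_window=baseline_window
    )
    return m, trace


# ---------------------------------------------------------------------------
# light reflex
# ---------------------------------------------------------------------------

@dataclass
class LightReflexResult:
    intensities: tuple[float, ...]
    metrics: list[ResponseMetrics]
    checks: dict[str, bool]

    @property
    def passed(self) -> bool:
        return all(self.checks.values())


def light_reflex_curve(
    network: Network,
    intensities: Sequence[float],
    onset_s: float = 1.0,
    duration_s: float = 1.0,
    total_s: float = 3.0,
) -> LightReflexResult:
    """Constriction metrics across an increasing series of light intensities.

    Checks that constriction magnitude is strictly increasing and latency
    non-increasing in intensity.  Each intensity runs on a fresh copy of
    the network.
    """
    intensities = tuple(intensities)
    dt = network.dt
    onset = int(round(onset_s / dt))
    metrics = []
    for intensity in intensities:
        proto = make_light_protocol(intensity, onset_s, duration_s, total_s, dt=dt)
        m, _ = _diameter_metrics(_fresh(network), proto, onset)
        metrics.append(m)
    amps = [abs(m.amplitude) for m in metrics]
    lats = [m.latency_s for m in metrics]
    checks = {
        "amplitude_increases_with_intensity": all(
            a2 > a1 for a1, a2 in zip(amps, amps[1:])
        ),
        "latency_non_increasing": all(
            l1 is not None and l2 is not None and l2 <= l1 + dt / 2
            for l1, l2 in zip(lats, lats[1:])
        ),
    }
    return LightReflexResult(intensities=intensities, metrics=metrics, checks=checks)


# ---------------------------------------------------------------------------
# novelty / habituation
# ---------------------------------------------------------------------------

@dataclass
class HabituationResult:
    amplitudes: np.ndarray
    checks: dict[str, bool]

    @property
    def passed(self) -> bool:
        return all(self.checks.values())


def habituation_curve(
    network: Network,
    repeats: int,
    identity: int = 3,
    exposure_s: float = 0.5,
    gap_s: float = 2.0,
    light_level: float = 0.3,
) -> HabituationResult:
    """Dilation amplitude per presentation of one repeated stimulus.

    Luminance is held constant throughout, so dilation is novelty-driven.
    Each amplitude is measured against its own pre-onset baseline.  Checks:
    the first presentation dilates strictly more than every later one, and
    the sequence is non-increasing.
    """
    if repeats < 2:
        raise ValueError("need at least two presentations to habituate")
    dt = network.dt
    net = _fresh(network)
    lead_in_s = 1.5
    proto = make_novelty_protocol(
        [identity] * repeats,
        exposure_s=exposure_s,
        gap_s=gap_s,
        dt=dt,
        light_level=light_level,
        lead_in_s=lead_in_s,
    )
    trace = run_simulation(net, proto, learning=True)
    period = exposure_s + gap_s
    period_ticks = int(round(period / dt))
    window = int(round(0.25 / dt))
    amplitudes = []
    for k in range(repeats):
        onset = int(round((lead_in_s + k * period) / dt))
        # metrics confined to this presentation's own period
        segment = trace[PLANT_PATH][onset - window : onset + period_ticks]
        m = response_metrics(segment, dt, window, baseline_window=(0, window))
        amplitudes.append(m.amplitude)
    amplitudes = np.array(amplitudes)
    checks = {
        "first_exposure_dilates_most": bool(np.all(amplitudes[0] > amplitudes[1:])),
        "dilation_non_increasing": bool(
            np.all(np.diff(amplitudes) <= 1e-9)
        ),
        "dilation_positive_on_first_exposure": bool(amplitudes[0] > 0),
    }
    return HabituationResult(amplitudes=amplitudes, checks=checks)


# ---------------------------------------------------------------------------
# emotional reactivity
# ---------------------------------------------------------------------------

@dataclass
class EmotionResult:
    amplitude_positive: float
    amplitude_negative: float
    arousal_positive: float
    arousal_negative: float
    checks: dict[str, bool]

    @property
    def passed(self) -> bool:
        return all(self.checks.values())


def emotion_experiment(
    network: Network,
    positive_id: int = 1,
    negative_id: int = 2,
    trials: int = 5,
    light_level: float = 0.3,
) -> EmotionResult:
    """Equal-magnitude dilation to positively and negatively conditioned stimuli.

    Two stimuli receive identical training schedules differing only in
    valence sign (+1 vs -1); at test each is shown alone at equal
    luminance and with learning frozen.  Checks that both dilate, and that
    the two amplitudes (and peak amygdala arousals) are equal to within a
    relative tolerance — arousal encodes emotional magnitude, not sign.
    """
    dt = network.dt
    net = _fresh(network)
    ids = [positive_id, negative_id] * trials
    valences = [1.0, -1.0] * trials
    train = make_novelty_protocol(
        ids, dt=dt, light_level=light_level, valences=valences
    )
    run_simulation(net, train, learning=True)

    results = {}
    for ident in (positive_id, negative_id):
        test = make_novelty_protocol(
            [ident], dt=dt, light_level=light_level, lead_in_s=1.5
        )
        onset = int(round(1.5 / dt))
        test_net = copy.deepcopy(net)
        m, trace = _diameter_metrics(test_net, test, onset, learning=False)
        arousal = float(trace[AMYGDALA_PATH].max())
        results[ident] = (m.amplitude, arousal)
    amp_p, aro_p = results[positive_id]
    amp_n, aro_n = results[negative_id]
    checks = {
        "both_valences_dilate": amp_p > 0 and amp_n > 0,
        "arousal_polarity_independent": math.isclose(aro_p, aro_n, rel_tol=1e-6),
        "dilation_polarity_independent": math.isclose(amp_p, amp_n, rel_tol=1e-3),
    }
    return EmotionResult(
        amplitude_positive=amp_p,
        amplitude_negative=amp_n,
        arousal_positive=aro_p,
        arousal_negative=aro_n,
        checks=checks,
    )


# ---------------------------------------------------------------------------
# classical conditioning of the light response
# ---------------------------------------------------------------------------

@dataclass
class ConditioningResult:
    isi_values: tuple[float, ...]
    tuning: dict[float, float]  # ISI (s) -> |CR amplitude| (mm)
    test_metrics: ResponseMetrics
    control_amplitude: float
    optimal_isi_s: float
    checks: dict[str, bool]

    @property
    def passed(self) -> bool:
        return all(self.checks.values())


def conditioning_experiment(
    network: Network,
    isi_values: Sequence[float] = (0.02, 0.03, 0.04, 0.05, 0.06),
    n_trials: int = 20,
    cs_id: int = 0,
    control_id: int = 1,
    us_brightness: float = 1.0,
) -> ConditioningResult:
    """ISI tuning of the conditioned light response, plus a CS-alone test.

    For each inter-stimulus interval a fresh network is trained on
    ``n_trials`` CS-US pairings, then probed with the CS alone at equal
    luminance and learning frozen; the conditioned constriction amplitude
    forms the tuning curve.  A familiarized but never-paired control
    stimulus provides the null response.  Checks: the trained CS alone
    constricts, the control does not, and the tuning peaks at the ISI
    matching the cerebellar path delay.
    """
    dt = network.dt
    cs_dur = 0.03
    expected_isi = getattr(
        network, "config", None
    ) and network.config.optimal_isi_ticks * dt

    def cs_alone(ident: int) -> StimulusProtocol:
        return make_novelty_protocol(
            [ident], exposure_s=cs_dur, gap_s=1.5, dt=dt, light_level=0.0, lead_in_s=1.0
        )

    familiarize = make_novelty_protocol(
        [control_id] * 10, exposure_s=cs_dur, gap_s=0.5, dt=dt, light_level=0.0
    )
    onset = int(round(1.0 / dt))

    tuning: dict[float, float] = {}
    test_metrics = None
    control_amplitude = 0.0
    for isi in isi_values:
        net = _fresh(network, full=True)
        train = make_conditioning_protocol(
            n_trials, cs_id, isi, dt=dt, us_brightness=us_brightness,
            cs_duration_s=cs_dur,
        )
        run_simulation(net, train, learning=True)
        run_simulation(net, familiarize, learning=True)
        m, _ = _diameter_metrics(copy.deepcopy(net), cs_alone(cs_id), onset)
        tuning[isi] = abs(m.amplitude) if m.amplitude < 0 else 0.0
        if expected_isi is not None and math.isclose(isi, expected_isi, abs_tol=dt / 2):
            test_metrics = m
            mc, _ = _diameter_metrics(copy.deepcopy(net), cs_alone(control_id), onset)
            control_amplitude = mc.amplitude
    if test_metrics is None:  # expected ISI not among the probed values
        best = max(tuning, key=tuning.get)
        net = _fresh(network, full=True)
        run_simulation(
            net,
            make_conditioning_protocol(
                n_trials, cs_id, best, dt=dt, us_brightness=us_brightness,
                cs_duration_s=cs_dur,
            ),
            learning=True,
        )
        run_simulation(net, familiarize, learning=True)
        test_metrics, _ = _diameter_metrics(copy.deepcopy(net), cs_alone(cs_id), onset)
        mc, _ = _diameter_metrics(copy.deepcopy(net), cs_alone(control_id), onset)
        control_amplitude = mc.amplitude

    optimal = max(tuning, key=tuning.get)
    checks = {
        "trained_cs_alone_constricts": test_metrics.amplitude < -0.01,
        "untrained_control_flat": abs(control_amplitude) < 0.02,
        "tuning_peaks_at_cb_delay": (
            expected_isi is None or math.isclose(optimal, expected_isi, abs_tol=dt / 2)
        ),
    }
    return ConditioningResult(
        isi_values=tuple(isi_values),
        tuning=tuning,
        test_metrics=test_metrics,
        control_amplitude=control_amplitude,
        optimal_isi_s=optimal,
        checks=checks,
    )


# ---------------------------------------------------------------------------
# fear-inhibited light reflex
# ---------------------------------------------------------------------------

@dataclass
class FearInhibitionResult:
    amplitude_with_cs: float
    amplitude_without_cs: float
    checks: dict[str, bool]

    @property
    def reduction(self) -> float:
        return abs(self.amplitude_without_cs) - abs(self.amplitude_with_cs)

    @property
    def passed(self) -> bool:
        return all(self.checks.values())


def fear_inhibition_experiment(
    network: Network,
    pretrain_trials: int = 10,
    fear_id: int = 4,
    light_intensity: float = 0.5,
    lead_s: float = 1.0,
) -> FearInhibitionResult:
    """Reduced light-evoked constriction when preceded by a fear-conditioned CS.

    The stimulus is fear-conditioned (valence -1) after a familiarization
    phase, then the same light step is probed twice from the identical
    trained state: once preceded by the CS and once without it.  The lead
    time lets the CS-driven sympathetic dilation plateau before the light
    arrives, so the light-evoked constriction can be measured as the dip
    below the immediately pre-light baseline in both conditions.  With
    zero pretraining trials the two dips agree (null control); with
    training, the CS-preceded dip is smaller — arousal reaches the locus
    coeruleus, which divisively inhibits the constriction pathway.
    """
    dt = network.dt
    train, with_cs, without_cs = make_fear_light_protocol(
        fear_id, pretrain_trials, light_intensity=light_intensity, lead_s=lead_s, dt=dt
    )
    net = _fresh(network, full=True)
    run_simulation(net, train, learning=True)
    onset = int(round((1.0 + lead_s) / dt))
    window = int(round(0.25 / dt))
    # dip is evaluated while the light (and, with it, the held CS) is on,
    # so the post-offset collapse of the dilation plateau is not mistaken
    # for constriction
    end = onset + int(round(1.0 / dt))

    def light_dip(trained_net: Network, proto: StimulusProtocol) -> float:
        trace = run_simulation(trained_net, proto, learning=False)
        series = trace[PLANT_PATH]
        baseline = float(series[onset - window : onset].mean())
        return float(series[onset:end].min() - baseline)

    dip_with = light_dip(copy.deepcopy(net), with_cs)
    dip_without = light_dip(copy.deepcopy(net), without_cs)
    trained = pretrain_trials > 0
    checks = {
        "light_constricts": dip_without < 0,
        "fear_cs_reduces_constriction": (
            abs(dip_with) < abs(dip_without)
            if trained
            else abs(abs(dip_with) - abs(dip_without)) < 0.05
        ),
    }
    return FearInhibitionResult(
        amplitude_with_cs=dip_with,
        amplitude_without_cs=dip_without,
        checks=checks,
    )


# ---------------------------------------------------------------------------
# dilation / constriction timing asymmetry
# ---------------------------------------------------------------------------

@dataclass
class AsymmetryResult:
    contraction_time_to_peak_s: float
    dilation_time_to_peak_s: float
    hop_delay_s: float
    checks: dict[str, bool]

    @property
    def lag_s(self) -> float:
        return self.dilation_time_to_peak_s - self.contraction_time_to_peak_s

    @property
    def passed(self) -> bool:
        return all(self.checks.values())


def asymmetry_experiment(
    network: Network,
    light_intensity: float = 0.8,
    arousal_step: float = 1.0,
    onset_s: float = 1.0,
    duration_s: float = 0.5,
    total_s: float = 3.0,
) -> AsymmetryResult:
    """Dilation is slower than constriction by at least one connection delay.

    Matched step probes: a light step drives the 4-hop parasympathetic
    chain; an arousal step injected at the amygdala drives the 5-hop
    sympathetic chain.  Both chains pass four integrating nuclei, so the
    extra hop of the sympathetic route shows up directly as a longer time
    to peak.
    """
    dt = network.dt
    onset = int(round(onset_s / dt))
    light = make_light_protocol(light_intensity, onset_s, duration_s, total_s, dt=dt)
    m_con, _ = _diameter_metrics(_fresh(network), light, onset)

    probe = StimulusProtocol.blank(int(round(total_s / dt)), dt)
    probe.arousal[onset : onset + int(round(duration_s / dt))] = arousal_step
    m_dil, _ = _diameter_metrics(_fresh(network), probe, onset)

    hop = getattr(network, "config", None)
    hop_delay_s = hop.hop_delay_s if hop else dt
    checks = {
        "probes_have_opposite_sign": m_con.amplitude < 0 < m_dil.amplitude,
        "dilation_slower_than_contraction": (
            m_dil.time_to_peak_s is not None
            and m_con.time_to_peak_s is not None
            and m_dil.time_to_peak_s - m_con.time_to_peak_s >= hop_delay_s - 1e-9
        ),
    }
    return AsymmetryResult(
        contraction_time_to_peak_s=m_con.time_to_peak_s,
        dilation_time_to_peak_s=m_dil.time_to_peak_s,
        hop_delay_s=hop_delay_s,
        checks=checks,
    )


# ---------------------------------------------------------------------------
# population-level evaluation
# ---------------------------------------------------------------------------

@dataclass
class PopulationResult:
    runs: pd.DataFrame
    mean: pd.Series
    std: pd.Series


def _sample(rng: np.random.Generator, dist: tuple) -> float:
    kind, *args = dist
    if kind == "constant":
        return float(args[0])
    if kind == "normal":
        return float(rng.normal(args[0], args[1]))
    if kind == "uniform":
        return float(rng.uniform(args[0], args[1]))
    raise ValueError(f"unknown distribution kind {kind!r}")


def default_population_metric(network: Network) -> Mapping[str, float]:
    """Light-reflex amplitude and latency at a fixed probe intensity."""
    proto = make_light_protocol(0.8, 1.0, 1.0, 3.0, dt=network.dt)
    onset = int(round(1.0 / network.dt))
    m, _ = _diameter_metrics(network, proto, onset)
    return {"amplitude": m.amplitude, "latency_s": m.latency_s}


def population_run(
    builder: Callable[..., Network],
    param_distributions: Mapping[str, tuple],
    n_runs: int,
    seed: int,
    metric_fn: Callable[[Network], Mapping[str, float]] | None = None,
) -> PopulationResult:
    """Aggregate behavior over a population of parameter-sampled individuals.

    Each run draws one value per named parameter from its distribution
    (``("constant", v)``, ``("normal", mu, sd)`` or ``("uniform", lo,
    hi)``), builds a network with ``builder(**params)``, and evaluates
    ``metric_fn`` on it.  Per-run seeds derive deterministically from the
    master seed, so the same seed reproduces the same aggregate.
    """
    if n_runs < 1:
        raise ValueError("need at least one run")
    metric_fn = metric_fn or default_population_metric
    rows = []
    for child in np.random.SeedSequence(seed).spawn(n_runs):
        rng = np.random.default_rng(child)
        params = {k: _sample(rng, d) for k, d in param_distributions.items()}
        net = builder(**params)
        rows.append({**params, **metric_fn(net)})
    runs = pd.DataFrame(rows)
    numeric = runs.select_dtypes("number")
    return PopulationResult(runs=runs, mean=numeric.mean(), std=numeric.std(ddof=0))


# ---------------------------------------------------------------------------
# the full behavioral validation suite
# ---------------------------------------------------------------------------

def validation_suite(network: Network | None = None) -> dict[str, dict]:
    """Run all six behavioral experiments on one network configuration.

    Returns ``{experiment: {"passed": bool, "checks": {...}, ...summary
    numbers...}}`` plus an ``"overall"`` entry.  With no argument the
    shipped pupil model at default parameters is used.
    """
    net = network if network is not None else build_pupil_network()
    report: dict[str, dict] = {}

    lr = light_reflex_curve(net, (0.2, 0.5, 0.9))
    report["light_reflex"] = {
        "passed": lr.passed,
        "checks": lr.checks,
        "amplitudes_mm": [m.amplitude for m in lr.metrics],
        "latencies_s": [m.latency_s for m in lr.metrics],
    }

    hab = habituation_curve(net, repeats=5)
    report["novelty"] = {
        "passed": hab.passed,
        "checks": hab.checks,
        "amplitudes_mm": hab.amplitudes.tolist(),
    }

    emo = emotion_experiment(net)
    report["emotion"] = {
        "passed": emo.passed,
        "checks": emo.checks,
        "amplitude_positive_mm": emo.amplitude_positive,
        "amplitude_negative_mm": emo.amplitude_negative,
    }

    cond = conditioning_experiment(net, n_trials=12)
    report["conditioning"] = {
        "passed": cond.passed,
        "checks": cond.checks,
        "tuning": {f"{k:.2f}": v for k, v in cond.tuning.items()},
        "cs_alone_amplitude_mm": cond.test_metrics.amplitude,
        "optimal_isi_s": cond.optimal_isi_s,
    }

    fear = fear_inhibition_experiment(net)
    report["fear_inhibition"] = {
        "passed": fear.passed,
        "checks": fear.checks,
        "amplitude_with_cs_mm": fear.amplitude_with_cs,
        "amplitude_without_cs_mm": fear.amplitude_without_cs,
    }

    asym = asymmetry_experiment(net)
    report["asymmetry"] = {
        "passed": asym.passed,
        "checks": asym.checks,
        "contraction_time_to_peak_s": asym.contraction_time_to_peak_s,
        "dilation_time_to_peak_s": asym.dilation_time_to_peak_s,
    }

    report["overall"] = {"passed": all(r["passed"] for r in report.values())}
    return report
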