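"""Stimulus protocols: per-tick input timelines for the behavioral experiments.

A protocol is a bundle of named channels, one value per tick:

``light``
    Ambient/stimulus luminance in [0, 1], driving the retina.
``us_light``
    A brightness flash used as the unconditioned stimulus in conditioning;
    it adds to the retinal input and doubles as the cerebellar teaching
    signal.
``identity``
    Symbolic stimulus identity (an index; -1 means no stimulus shown),
    driving recognition, novelty, and associative learning.
``valence``
    Signed emotional value in [-1, 1] of the currently shown stimulus
    (the amygdala's teaching signal).
``arousal``
    Direct arousal probe injected at the amygdala; used by timing
    experiments to deliver a dilation step of controlled magnitude.

All generators are deterministic functions of their arguments.  Protocols
compose channel-wise: luminance-like channels by maximum, identity (and
its valence) first-wins — both operations are associative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StimulusProtocol",
    "make_light_protocol",
    "make_conditioning_protocol",
    "make_novelty_protocol",
    "make_fear_light_protocol",
]

MAX_CHANNELS = ("light", "us_light", "arousal")


@dataclass
class StimulusProtocol:
    """Per-tick multichannel stimulus timeline."""

    dt: float
    light: np.ndarray
    identity: np.ndarray
    valence: np.ndarray
    us_light: np.ndarray
    arousal: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.light)
        for name in ("identity", "valence", "us_light", "arousal"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name} has wrong length")
        if self.light.size and (self.light.min() < 0 or self.light.max() > 1):
            raise ValueError("light must stay within [0, 1]")

    @property
    def duration_ticks(self) -> int:
        return len(self.light)

    @property
    def duration_s(self) -> float:
        return self.duration_ticks * self.dt

    @classmethod
    def blank(cls, duration_ticks: int, dt: float) -> "StimulusProtocol":
        n = int(duration_ticks)
        return cls(
            dt=dt,
            light=np.zeros(n),
            identity=np.full(n, -1, dtype=int),
            valence=np.zeros(n),
            us_light=np.zeros(n),
            arousal=np.zeros(n),
        )

    def externals_at(self, tick: int) -> dict:
        return {
            "light": float(self.light[tick]),
            "us_light": float(self.us_light[tick]),
            "identity": int(self.identity[tick]),
            "valence": float(self.valence[tick]),
            "arousal": float(self.arousal[tick]),
        }

    def compose(self, other: "StimulusProtocol") -> "StimulusProtocol":
        """Overlay two protocols of equal step size.

        Luminance-like channels combine by element-wise maximum; the
        identity channel is first-wins (this protocol's stimulus, where
        present, shadows the other's), and valence follows identity.
        Shorter protocols are zero-padded.
        """
        if abs(self.dt - other.dt) > 1e-12:
            raise ValueError("cannot compose protocols with different dt")
        n = max(self.duration_ticks, other.duration_ticks)
        a, b = self.padded(n), other.padded(n)
        identity = np.where(a.identity >= 0, a.identity, b.identity)
        valence = np.where(a.identity >= 0, a.valence, b.valence)
        return StimulusProtocol(
            dt=self.dt,
            light=np.maximum(a.light, b.light),
            identity=identity,
            valence=valence,
            us_light=np.maximum(a.us_light, b.us_light),
            arousal=np.maximum(a.arousal, b.arousal),
        )

    def padded(self, duration_ticks: int) -> "StimulusProtocol":
        n = duration_ticks - self.duration_ticks
        if n < 0:
            raise ValueError("cannot pad to a shorter duration")
        if n == 0:
            return self
        pad = StimulusProtocol.blank(n, self.dt)
        return StimulusProtocol(
            dt=self.dt,
            light=np.concatenate([self.light, pad.light]),
            identity=np.concatenate([self.identity, pad.identity]),
            valence=np.concatenate([self.valence, pad.valence]),
            us_light=np.concatenate([self.us_light, pad.us_light]),
            arousal=np.concatenate([self.arousal, pad.arousal]),
        )

    # -- serialization -----------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": np.arange(self.duration_ticks) * self.dt,
                "light": self.light,
                "identity": self.identity,
                "valence": self.valence,
                "us_light": self.us_light,
                "arousal": self.arousal,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StimulusProtocol":
        df = pd.read_csv(path)
        t = df["time"].to_numpy()
        dt = float(t[1] - t[0]) if len(t) > 1 else 0.01
        return cls(
            dt=dt,
            light=df["light"].to_numpy(dtype=float),
            identity=df["identity"].to_numpy(dtype=int),
            valence=df["valence"].to_numpy(dtype=float),
            us_light=df["us_light"].to_numpy(dtype=float),
            arousal=df["arousal"].to_numpy(dtype=float),
        )


def _ticks(seconds: float, dt: float) -> int:
    return int(round(seconds / dt))


def make_light_protocol(
    intensity: float,
    onset_s: float,
    duration_s: float,
    total_s: float,
    dt: float = 0.01,
    baseline: float = 0.0,
) -> StimulusProtocol:
    """A single luminance step on an otherwise constant baseline.

    The light channel holds ``intensity`` on ``[onset, onset + duration)``
    and ``baseline`` elsewhere.  Reflex experiments use a dark baseline;
    novelty/emotion experiments use a non-zero ambient level so that
    dilation is observable.
    """
    if not 0.0 <= intensity <= 1.0:
        raise ValueError(f"intensity must lie in [0, 1], got {intensity}")
    if not 0.0 <= baseline <= 1.0:
        raise ValueError(f"baseline must lie in [0, 1], got {baseline}")
    if onset_s + duration_s > total_s:
        raise ValueError("stimulus must end before the protocol does")
    proto = StimulusProtocol.blank(_ticks(total_s, dt), dt)
    proto.light[:] = baseline
    a, b = _ticks(onset_s, dt), _ticks(onset_s + duration_s, dt)
    proto.light[a:b] = intensity
    return proto


def make_conditioning_protocol(
    n_trials: int,
    cs_id: int,
    isi_s: float,
    trial_spacing_s: float = 1.5,
    us_brightness: float = 1.0,
    dt: float = 0.01,
    test_trial: bool = False,
    cs_duration_s: float = 0.03,
    us_duration_s: float = 0.03,
    lead_in_s: float = 0.5,
    baseline_light: float = 0.0,
) -> StimulusProtocol:
    """Paired CS-US trials: a symbolic stimulus followed by a brightness flash.

    Each trial presents identity ``cs_id`` for ``cs_duration_s`` and, at
    ``isi_s`` after CS onset, a ``us_light`` flash of ``us_brightness``.
    The flash reaches the retina (so the unconditioned constriction
    occurs) and serves as the cerebellar teaching signal.  With
    ``test_trial`` a final CS-alone presentation is appended with zero
    flash — luminance there is identical to an untrained presentation, so
    any constriction is a conditioned response.  Short CS/US pulses keep
    the ISI tuning of learning sharp.
    """
    if n_trials < 1:
        raise ValueError("need at least one conditioning trial")
    if isi_s < dt:
        raise ValueError("inter-stimulus interval must be at least one tick")
    n_pres = n_trials + (1 if test_trial else 0)
    total = lead_in_s + n_pres * trial_spacing_s
    proto = StimulusProtocol.blank(_ticks(total, dt), dt)
    proto.light[:] = baseline_light
    for k in range(n_pres):
        onset = _ticks(lead_in_s + k * trial_spacing_s, dt)
        proto.identity[onset : onset + _ticks(cs_duration_s, dt)] = cs_id
        if k < n_trials:  # the appended test presentation is CS-alone
            us_on = onset + _ticks(isi_s, dt)
            proto.us_light[us_on : us_on + _ticks(us_duration_s, dt)] = us_brightness
    return proto


def make_novelty_protocol(
    ids: Sequence[int],
    exposure_s: float = 0.5,
    gap_s: float = 2.0,
    dt: float = 0.01,
    light_level: float = 0.3,
    lead_in_s: float = 1.0,
    valences: Sequence[float] | None = None,
) -> StimulusProtocol:
    """Sequential stimulus presentations under constant luminance.

    Identities are shown in order, each for ``exposure_s`` with ``gap_s``
    of blank between presentations; the light channel is held at a fixed
    ambient level throughout so pupil changes cannot be luminance-driven.
    ``valences`` optionally assigns an emotional value per presentation
    (for emotional-conditioning schedules).
    """
    ids = list(ids)
    if not ids:
        raise ValueError("need at least one presentation")
    if valences is not None and len(valences) != len(ids):
        raise ValueError("valences must match ids one-to-one")
    period = exposure_s + gap_s
    total = lead_in_s + len(ids) * period
    proto = StimulusProtocol.blank(_ticks(total, dt), dt)
    proto.light[:] = light_level
    for k, ident in enumerate(ids):
        a = _ticks(lead_in_s + k * period, dt)
        b = a + _ticks(exposure_s, dt)
        proto.identity[a:b] = ident
        if valences is not None:
            proto.valence[a:b] = valences[k]
    return proto


def make_fear_light_protocol(
    fear_id: int,
    pretrain_trials: int,
    light_intensity: float = 0.5,
    lead_s: float = 1.0,
    dt: float = 0.01,
    familiarization_trials: int = 10,
    exposure_s: float = 0.5,
    gap_s: float = 1.5,
    light_duration_s: float = 1.0,
    lead_in_s: float = 1.0,
    tail_s: float = 1.5,
) -> tuple[StimulusProtocol, StimulusProtocol, StimulusProtocol]:
    """Fear-conditioning schedule plus a matched pair of light-reflex probes.

    Returns ``(train, test_with_cs, test_without_cs)``.  Training first
    familiarizes the stimulus with neutral exposures (so that at test the
    conditioned stimulus is no longer novel — novelty itself arouses, and
    would confound the untrained null control), then pairs it with
    valence -1 for ``pretrain_trials`` exposures.  The two test protocols
    deliver bitwise-identical light steps; in one the light is preceded,
    ``lead_s`` earlier, by the conditioned stimulus (shown through the end
    of the light step so its arousal overlaps the reflex).
    """
    if lead_s <= 0:
        raise ValueError("the conditioned stimulus must precede the light")
    n_train = familiarization_trials + pretrain_trials
    valences = [0.0] * familiarization_trials + [-1.0] * pretrain_trials
    if n_train == 0:
        train = StimulusProtocol.blank(_ticks(lead_in_s, dt), dt)
    else:
        train = make_novelty_protocol(
            [fear_id] * n_train,
            exposure_s=exposure_s,
            gap_s=gap_s,
            dt=dt,
            light_level=0.0,
            lead_in_s=lead_in_s,
            valences=valences,
        )

    total = lead_in_s + lead_s + light_duration_s + tail_s
    without_cs = make_light_protocol(
        light_intensity, lead_in_s + lead_s, light_duration_s, total, dt=dt
    )
    with_cs = make_light_protocol(
        light_intensity, lead_in_s + lead_s, light_duration_s, total, dt=dt
    )
    a = _ticks(lead_in_s, dt)
    b = _ticks(lead_in_s + lead_s + light_duration_s, dt)
    with_cs.identity[a:b] = fear_id
    return train, with_cs, without_cs
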