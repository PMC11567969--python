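"""Stimulation protocols: repeated square-wave pulses and pseudo-random
orientation sequences.

A protocol is a sorted, non-overlapping list of stimulus events, each a
square-wave drive of a given amplitude on one of ``K`` channels.  Event
intervals are half-open ``[onset, onset + duration)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "StimulusEvent",
    "StimulusProtocol",
    "build_pulse_protocol",
    "build_orientation_protocol",
    "stimulus_drive",
]


class ProtocolError(ValueError):
    """Invalid protocol construction parameter."""


@dataclass(frozen=True)
class StimulusEvent:
    onset: float
    duration: float
    channel: int
    amplitude: float


@dataclass(frozen=True)
class StimulusProtocol:
    """Timed sequence of square-wave stimulus events on ``n_channels`` channels."""

    events: tuple[StimulusEvent, ...]
    total_duration: float
    n_channels: int = 1

    def __post_init__(self) -> None:
        evs = tuple(self.events)
        object.__setattr__(self, "events", evs)
        prev_end = -np.inf
        for e in evs:
            if e.duration <= 0:
                raise ProtocolError("event duration must be positive")
            if not (np.isfinite(e.amplitude) and np.isfinite(e.onset)):
                raise ProtocolError("event onset/amplitude must be finite")
            if not 0 <= e.channel < self.n_channels:
                raise ProtocolError("event channel out of range")
            if e.onset < prev_end:
                raise ProtocolError("events must be sorted and non-overlapping")
            prev_end = e.onset + e.duration
        if evs and prev_end > self.total_duration:
            raise ProtocolError("events extend beyond total_duration")

    @property
    def n_trials(self) -> int:
        return len(self.events)

    def drive_schedule(self, dt: float, n_steps: int) -> tuple[np.ndarray, np.ndarray]:
        """Step-indexed drive lookup for an Euler integrator.

        Returns ``(idx, table)`` where ``table[idx[s]]`` is the K-vector
        drive active during step ``s`` (the interval ``[s*dt, (s+1)*dt)``,
        evaluated at its left edge).  Row 0 of the table is the zero drive.
        """
        idx = np.zeros(n_steps, dtype=int)
        table = np.zeros((len(self.events) + 1, self.n_channels))
        for j, e in enumerate(self.events, start=1):
            table[j, e.channel] = e.amplitude
            s0 = int(np.ceil(e.onset / dt - 1e-9))
            s1 = int(np.ceil((e.onset + e.duration) / dt - 1e-9))
            idx[s0 : min(s1, n_steps)] = j
        return idx, table

    # -- YAML round-trip ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_channels": int(self.n_channels),
            "total_duration": float(self.total_duration),
            "events": [
                {
                    "onset": float(e.onset),
                    "duration": float(e.duration),
                    "channel": int(e.channel),
                    "amplitude": float(e.amplitude),
                }
                for e in self.events
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(
            events=tuple(StimulusEvent(**e) for e in d["events"]),
            total_duration=d["total_duration"],
            n_channels=d["n_channels"],
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "StimulusProtocol":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def build_pulse_protocol(
    n_trials: int,
    amplitudes: float | list[float],
    duration: float = 1.0,
    iti_range: tuple[float, float] = (5.0, 8.0),
    rng: np.random.Generator | None = None,
) -> StimulusProtocol:
    """Repeated single-channel square pulses separated by random intervals.

    Mirrors a deep-brain-stimulation paradigm: ``n_trials`` pulses of
    ``duration`` seconds on one channel, with inter-trial intervals drawn
    uniformly from ``iti_range``.  The protocol starts and ends with one
    interval draw of lead-in/tail.
    """
    if rng is None:
        rng = np.random.default_rng()
    lo, hi = iti_range
    if lo <= 0 or hi < lo:
        raise ProtocolError("iti_range must satisfy 0 < min <= max")
    if duration <= 0:
        raise ProtocolError("duration must be positive")
    amps = np.broadcast_to(np.atleast_1d(np.asarray(amplitudes, dtype=float)), (max(n_trials, 1),))
    events = []
    t = float(rng.uniform(lo, hi))
    for j in range(n_trials):
        events.append(StimulusEvent(onset=t, duration=duration, channel=0, amplitude=float(amps[j])))
        t += duration + float(rng.uniform(lo, hi))
    return StimulusProtocol(events=tuple(events), total_duration=t, n_channels=1)


def build_orientation_protocol(
    n_per_class: int,
    n_classes: int = 8,
    duration: float = 1.0,
    iti: float = 4.0,
    amplitude: float = 1.0,
    rng: np.random.Generator | None = None,
) -> StimulusProtocol:
    """Pseudo-random sequence of ``n_classes`` stimulus identities.

    Emulates a drifting-grating session with orientations 0°–315° in 45°
    steps: stimuli are presented in shuffled blocks (each block one
    presentation per class) so every class occurs exactly ``n_per_class``
    times, each for ``duration`` s followed by an ``iti`` s blank.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_classes < 1:
        raise ProtocolError("n_classes must be >= 1")
    if n_per_class < 1:
        raise ProtocolError("n_per_class must be >= 1")
    if duration <= 0 or iti <= 0:
        raise ProtocolError("duration and iti must be positive")
    order = np.concatenate([rng.permutation(n_classes) for _ in range(n_per_class)])
    events = []
    t = iti
    for c in order:
        events.append(StimulusEvent(onset=t, duration=duration, channel=int(c), amplitude=amplitude))
        t += duration + iti
    return StimulusProtocol(events=tuple(events), total_duration=t, n_channels=n_classes)


def stimulus_drive(protocol: StimulusProtocol, t: float) -> np.ndarray:
    """Drive vector ``s(t)``: the active event's amplitude on its channel.

    Square-wave semantics over the half-open interval ``[onset, offset)``.
    """
    if t < 0:
        raise ProtocolError("t must be nonnegative")
    drive = np.zeros(protocol.n_channels)
    for e in protocol.events:
        if e.onset <= t < e.onset + e.duration:
            drive[e.channel] = e.amplitude
            break
        if e.onset > t:
            break
    return drive
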