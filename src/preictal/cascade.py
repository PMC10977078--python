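"""Event-driven two-stage inference: BNN gate → CNN verifier.

The always-on binary network scans the window stream; a run of
``gate_threshold`` consecutive positive gate decisions raises a gate event.
Each gate event outside the post-alarm refractory period wakes the 8-bit
verifier network, whose positive decision confirms the alarm (a negative
decision rejects it — the false-alarm filter).  The fraction of stream
windows on which the verifier runs is the duty cycle, the software proxy for
the event-driven power saving: the cheap gate governs power, the verifier
governs the false-alarm rate.

Structural guarantees: confirmed alarms are a subset of gate events, so the
cascade's false-alarm rate and sensitivity never exceed the gate's; the
verifier invocation count equals the number of gate events outside
refractory, exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CascadeConfig",
    "GateState",
    "AlarmTrace",
    "gate_step",
    "verify_event",
    "run_cascade",
    "AlwaysPositiveVerifier",
]


@dataclass(frozen=True)
class CascadeConfig:
    """Event threshold, refractory period, and stream stepping."""

    gate_threshold: int = 1
    refractory_s: float = 300.0

    def __post_init__(self):
        if self.gate_threshold < 1:
            raise ValueError("gate_threshold must be >= 1")
        if self.refractory_s < 0:
            raise ValueError("refractory_s must be >= 0")


@dataclass
class GateState:
    consecutive_positives: int = 0


@dataclass
class AlarmTrace:
    """Timestamped cascade run record."""

    gate_events: list = field(default_factory=list)       # times (s)
    confirmed_alarms: list = field(default_factory=list)  # times (s)
    n_windows_total: int = 0
    n_cnn_invocations: int = 0
    gate_positive_windows: int = 0

    @property
    def duty_cycle(self) -> float:
        if self.n_windows_total == 0:
            return 0.0
        return self.n_cnn_invocations / self.n_windows_total

    def to_dict(self) -> dict:
        return {
            "gate_events": list(map(float, self.gate_events)),
            "confirmed_alarms": list(map(float, self.confirmed_alarms)),
            "n_windows_total": int(self.n_windows_total),
            "n_cnn_invocations": int(self.n_cnn_invocations),
            "gate_positive_windows": int(self.gate_positive_windows),
            "duty_cycle": float(self.duty_cycle),
        }


def gate_step(decision_positive: bool, state: GateState, gate_threshold: int):
    """Advance the consecutive-positive counter; returns (event?, state).

    A positive decision increments the counter; a negative one resets it.
    An event fires when the counter reaches ``gate_threshold`` (the counter
    then resets so overlapping runs raise one event per full run).
    """
    if decision_positive:
        state.consecutive_positives += 1
        if state.consecutive_positives >= gate_threshold:
            state.consecutive_positives = 0
            return True, state
    else:
        state.consecutive_positives = 0
    return False, state


def verify_event(cnn, window) -> bool:
    """Verifier decision on the window that completed the event."""
    return bool(_predict_one(cnn, window) == 1)


class AlwaysPositiveVerifier:
    """Degenerate verifier confirming every event (gate-only metrics)."""

    def predict(self, X):
        return np.ones(len(X), dtype=np.int64)


def _predict_one(model, window) -> int:
    pred = model.predict(np.asarray(window)[None, :, :])
    return int(pred[0])


def run_cascade(bnn, cnn, stream, cfg: CascadeConfig) -> AlarmTrace:
    """Stream (time, window) pairs through the gate→verifier cascade.

    ``stream`` is an iterable of (start_time_s, window) in increasing time
    order (a :class:`~preictal.windowing.WindowDataset` can be adapted via
    :func:`dataset_stream`).  ``bnn`` and ``cnn`` expose ``predict`` on a
    batch of windows with positive class 1.  Deterministic given inputs.
    """
    items = list(stream)
    times = [t for t, _w in items]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("cascade stream must be in increasing time order")

    trace = AlarmTrace()
    state = GateState()
    # gate decisions are independent of alarm state: batch them for speed
    if items:
        windows = np.stack([w for _t, w in items])
        gate_pos = np.asarray(bnn.predict(windows)) == 1
    else:
        gate_pos = np.zeros(0, dtype=bool)

    last_alarm_t = -np.inf
    for (t, window), positive in zip(items, gate_pos):
        trace.n_windows_total += 1
        trace.gate_positive_windows += int(positive)
        event, state = gate_step(bool(positive), state, cfg.gate_threshold)
        if not event:
            continue
        trace.gate_events.append(float(t))
        if t - last_alarm_t < cfg.refractory_s:
            continue  # inside refractory: verifier stays asleep
        trace.n_cnn_invocations += 1
        if verify_event(cnn, window):
            trace.confirmed_alarms.append(float(t))
            last_alarm_t = t
    return trace


def dataset_stream(ds):
    """Adapt a WindowDataset into a time-ordered (start_s, window) stream."""
    order = sorted(range(len(ds)), key=lambda i: (ds.origin[i][0], ds.origin[i][1]))
    for i in order:
        yield ds.origin[i][1], ds.windows[i]
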