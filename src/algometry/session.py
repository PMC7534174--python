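"""Test orchestration: run a protocol over a sample source and summarize.

A *sample source* is anything pull-based that yields timestamped
(force, eVAS, trigger) samples at a declared sampling frequency — the
bundled simulator, a CSV replay, or a future DAQ adapter.  The runner zeroes
the baseline from a pre-task window, converts voltage to force when the
source yields volts, detects debounced trigger events, flags safety-limit
crossings (the limit is guidance, not a hard stop), computes per-cycle
impulses for trains, and aggregates repetitions into a session summary
(mean peak force, mean first-trigger force).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol as _Protocol, runtime_checkable

import numpy as np

from .calibration import GaugeSpec, volts_to_force, zero_baseline
from .guideline import TimeSeries, ascending_pathway, train_guided_duration
from .impulse import numeric_impulse, segment_cycles
from .protocol import AscendingProtocol, TrainProtocol

#: Default debounce window for the momentary trigger button, seconds
#: (one sample at the 20 Hz default rate).
DEFAULT_DEBOUNCE = 0.05

#: Trigger-channel voltages above this fraction of the button supply count
#: as pressed (normally-open momentary switch).
TRIGGER_THRESHOLD_FRACTION = 0.5


@dataclass(frozen=True)
class Sample:
    """One timestamped multi-channel reading."""

    t: float
    force: float
    evas: float
    trigger: bool

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"sample time must be >= 0, got {self.t}")
        if not 0 <= self.evas <= 100:
            raise ValueError(f"eVAS must lie in [0, 100], got {self.evas}")


@dataclass(frozen=True)
class SampleStream:
    """Uniformly sampled force / eVAS / trigger recording."""

    times: np.ndarray
    force: np.ndarray
    evas: np.ndarray
    trigger: np.ndarray  # boolean pressed state

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "force", np.asarray(self.force, dtype=float))
        object.__setattr__(self, "evas", np.asarray(self.evas, dtype=float))
        object.__setattr__(self, "trigger", np.asarray(self.trigger, dtype=bool))
        n = self.times.size
        for name in ("force", "evas", "trigger"):
            if getattr(self, name).size != n:
                raise ValueError(f"channel {name!r} length mismatch")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def dt(self) -> float:
        if len(self) < 2:
            raise ValueError("dt undefined for fewer than two samples")
        return float(self.times[1] - self.times[0])

    def to_timeseries(self) -> TimeSeries:
        return TimeSeries(
            times=self.times,
            channels={"force": self.force, "evas": self.evas, "trigger": self.trigger},
        )

    @classmethod
    def from_samples(cls, samples: list[Sample]) -> "SampleStream":
        return cls(
            times=np.array([s.t for s in samples]),
            force=np.array([s.force for s in samples]),
            evas=np.array([s.evas for s in samples]),
            trigger=np.array([s.trigger for s in samples]),
        )


@runtime_checkable
class SampleSource(_Protocol):
    """Pull-based sample-provider contract.

    ``next_sample()`` returns the next :class:`Sample` or ``None`` at end of
    stream.  ``units`` is ``"newtons"`` or ``"volts"`` for the force channel;
    sources may expose ``pre_task_forces`` (an array of force readings taken
    before task start) for baseline zeroing.
    """

    sampling_frequency: float
    units: str

    def next_sample(self) -> Sample | None: ...


@dataclass(frozen=True)
class TriggerEvent:
    """A debounced press of the participant's momentary trigger button."""

    ordinal: int
    t: float
    force_at_event: float
    evas_at_event: float


@dataclass
class TestResult:
    """Outcome of one test repetition."""

    repetition_index: int
    baseline_force: float
    peak_force: float
    peak_time: float
    trigger_events: list[TriggerEvent]
    per_cycle_impulses: list[float]
    limit_exceeded: bool
    limit_first_time: float | None
    stream: SampleStream
    notes: str = ""


@dataclass(frozen=True)
class SessionSummary:
    """Cross-repetition aggregation of a test series at one site."""

    n_repetitions: int
    mean_peak_force: float
    mean_first_trigger_force: float | None
    n_first_triggers: int
    peak_forces: tuple[float, ...]
    first_trigger_forces: tuple[float, ...]


def trigger_states_from_voltage(voltages, supply_voltage: float) -> np.ndarray:
    """Map raw trigger-channel voltage to pressed/released (> 50% of supply)."""
    v = np.asarray(voltages, dtype=float)
    return v > TRIGGER_THRESHOLD_FRACTION * supply_voltage


def detect_trigger_events(
    stream: SampleStream, debounce: float = DEFAULT_DEBOUNCE
) -> list[TriggerEvent]:
    """One event per released-to-pressed transition, debounced.

    Transitions within ``debounce`` seconds of the previous *accepted* event
    are ignored (contact bounce of the momentary switch).  Event force and
    eVAS are the sample values at the transition sample.
    """
    pressed = stream.trigger
    if len(stream) == 0:
        return []
    prev = np.concatenate(([False], pressed[:-1]))
    edges = np.flatnonzero(pressed & ~prev)
    events: list[TriggerEvent] = []
    last_t = -np.inf
    for i in edges:
        t = float(stream.times[i])
        if t - last_t <= debounce:
            continue
        events.append(
            TriggerEvent(
                ordinal=len(events) + 1,
                t=t,
                force_at_event=float(stream.force[i]),
                evas_at_event=float(stream.evas[i]),
            )
        )
        last_t = t
    return events


def peak_force(stream: SampleStream) -> tuple[float, float]:
    """(time, force) of the maximum force; first occurrence on ties."""
    if len(stream) == 0:
        raise ValueError("peak_force requires a non-empty stream")
    i = int(np.argmax(stream.force))
    return float(stream.times[i]), float(stream.force[i])


def safety_check(
    stream: SampleStream, limit: float
) -> tuple[bool, float | None]:
    """Whether any sample force strictly exceeds the limit, and when first.

    The limit flags rather than stops: it is advanced notice to the tester,
    not a hard cutoff, so recording always continues.
    """
    if not limit > 0:
        raise ValueError(f"limit must be > 0, got {limit!r}")
    over = np.flatnonzero(stream.force > limit)
    if over.size == 0:
        return False, None
    return True, float(stream.times[over[0]])


def guided_duration(protocol) -> float:
    """Length of the guided portion of one repetition, seconds."""
    if isinstance(protocol, AscendingProtocol):
        return ascending_pathway(protocol).end
    if isinstance(protocol, TrainProtocol):
        return train_guided_duration(protocol)
    raise TypeError(f"no guided duration for {type(protocol).__name__}")


def run_test(
    protocol,
    source: SampleSource,
    gauge: GaugeSpec | None = None,
    repetition_index: int = 0,
    debounce: float = DEFAULT_DEBOUNCE,
    remote_start: bool = False,
    stop_at_trigger_ordinal: int | None = None,
) -> TestResult:
    """Run one repetition of a protocol over a pull-based sample source.

    The baseline is zeroed from the source's pre-task window when it exposes
    one.  When the source yields volts, a ``gauge`` is required and readings
    are converted before baseline subtraction.  With ``remote_start``, an
    initial trigger press is consumed as the start signal (the task clock is
    shifted to that sample and no event is emitted for it).  An optional
    early-stop ends acquisition once the participant's Nth trigger has been
    seen (e.g. stop at pain tolerance).
    """
    fs = source.sampling_frequency
    dt = 1.0 / fs
    duration = guided_duration(protocol)
    units = getattr(source, "units", "newtons")
    if units == "volts" and gauge is None:
        raise ValueError("a GaugeSpec is required when the source yields volts")

    def to_newtons(value: float) -> float:
        return volts_to_force(value, gauge) if units == "volts" else value

    pre = getattr(source, "pre_task_forces", None)
    baseline = (
        zero_baseline([to_newtons(v) for v in np.asarray(pre, dtype=float)])
        if pre is not None and len(pre) > 0
        else 0.0
    )

    samples: list[Sample] = []
    notes = ""
    t0: float | None = None if remote_start else 0.0
    n_expected = int(round(duration * fs)) + 1
    n_triggers_seen = 0
    prev_pressed = False
    while True:
        raw = source.next_sample()
        if raw is None:
            if len(samples) < n_expected:
                notes = (
                    f"source exhausted after {len(samples)} of {n_expected} "
                    "samples (truncated before the guided duration elapsed)"
                )
            break
        if t0 is None:
            if not raw.trigger:
                continue  # waiting for the remote-start press
            t0 = raw.t
            # the start press is a control signal, not a response
            raw = Sample(t=raw.t, force=raw.force, evas=raw.evas, trigger=False)
        t = raw.t - t0
        samples.append(
            Sample(
                t=t,
                force=to_newtons(raw.force) - baseline,
                evas=raw.evas,
                trigger=raw.trigger,
            )
        )
        if raw.trigger and not prev_pressed:
            n_triggers_seen += 1
            if (
                stop_at_trigger_ordinal is not None
                and n_triggers_seen >= stop_at_trigger_ordinal
            ):
                notes = f"stopped at trigger ordinal {stop_at_trigger_ordinal}"
                break
        prev_pressed = raw.trigger
        if t >= duration - dt / 2:
            break

    if not samples:
        raise ValueError("source yielded no samples")
    stream = SampleStream.from_samples(samples)
    pk_t, pk_f = peak_force(stream)
    events = detect_trigger_events(stream, debounce=debounce)
    limit = getattr(protocol, "safety_limit", None)
    exceeded, first_time = (
        safety_check(stream, limit) if limit is not None else (False, None)
    )
    impulses: list[float] = []
    if isinstance(protocol, TrainProtocol) and not notes.startswith("source exhausted"):
        windows = segment_cycles(stream.to_timeseries(), protocol)
        impulses = numeric_impulse(stream.to_timeseries(), 0.0, windows)
    return TestResult(
        repetition_index=repetition_index,
        baseline_force=baseline,
        peak_force=pk_f,
        peak_time=pk_t,
        trigger_events=events,
        per_cycle_impulses=impulses,
        limit_exceeded=exceeded,
        limit_first_time=first_time,
        stream=stream,
        notes=notes,
    )


def summarize_session(results: list[TestResult]) -> SessionSummary:
    """Mean peak force and mean first-trigger force across repetitions.

    Repetitions without trigger events are excluded from the first-trigger
    mean; the count of contributing repetitions is reported.
    """
    if not results:
        raise ValueError("summarize_session requires at least one TestResult")
    peaks = tuple(r.peak_force for r in results)
    firsts = tuple(
        r.trigger_events[0].force_at_event for r in results if r.trigger_events
    )
    return SessionSummary(
        n_repetitions=len(results),
        mean_peak_force=float(np.mean(peaks)),
        mean_first_trigger_force=float(np.mean(firsts)) if firsts else None,
        n_first_triggers=len(firsts),
        peak_forces=peaks,
        first_trigger_forces=firsts,
    )
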