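"""Trigger detection, peaks, safety checks, the runner and session summaries."""

import numpy as np
import pytest

from algometry import (
    AscendingProtocol,
    GaugeSpec,
    OperatorModel,
    Sample,
    SampleStream,
    SimulatedSource,
    SubjectModel,
    detect_trigger_events,
    individualize_train,
    peak_force,
    run_test,
    safety_check,
    summarize_session,
)
from algometry.session import trigger_states_from_voltage


def make_stream(trigger, fs=20.0, force=None, evas=None):
    n = len(trigger)
    return SampleStream(
        times=np.arange(n) / fs,
        force=np.arange(n, dtype=float) if force is None else force,
        evas=np.zeros(n) if evas is None else evas,
        trigger=np.asarray(trigger, dtype=bool),
    )


def test_detect_trigger_events_rising_edges():
    stream = make_stream([0, 0, 1, 1, 0, 0, 1])
    events = detect_trigger_events(stream)
    assert [e.ordinal for e in events] == [1, 2]
    assert [e.t for e in events] == pytest.approx([0.10, 0.30])
    assert events[0].force_at_event == pytest.approx(2.0)


def test_detect_trigger_events_empty():
    assert detect_trigger_events(make_stream([0, 0, 0, 0])) == []


def test_detect_trigger_events_debounces_contact_bounce():
    # bounce pattern 0,1,0,1 inside 0.05 s at 100 Hz collapses to one event
    stream = make_stream([0, 1, 0, 1, 0], fs=100.0)
    events = detect_trigger_events(stream, debounce=0.05)
    assert len(events) == 1


def test_trigger_events_time_ordered_and_spaced():
    rng = np.random.default_rng(11)
    stream = make_stream(rng.integers(0, 2, size=400), fs=100.0)
    events = detect_trigger_events(stream, debounce=0.05)
    times = [e.t for e in events]
    assert all(b - a > 0.05 for a, b in zip(times, times[1:]))
    assert [e.ordinal for e in events] == list(range(1, len(events) + 1))


def test_trigger_voltage_thresholding():
    states = trigger_states_from_voltage([0.0, 2.4, 2.6, 5.0], supply_voltage=5.0)
    assert states.tolist() == [False, False, True, True]


def test_peak_force_first_occurrence():
    stream = make_stream([0] * 7, force=np.array([0, 50, 100, 100, 100, 30, 0.0]))
    t, f = peak_force(stream)
    assert (t, f) == (pytest.approx(0.10), 100.0)


def test_peak_force_all_zero_and_empty():
    t, f = peak_force(make_stream([0, 0], force=np.zeros(2)))
    assert (t, f) == (0.0, 0.0)
    with pytest.raises(ValueError):
        peak_force(SampleStream(times=[], force=[], evas=[], trigger=[]))


def test_safety_check_below_and_above_limit():
    ramp = make_stream([0] * 160, force=np.arange(160) / 20.0 * 20.0)
    assert safety_check(ramp, 200.0) == (False, None)
    exceeded, first = safety_check(ramp, 150.0)
    # ramp reaches 150 N at 7.5 s; the first strictly-exceeding sample is next
    assert exceeded and first == pytest.approx(7.55)


def test_safety_check_tiny_limit():
    exceeded, first = safety_check(make_stream([0, 0, 0], force=np.array([0, 1, 2.0])), 0.1)
    assert exceeded and first == pytest.approx(0.05)


def test_run_test_ascending_simulated(ascending_20, ideal_operator, subject_80):
    source = SimulatedSource(ascending_20, ideal_operator, subject_80)
    result = run_test(ascending_20, source)
    assert len(result.stream) == 151
    assert result.peak_force == pytest.approx(150.0)
    assert result.trigger_events[0].force_at_event == pytest.approx(80.0, abs=1.0)
    assert not result.limit_exceeded  # the guideline stops at, not above, the limit


def test_run_test_train_noiseless_matches_closed_form(ideal_operator, subject_80, train_a):
    source = SimulatedSource(train_a, ideal_operator, subject_80)
    result = run_test(train_a, source)
    assert len(result.per_cycle_impulses) == 10
    tol = max(0.005 * 350.0, 100.0 * 0.05 / 4.0)
    for value in result.per_cycle_impulses:
        assert value == pytest.approx(350.0, abs=tol)


def test_run_test_converts_volts_with_gauge(ascending_20, ideal_operator, subject_80):
    gauge = GaugeSpec(2.0, 1000.0)  # 0.002 V/N

    class VoltSource:
        units = "volts"

        def __init__(self, inner):
            self.inner = inner
            self.sampling_frequency = inner.sampling_frequency

        def next_sample(self):
            s = self.inner.next_sample()
            if s is None:
                return None
            return Sample(t=s.t, force=s.force * 0.002, evas=s.evas, trigger=s.trigger)

    source = VoltSource(SimulatedSource(ascending_20, ideal_operator, subject_80))
    result = run_test(ascending_20, source, gauge=gauge)
    assert result.peak_force == pytest.approx(150.0)
    with pytest.raises(ValueError, match="GaugeSpec"):
        run_test(ascending_20, VoltSource(
            SimulatedSource(ascending_20, ideal_operator, subject_80)))


def test_run_test_zeroes_baseline(ascending_20, ideal_operator, subject_80):
    source = SimulatedSource(ascending_20, ideal_operator, subject_80)
    source.pre_task_forces = np.full(10, 2.5)  # resting preload
    result = run_test(ascending_20, source)
    assert result.baseline_force == pytest.approx(2.5)
    assert result.peak_force == pytest.approx(150.0 - 2.5)


def test_run_test_remote_start(ascending_20):
    fs = 20.0

    class RemoteStartSource:
        units = "newtons"
        sampling_frequency = fs

        def __init__(self):
            n = 160
            press = np.zeros(n, dtype=bool)
            press[4] = True  # start signal 0.2 s in
            self.samples = [
                Sample(t=i / fs, force=max(0.0, (i - 4) / fs * 20.0),
                       evas=0.0, trigger=bool(press[i]))
                for i in range(n)
            ]

        def next_sample(self):
            return self.samples.pop(0) if self.samples else None

    result = run_test(ascending_20, RemoteStartSource(), remote_start=True)
    assert result.stream.times[0] == pytest.approx(0.0)
    assert result.trigger_events == []  # the start press is not a response


def test_run_test_truncated_source_noted(ascending_20, ideal_operator, subject_80):
    class EarlyStop:
        units = "newtons"

        def __init__(self, inner, stop_t):
            self.inner, self.stop_t = inner, stop_t
            self.sampling_frequency = inner.sampling_frequency

        def next_sample(self):
            s = self.inner.next_sample()
            return None if s is None or s.t > self.stop_t else s

    # participant withdraws 4 s into a 7.5 s ramp
    source = EarlyStop(SimulatedSource(ascending_20, ideal_operator, subject_80), 4.0)
    result = run_test(ascending_20, source)
    assert "exhausted" in result.notes
    assert result.peak_force < 150.0


def test_summarize_session_means(ascending_20, ideal_operator, subject_80):
    results = [
        run_test(ascending_20, SimulatedSource(ascending_20, ideal_operator, subject_80),
                 repetition_index=i)
        for i in range(3)
    ]
    summary = summarize_session(results)
    assert summary.n_repetitions == 3
    assert summary.mean_peak_force == pytest.approx(results[0].peak_force)
    assert summary.mean_first_trigger_force == pytest.approx(
        results[0].trigger_events[0].force_at_event
    )


def test_summarize_session_partial_triggers(ascending_20, ideal_operator, subject_80):
    results = [
        run_test(ascending_20, SimulatedSource(ascending_20, ideal_operator, subject_80),
                 repetition_index=i)
        for i in range(3)
    ]
    results[1].trigger_events = []
    summary = summarize_session(results)
    assert summary.n_first_triggers == 2
    assert summary.mean_first_trigger_force == pytest.approx(
        results[0].trigger_events[0].force_at_event
    )
    with pytest.raises(ValueError):
        summarize_session([])


def test_noiseless_first_trigger_within_one_sample_increment(ascending_20):
    """Zero lag and reaction: first-trigger force equals the threshold to
    within one sample's force increment (rate / fs)."""
    subject = SubjectModel(detection_threshold=83.3, pain_threshold=83.3,
                           tolerance_threshold=83.3, reaction_time=0.0)
    operator = OperatorModel(tracking_time_constant=0.0, noise_sd=0.0)
    result = run_test(ascending_20, SimulatedSource(ascending_20, operator, subject))
    increment = ascending_20.loading_rate / 20.0
    assert result.trigger_events[0].force_at_event == pytest.approx(83.3, abs=increment)
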