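"""Virtual operator and subject: hardware-free session generation.

The *operator* tracks the guideline with a first-order lag plus white noise
— the simplest tracking model with a closed-form ramp response (steady-state
deficit tau * rate below a ramp), which makes it usable as a test oracle.
The *subject* holds detection, pain and tolerance thresholds; each threshold
produces a one-sample trigger press at its first upward crossing, delayed by
a reaction time rounded to the nearest sample.  Continuous pain rating
(eVAS, 0-100) rises linearly above the pain threshold and saturates at 100
— a declared simulation assumption, not a psychophysical claim.

Operator and subject randomness come from independent seeded streams so
either can be held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import AcquisitionConfig
from .guideline import Pathway, TimeSeries, pathway_for, sample_pathway
from .session import Sample, SampleStream


@dataclass(frozen=True)
class OperatorModel:
    """First-order-lag tracking of the guideline with additive white noise.

    tracking_time_constant : float
        Lag tau in seconds; 0 means exact tracking (plus noise).
    noise_sd : float
        Standard deviation of the per-sample Gaussian disturbance, newtons.
    seed : int
        Seed of the operator's private random stream.
    """

    tracking_time_constant: float = 0.2
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tracking_time_constant < 0:
            raise ValueError("tracking_time_constant must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SubjectModel:
    """Threshold set and response dynamics of the virtual participant.

    Thresholds are ordered detection <= pain <= tolerance (newtons of
    applied force).  ``reaction_time`` lags every button press; the press
    itself lasts one sample (momentary switch).  ``evas_slope`` is the
    continuous rating gain in units per newton above the pain threshold.
    """

    detection_threshold: float
    pain_threshold: float
    tolerance_threshold: float
    reaction_time: float = 0.0
    evas_slope: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (
            0 <= self.detection_threshold
            <= self.pain_threshold
            <= self.tolerance_threshold
        ):
            raise ValueError(
                "thresholds must satisfy 0 <= detection <= pain <= tolerance, got "
                f"({self.detection_threshold}, {self.pain_threshold}, "
                f"{self.tolerance_threshold})"
            )
        if self.reaction_time < 0:
            raise ValueError("reaction_time must be >= 0")
        if self.evas_slope < 0:
            raise ValueError("evas_slope must be >= 0")

    @property
    def thresholds(self) -> tuple[float, ...]:
        return (
            self.detection_threshold,
            self.pain_threshold,
            self.tolerance_threshold,
        )


def simulate_operator_trace(
    pathway: Pathway, model: OperatorModel, fs: float
) -> TimeSeries:
    """Force trace of an operator tracking the guideline.

    With tau > 0:  F[i+1] = F[i] + (dt/tau) * (G(t_i) - F[i]) + eps_i,
    eps_i ~ N(0, noise_sd); F[0] = G(0).  tau = 0 degenerates to exact
    tracking plus noise.  Forces are clipped at 0 (the probe cannot pull).
    """
    acq = AcquisitionConfig(sampling_frequency=fs)
    guide = sample_pathway(pathway, acq)
    g = guide["force"]
    n = g.size
    rng = np.random.default_rng(model.seed)
    eps = (
        rng.normal(0.0, model.noise_sd, size=n)
        if model.noise_sd > 0
        else np.zeros(n)
    )
    tau = model.tracking_time_constant
    dt = 1.0 / fs
    if tau == 0:
        force = g + eps
    else:
        # a lag shorter than one sample is indistinguishable from exact
        # tracking at this rate; clamping also keeps the update stable
        alpha = min(dt / tau, 1.0)
        force = np.empty(n)
        force[0] = g[0]
        for i in range(n - 1):
            force[i + 1] = force[i] + alpha * (g[i] - force[i]) + eps[i]
    return TimeSeries(times=guide.times, channels={"force": np.maximum(force, 0.0)})


def simulate_subject_responses(
    force: TimeSeries, model: SubjectModel
) -> tuple[np.ndarray, np.ndarray]:
    """Trigger and eVAS channels evoked by a force trace.

    One one-sample press at the first upward crossing of each configured
    threshold, delayed by the reaction time rounded to the nearest sample;
    eVAS(t) = clip(evas_slope * (force(t) - pain_threshold), 0, 100).
    """
    f = np.asarray(force["force"], dtype=float)
    n = f.size
    fs = 1.0 / force.dt if n >= 2 else 1.0
    lag = int(round(model.reaction_time * fs))
    trigger = np.zeros(n, dtype=bool)
    for theta in model.thresholds:
        above = f >= theta
        crossings = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
        if crossings.size:
            i = crossings[0] + lag
            if i < n:
                trigger[i] = True
    evas = np.clip(model.evas_slope * (f - model.pain_threshold), 0.0, 100.0)
    return trigger, evas


def simulate_session_stream(
    protocol,
    operator: OperatorModel,
    subject: SubjectModel,
    pre_task_duration: float = 0.5,
) -> tuple[SampleStream, np.ndarray]:
    """Full multi-channel stream plus a pre-task baseline window.

    Composes guideline -> operator trace -> subject responses; deterministic
    given the two model seeds.  The pre-task window contains operator noise
    around zero force (the gauge resting before task start).
    """
    pathway = pathway_for(protocol)
    fs = protocol.acquisition.sampling_frequency
    trace = simulate_operator_trace(pathway, operator, fs)
    trigger, evas = simulate_subject_responses(trace, subject)
    stream = SampleStream(
        times=trace.times, force=trace["force"], evas=evas, trigger=trigger
    )
    n_pre = max(1, int(round(pre_task_duration * fs)))
    pre_rng = np.random.default_rng(np.random.SeedSequence((operator.seed, 1)))
    pre = (
        pre_rng.normal(0.0, operator.noise_sd, size=n_pre)
        if operator.noise_sd > 0
        else np.zeros(n_pre)
    )
    return stream, pre


class SimulatedSource:
    """Pull-based sample source over a simulated session stream.

    Satisfies the session module's source contract: declared sampling
    frequency, newton units, a pre-task force window for baseline zeroing,
    and ``next_sample()`` yielding samples in time order.
    """

    units = "newtons"

    def __init__(
        self,
        protocol,
        operator: OperatorModel,
        subject: SubjectModel,
        pre_task_duration: float = 0.5,
    ):
        self.sampling_frequency = protocol.acquisition.sampling_frequency
        stream, pre = simulate_session_stream(
            protocol, operator, subject, pre_task_duration
        )
        # pre-task readings sit on top of the (zero) resting force
        self.pre_task_forces = pre
        self._stream = stream
        self._i = 0

    def next_sample(self) -> Sample | None:
        if self._i >= len(self._stream):
            return None
        s = self._stream
        i = self._i
        self._i += 1
        return Sample(
            t=float(s.times[i]),
            force=float(s.force[i]),
            evas=float(s.evas[i]),
            trigger=bool(s.trigger[i]),
        )


def simulate_session(
    protocol,
    operator: OperatorModel,
    subject: SubjectModel,
    pre_task_duration: float = 0.5,
) -> SampleStream:
    """Convenience wrapper returning just the multi-channel stream."""
    stream, _ = simulate_session_stream(
        protocol, operator, subject, pre_task_duration
    )
    return stream
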