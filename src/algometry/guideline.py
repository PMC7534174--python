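"""Target force-time pathways and their sampling.

A *pathway* is the piecewise-linear guideline the operator is asked to
track: force as a function of time, fully defined by an ordered breakpoint
list with linear interpolation in between.  Ascending tests are a single
ramp terminating at the safety limit; trains are repeated trapezoids at the
cycle baseline in between.

An instantaneous descent (d = 0) is encoded as a vertical drop spanning half
of one sample interval so breakpoint times stay strictly increasing; its
force-time area (f * dt / 4) is negligible and absorbed by the numeric
integration tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import AcquisitionConfig
from .protocol import AscendingProtocol, TrainProtocol

#: Relative tolerance used when deciding whether the pathway end time lies
#: on the sampling grid.
_GRID_EPS = 1e-9


@dataclass(frozen=True)
class Pathway:
    """Piecewise-linear force-time guideline.

    Attributes
    ----------
    breakpoints : tuple of (time_s, force_N)
        Strictly increasing times starting at 0; linear interpolation
        between breakpoints fully defines the target.
    safety_limit : float | None
        When attached, no breakpoint force may exceed it.
    """

    breakpoints: tuple[tuple[float, float], ...]
    safety_limit: float | None = None

    def __post_init__(self) -> None:
        if len(self.breakpoints) < 2:
            raise ValueError("a Pathway needs at least two breakpoints")
        times = np.array([t for t, _ in self.breakpoints], dtype=float)
        forces = np.array([f for _, f in self.breakpoints], dtype=float)
        if times[0] != 0.0:
            raise ValueError(f"pathway must start at t = 0, got {times[0]}")
        if not np.all(np.diff(times) > 0):
            raise ValueError("breakpoint times must be strictly increasing")
        if np.any(forces < 0):
            raise ValueError("breakpoint forces must be >= 0")
        if self.safety_limit is not None and np.any(forces > self.safety_limit):
            raise ValueError(
                f"breakpoint force exceeds safety limit {self.safety_limit} N"
            )

    @property
    def end(self) -> float:
        """Time of the final breakpoint, seconds."""
        return self.breakpoints[-1][0]

    def __call__(self, t):
        """Target force at time(s) ``t`` by linear interpolation (clamped ends)."""
        times = [bp[0] for bp in self.breakpoints]
        forces = [bp[1] for bp in self.breakpoints]
        return np.interp(t, times, forces)


@dataclass(frozen=True)
class TimeSeries:
    """Uniformly sampled multi-channel recording."""

    times: np.ndarray
    channels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        channels = {k: np.asarray(v) for k, v in self.channels.items()}
        object.__setattr__(self, "channels", channels)
        if times.size >= 2:
            dts = np.diff(times)
            if not np.allclose(dts, dts[0], rtol=0, atol=1e-9):
                raise ValueError("TimeSeries requires a uniform time grid")
        for name, values in channels.items():
            if len(values) != times.size:
                raise ValueError(
                    f"channel {name!r} has {len(values)} samples for "
                    f"{times.size} timestamps"
                )

    @property
    def dt(self) -> float:
        if self.times.size < 2:
            raise ValueError("dt undefined for fewer than two samples")
        return float(self.times[1] - self.times[0])

    def __getitem__(self, channel: str) -> np.ndarray:
        return self.channels[channel]


@dataclass(frozen=True)
class FeedbackFrame:
    """Renderer-agnostic snapshot of the operator-guidance display state."""

    now: float
    target_force: float
    live_force: float
    tracking_error: float
    limit_line: float
    limit_exceeded: bool
    trigger_alert: bool


def ascending_pathway(protocol: AscendingProtocol) -> Pathway:
    """Linear ramp at the configured rate, terminating at the safety limit."""
    end = protocol.safety_limit / protocol.loading_rate
    return Pathway(
        breakpoints=((0.0, 0.0), (end, protocol.safety_limit)),
        safety_limit=protocol.safety_limit,
    )


def train_guided_duration(train: TrainProtocol) -> float:
    """Nominal guided duration n*(a+p+d) + (n-1)*isi, seconds."""
    c = train.cycle
    return train.n_stimuli * c.t + (train.n_stimuli - 1) * train.inter_stimulus_interval


def train_pathway(train: TrainProtocol) -> Pathway:
    """Guideline for a trapezoidal-cycle train.

    Cycle k starts at ``s_k = k * (a + p + d + isi)``: baseline at ``s_k``,
    ramp to f over a, hold for p, descend to baseline over d; the interval
    between cycles sits at the baseline force.  Instantaneous descents drop
    over half a sample interval (see module docstring).
    """
    from .protocol import validate_protocol

    violations = validate_protocol(train)
    if violations:
        raise ValueError("invalid train: " + "; ".join(violations))

    c = train.cycle
    isi = train.inter_stimulus_interval
    dt = train.acquisition.dt
    # instantaneous descent: vertical drop spanning half a sample interval,
    # centred on the nominal hold end when the hold is long enough, so that
    # trapezoidal quadrature through the drop reproduces the closed form
    # exactly for grid-aligned cycles
    drop = min(dt / 2.0, isi / 2.0) if isi > 0 else dt / 2.0

    bps: list[tuple[float, float]] = [(0.0, c.baseline)]
    for k in range(train.n_stimuli):
        s_k = k * (c.t + isi)
        if s_k > 0:
            bps.append((s_k, c.baseline))
        bps.append((s_k + c.a, c.f))
        if c.d > 0:
            if c.p > 0:
                bps.append((s_k + c.a + c.p, c.f))
            bps.append((s_k + c.a + c.p + c.d, c.baseline))
        elif c.p >= dt / 2.0:
            bps.append((s_k + c.a + c.p - drop / 2.0, c.f))
            bps.append((s_k + c.a + c.p + drop / 2.0, c.baseline))
        else:
            if c.p > 0:
                bps.append((s_k + c.a + c.p, c.f))
            bps.append((s_k + c.a + c.p + drop, c.baseline))
    # settle on the next grid point so the sampled trace covers the final drop
    end = bps[-1][0]
    grid_end = np.ceil(end * train.acquisition.sampling_frequency - _GRID_EPS) * dt
    if grid_end > end:
        bps.append((grid_end, c.baseline))
    return Pathway(breakpoints=tuple(bps), safety_limit=train.safety_limit)


def pathway_for(protocol) -> Pathway:
    """Dispatch to the pathway constructor matching the protocol type."""
    if isinstance(protocol, AscendingProtocol):
        return ascending_pathway(protocol)
    if isinstance(protocol, TrainProtocol):
        return train_pathway(protocol)
    raise TypeError(f"no pathway construction for {type(protocol).__name__}")


def sample_pathway(pathway: Pathway, acquisition: AcquisitionConfig) -> TimeSeries:
    """Sample a pathway on the uniform acquisition grid covering [0, end].

    The grid includes t = 0, and includes the final breakpoint time when
    ``end * fs`` is integral to 1e-9; otherwise it stops at the last grid
    point strictly below the end.
    """
    fs = acquisition.sampling_frequency
    n_intervals = pathway.end * fs
    n_last = int(round(n_intervals))
    if abs(n_intervals - n_last) > _GRID_EPS * max(1.0, abs(n_intervals)):
        n_last = int(np.floor(n_intervals))
    times = np.arange(n_last + 1) / fs
    return TimeSeries(times=times, channels={"force": np.asarray(pathway(times))})


def feedback_frame(
    pathway: Pathway,
    now: float,
    live_force: float,
    safety_limit: float,
    trigger_active: bool = False,
) -> FeedbackFrame:
    """Snapshot of guidance state for an external renderer."""
    if now < 0:
        raise ValueError(f"now must be >= 0, got {now!r}")
    target = float(pathway(now))
    return FeedbackFrame(
        now=now,
        target_force=target,
        live_force=live_force,
        tracking_error=live_force - target,
        limit_line=safety_limit,
        limit_exceeded=live_force > safety_limit,
        trigger_alert=bool(trigger_active),
    )


def export_pathway_csv(pathway: Pathway, acquisition: AcquisitionConfig, path) -> None:
    """Write the sampled pathway as two-column CSV (time_s, target_force_N)."""
    import pandas as pd

    ts = sample_pathway(pathway, acquisition)
    pd.DataFrame({"time_s": ts.times, "target_force_N": ts["force"]}).to_csv(
        path, index=False
    )
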