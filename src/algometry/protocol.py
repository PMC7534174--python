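"""Loading-protocol definitions and validation.

Two test modes are covered:

* **Ascending** — an uninterrupted linear ramp at a constant loading rate,
  terminated at a configured safety limit (ascending method of limits, used
  for pressure pain threshold testing).
* **Train** — a series of identical trapezoidal loading cycles (ascend to a
  peak force, hold, descend) separated by an inter-stimulus interval, used
  for temporal summation testing.

A trapezoidal cycle can be individualized to a participant's pressure pain
threshold in two distinct ways:

* ``fixed_durations`` — every phase keeps the same *time duration* for all
  participants; the ascending rate varies with peak force (Method 1).
* ``fixed_rates`` — the ascending (and optionally descending) *loading rate*
  is constant; phase durations vary with peak force (Method 2).

The two coincide only at the reference peak force; elsewhere they deliver
different impulses (see the impulse module).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .calibration import AcquisitionConfig

#: Default safety limit for ascending tests, newtons.
DEFAULT_SAFETY_LIMIT = 150.0
#: Worked-example train defaults: stimuli per train / peak hold / ISI.
DEFAULT_N_STIMULI = 10
DEFAULT_PEAK_DURATION = 1.0
DEFAULT_ISI = 2.0


class Instantaneous:
    """Sentinel for an instantaneous (zero-duration) descending phase.

    Used in place of a finite descending rate; avoids non-finite arithmetic
    for the vertical drop case where the descending force-time area is
    negligible by construction.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "INSTANTANEOUS"


INSTANTANEOUS = Instantaneous()


@dataclass(frozen=True)
class CycleSpec:
    """One trapezoidal loading cycle.

    Attributes
    ----------
    f : float
        Target peak force, newtons.
    a : float
        Ascending-phase duration, seconds (> 0).
    p : float
        Peak-phase (hold) duration, seconds (0 makes the hold instantaneous,
        reducing the trapezoid to a triangle).
    d : float
        Descending-phase duration, seconds; 0 encodes an instantaneous
        descent with negligible force-time area.
    baseline : float
        Inter-cycle baseline force, newtons; need not be zero when cycles
        repeat without full unloading.
    """

    f: float
    a: float
    p: float
    d: float
    baseline: float = 0.0

    def __post_init__(self) -> None:
        violations = validate_cycle(self)
        if violations:
            raise ValueError("invalid CycleSpec: " + "; ".join(violations))

    @property
    def t(self) -> float:
        """Total cycle duration a + p + d, seconds."""
        return self.a + self.p + self.d

    @property
    def r_a(self) -> float:
        """Ascending loading rate f / a, N/s."""
        return self.f / self.a

    @property
    def r_d(self) -> float | Instantaneous:
        """Descending rate f / d, N/s; INSTANTANEOUS when d == 0."""
        if self.d == 0:
            return INSTANTANEOUS
        return self.f / self.d


def validate_cycle(cycle: CycleSpec) -> list[str]:
    """Human-readable invariant violations for a cycle; empty when valid."""
    v: list[str] = []
    if not cycle.baseline >= 0:
        v.append(f"baseline must be >= 0 (got {cycle.baseline})")
    if not cycle.f > cycle.baseline:
        v.append(f"peak force f must exceed baseline (f={cycle.f}, baseline={cycle.baseline})")
    if not cycle.a > 0:
        v.append(f"ascending duration a must be > 0 (got {cycle.a})")
    if not cycle.p >= 0:
        v.append(f"peak duration p must be >= 0 (got {cycle.p})")
    if not cycle.d >= 0:
        v.append(f"descending duration d must be >= 0 (got {cycle.d})")
    return v


def make_cycle_fixed_durations(
    f: float, a: float, p: float, d: float, baseline: float = 0.0
) -> CycleSpec:
    """Cycle with constant phase *durations* (Method 1); rates derive as f/a, f/d."""
    return CycleSpec(f=f, a=a, p=p, d=d, baseline=baseline)


def make_cycle_fixed_rates(
    f: float,
    r_a: float,
    p: float,
    r_d: float | Instantaneous = INSTANTANEOUS,
    baseline: float = 0.0,
) -> CycleSpec:
    """Cycle with constant loading *rates* (Method 2); durations derive as f/r.

    ``r_d`` may be the :data:`INSTANTANEOUS` sentinel (or ``None``) for a
    vertical descent with negligible area.
    """
    violations: list[str] = []
    if not f > 0:
        violations.append(f"peak force f must be > 0 (got {f})")
    if not r_a > 0:
        violations.append(f"ascending rate r_a must be > 0 (got {r_a})")
    instantaneous = r_d is None or isinstance(r_d, Instantaneous)
    if not instantaneous and not r_d > 0:
        violations.append(f"descending rate r_d must be > 0 or INSTANTANEOUS (got {r_d})")
    if violations:
        raise ValueError("invalid rate parameters: " + "; ".join(violations))
    a = f / r_a
    d = 0.0 if instantaneous else f / r_d
    return CycleSpec(f=f, a=a, p=p, d=d, baseline=baseline)


@dataclass(frozen=True)
class AscendingProtocol:
    """Uninterrupted linear ramp test (ascending method of limits)."""

    loading_rate: float
    safety_limit: float = DEFAULT_SAFETY_LIMIT
    n_repetitions: int = 1
    inter_test_interval: float = 0.0
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)

    def __post_init__(self) -> None:
        violations = validate_protocol(self)
        if violations:
            raise ValueError("invalid AscendingProtocol: " + "; ".join(violations))


@dataclass(frozen=True)
class TrainProtocol:
    """Train of identical trapezoidal cycles separated by an inter-stimulus interval.

    The inter-stimulus interval is measured end-of-descent to start of the
    next ascent (end-to-start convention).
    """

    cycle: CycleSpec
    n_stimuli: int = DEFAULT_N_STIMULI
    inter_stimulus_interval: float = DEFAULT_ISI
    safety_limit: float = DEFAULT_SAFETY_LIMIT
    n_repetitions: int = 1
    inter_test_interval: float = 0.0
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)

    def __post_init__(self) -> None:
        if not self.n_stimuli >= 1:
            raise ValueError(f"n_stimuli must be >= 1, got {self.n_stimuli}")
        if not self.inter_stimulus_interval >= 0:
            raise ValueError(
                f"inter_stimulus_interval must be >= 0, got {self.inter_stimulus_interval}"
            )


def individualize_train(
    ppt: float,
    method: str,
    phase_params: dict,
    n_stimuli: int = DEFAULT_N_STIMULI,
    isi: float = DEFAULT_ISI,
    acquisition: AcquisitionConfig | None = None,
    safety_limit: float = DEFAULT_SAFETY_LIMIT,
) -> TrainProtocol:
    """Build a temporal-summation train whose peak force is a measured threshold.

    Parameters
    ----------
    ppt : float
        The participant's pressure pain threshold, newtons; becomes the
        target peak force of every cycle in the train.
    method : {"fixed_durations", "fixed_rates"}
        Individualization method: constant phase durations (Method 1) or
        constant loading rates (Method 2).
    phase_params : dict
        For ``fixed_durations``: keys ``a``, ``p``, ``d`` (seconds).
        For ``fixed_rates``: keys ``r_a`` (N/s), ``p`` (s) and optionally
        ``r_d`` (N/s or INSTANTANEOUS/None, default instantaneous).
    n_stimuli, isi
        Train length and end-to-start inter-stimulus interval; defaults are
        the worked-example values (10 stimuli, 2 s).
    """
    if not ppt > 0:
        raise ValueError(f"ppt must be > 0, got {ppt!r}")
    params = dict(phase_params)
    if method == "fixed_durations":
        required = {"a", "p", "d"}
        missing = required - params.keys()
        if missing:
            raise ValueError(
                f"fixed_durations requires phase params {sorted(required)}; "
                f"missing {sorted(missing)}"
            )
        cycle = make_cycle_fixed_durations(
            ppt, params["a"], params["p"], params["d"],
            baseline=params.get("baseline", 0.0),
        )
    elif method == "fixed_rates":
        required = {"r_a", "p"}
        missing = required - params.keys()
        if missing:
            raise ValueError(
                f"fixed_rates requires phase params {sorted(required)}; "
                f"missing {sorted(missing)}"
            )
        cycle = make_cycle_fixed_rates(
            ppt, params["r_a"], params["p"], params.get("r_d", INSTANTANEOUS),
            baseline=params.get("baseline", 0.0),
        )
    else:
        raise ValueError(
            f"method must be 'fixed_durations' or 'fixed_rates', got {method!r}"
        )
    kwargs = {}
    if acquisition is not None:
        kwargs["acquisition"] = acquisition
    return TrainProtocol(
        cycle=cycle,
        n_stimuli=n_stimuli,
        inter_stimulus_interval=isi,
        safety_limit=safety_limit,
        **kwargs,
    )


def validate_protocol(protocol) -> list[str]:
    """Collect human-readable violations for a protocol; empty when valid.

    Violations are returned as data rather than raised, so that a user
    interface can present all of them at once.
    """
    v: list[str] = []
    if isinstance(protocol, AscendingProtocol):
        if not protocol.loading_rate > 0:
            v.append(f"loading rate must be > 0 (got {protocol.loading_rate})")
        if not protocol.safety_limit > 0:
            v.append(f"safety limit must be > 0 (got {protocol.safety_limit})")
        if not protocol.n_repetitions >= 1:
            v.append(f"n_repetitions must be >= 1 (got {protocol.n_repetitions})")
        if not protocol.inter_test_interval >= 0:
            v.append(
                f"inter_test_interval must be >= 0 (got {protocol.inter_test_interval})"
            )
    elif isinstance(protocol, TrainProtocol):
        v.extend(validate_cycle(protocol.cycle))
        if protocol.cycle.f > protocol.safety_limit:
            v.append(
                f"peak force exceeds safety limit "
                f"({protocol.cycle.f} N > {protocol.safety_limit} N)"
            )
        if (
            protocol.cycle.d == 0
            and protocol.n_stimuli > 1
            and not protocol.inter_stimulus_interval > 0
        ):
            v.append(
                "instantaneous descent in a multi-cycle train requires a "
                "positive inter-stimulus interval"
            )
    elif isinstance(protocol, CycleSpec):
        v.extend(validate_cycle(protocol))
    else:
        v.append(f"unknown protocol type {type(protocol).__name__}")
    return v
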