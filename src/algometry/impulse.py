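"""Impulse dosimetry: force-time area per loading cycle.

The impulse delivered by one trapezoidal loading cycle decomposes into a
triangular ascending area, a rectangular peak area and a triangular
descending area:

* constant phase durations (Method 1):
  ``f*a/2 + f*p + f*d/2 = f(a + 2p + d)/2`` — linear in peak force;
* constant loading rates (Method 2):
  ``f^2/(2 r_a) + f*p + f^2/(2 r_d)`` — ascending/descending areas grow
  with the *square* of peak force, because a higher peak also lengthens
  the phase.

The consequence for individualized temporal-summation testing: under
Method 2 a participant whose threshold is 10% higher receives ~17.9% more
impulse per cycle, and a 21% higher threshold receives ~39% more, so the
dose is no longer proportional to the individualization variable.

Numeric impulses from recorded traces use trapezoidal quadrature of the
baseline-subtracted force over per-cycle windows aligned to the guideline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .guideline import TimeSeries, train_guided_duration
from .protocol import INSTANTANEOUS, Instantaneous, TrainProtocol

#: Relative tolerance for closed-form vs quadrature agreement; the absolute
#: floor f*dt/4 absorbs the instantaneous-descent encoding (see guideline).
QUADRATURE_RTOL = 0.005


@dataclass(frozen=True)
class ImpulseBreakdown:
    """Per-phase impulse (N·s) of one loading cycle."""

    ascending: float
    peak: float
    descending: float
    cycle_duration: float

    def __post_init__(self) -> None:
        for name in ("ascending", "peak", "descending"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} impulse must be >= 0")

    @property
    def total(self) -> float:
        return self.ascending + self.peak + self.descending


def cycle_impulse_fixed_durations(
    f: float, a: float, p: float, d: float
) -> ImpulseBreakdown:
    """Closed-form impulse for constant phase durations: f(a + 2p + d)/2.

    ``f = 0`` is allowed as a degenerate query (zero impulse) even though it
    is not a constructible loading cycle.
    """
    if f < 0 or not a > 0 or p < 0 or d < 0:
        raise ValueError(f"invalid cycle parameters f={f}, a={a}, p={p}, d={d}")
    return ImpulseBreakdown(
        ascending=f * a / 2.0,
        peak=f * p,
        descending=f * d / 2.0,
        cycle_duration=a + p + d,
    )


def cycle_impulse_fixed_rates(
    f: float,
    r_a: float,
    p: float,
    r_d: float | Instantaneous | None = INSTANTANEOUS,
) -> ImpulseBreakdown:
    """Closed-form impulse for constant loading rates: f²/(2r_a) + f·p + f²/(2r_d).

    ``r_d`` may be INSTANTANEOUS (or None) for a vertical descent whose area
    is zero by construction.
    """
    if not f > 0:
        raise ValueError(f"peak force f must be > 0, got {f}")
    if not r_a > 0:
        raise ValueError(f"ascending rate r_a must be > 0, got {r_a}")
    instantaneous = r_d is None or isinstance(r_d, Instantaneous)
    if not instantaneous and not r_d > 0:
        raise ValueError(f"descending rate r_d must be > 0 or INSTANTANEOUS, got {r_d}")
    if not p >= 0:
        raise ValueError(f"peak duration p must be >= 0, got {p}")
    d = 0.0 if instantaneous else f / r_d
    return ImpulseBreakdown(
        ascending=f**2 / (2.0 * r_a),
        peak=f * p,
        descending=0.0 if instantaneous else f**2 / (2.0 * r_d),
        cycle_duration=f / r_a + p + d,
    )


def cycle_impulse(cycle) -> ImpulseBreakdown:
    """Closed-form impulse of a CycleSpec (areas above its baseline)."""
    h = cycle.f - cycle.baseline
    return ImpulseBreakdown(
        ascending=h * cycle.a / 2.0,
        peak=h * cycle.p,
        descending=h * cycle.d / 2.0,
        cycle_duration=cycle.t,
    )


def numeric_impulse(
    trace: TimeSeries,
    baseline: float,
    cycle_windows: list[tuple[float, float]],
    channel: str = "force",
) -> list[float]:
    """Trapezoidal quadrature of max(force − baseline, 0) per window, N·s."""
    times = trace.times
    force = np.asarray(trace[channel], dtype=float)
    span = (times[0], times[-1])
    out: list[float] = []
    for start, end in cycle_windows:
        if start < span[0] - 1e-9 or end > span[1] + 1e-9:
            raise ValueError(
                f"window ({start}, {end}) lies outside the trace span {span}"
            )
        mask = (times >= start - 1e-12) & (times <= end + 1e-12)
        y = np.maximum(force[mask] - baseline, 0.0)
        out.append(float(np.trapezoid(y, times[mask])))
    return out


def segment_cycles(
    trace: TimeSeries, train: TrainProtocol
) -> list[tuple[float, float]]:
    """Per-cycle integration windows aligned to the train guideline.

    Each window spans one cycle (start of ascent to end of descent), padded
    by one sample interval on each side and clipped to the trace span.
    """
    guided = train_guided_duration(train)
    if trace.times[-1] + 1e-9 < guided:
        raise ValueError(
            f"trace ends at {trace.times[-1]:.3f} s but the guided train "
            f"lasts {guided:.3f} s"
        )
    c = train.cycle
    dt = train.acquisition.dt
    span = (float(trace.times[0]), float(trace.times[-1]))
    windows = []
    for k in range(train.n_stimuli):
        s_k = k * (c.t + train.inter_stimulus_interval)
        start = max(span[0], s_k - dt)
        end = min(span[1], s_k + c.t + dt)
        windows.append((start, end))
    return windows


@dataclass(frozen=True)
class MethodComparison:
    """Per-participant impulse dosimetry under both individualization methods."""

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def __str__(self) -> str:
        return self.table.to_string(
            index=False, float_format=lambda x: f"{x:.3f}"
        )


def compare_methods(
    ppts: list[float],
    method1_params: dict,
    method2_params: dict,
    n_stimuli: int = 10,
    isi: float = 2.0,
    labels: list[str] | None = None,
) -> MethodComparison:
    """Tabulate impulse dosimetry for each participant under both methods.

    Parameters
    ----------
    ppts : list of float
        Pressure pain thresholds (target peak forces), newtons; the first
        entry is the reference participant.
    method1_params : dict
        Constant phase durations: keys ``a``, ``p``, ``d``.
    method2_params : dict
        Constant loading rates: keys ``r_a``, ``p``, optional ``r_d``.
    n_stimuli, isi
        Train structure shared by all participants.

    Returns
    -------
    MethodComparison
        One row per participant x method with per-cycle impulse, train
        totals, train duration, and percentage difference of total impulse
        against the reference participant.
    """
    if not ppts:
        raise ValueError("ppts must be non-empty; the first entry is the reference")
    if labels is None:
        labels = [chr(ord("A") + i) if i < 26 else f"P{i}" for i in range(len(ppts))]

    rows = []
    ref_totals: dict[str, float] = {}
    for method, params in (("fixed_durations", method1_params),
                           ("fixed_rates", method2_params)):
        for label, f in zip(labels, ppts):
            if method == "fixed_durations":
                br = cycle_impulse_fixed_durations(
                    f, params["a"], params["p"], params["d"]
                )
            else:
                br = cycle_impulse_fixed_rates(
                    f, params["r_a"], params["p"], params.get("r_d", INSTANTANEOUS)
                )
            train_total = n_stimuli * br.total
            train_duration = n_stimuli * br.cycle_duration + (n_stimuli - 1) * isi
            if label == labels[0]:
                ref_totals[method] = train_total
            rows.append(
                {
                    "participant": label,
                    "method": method,
                    "peak_force_N": f,
                    "cycle_impulse_Ns": br.total,
                    "ascending_Ns": br.ascending,
                    "peak_Ns": br.peak,
                    "descending_Ns": br.descending,
                    "cycle_duration_s": br.cycle_duration,
                    "train_impulse_Ns": train_total,
                    "train_duration_s": train_duration,
                    "pct_diff_vs_reference": 100.0
                    * (train_total - ref_totals[method])
                    / ref_totals[method],
                }
            )
    return MethodComparison(table=pd.DataFrame(rows))
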