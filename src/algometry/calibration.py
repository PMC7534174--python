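"""Load-cell calibration and unit arithmetic.

Digital force gauges transduce applied load into an analogue voltage that is
linear over the gauge's rated range.  The conversion factor (volts per
newton) is the rated voltage span divided by the rated force span; applied
force is recovered by inverting that factor and subtracting any recorded
task baseline.  Pressure follows from force and the contact-tip area, and
the Nyquist bound gives the minimum sampling rate for a stimulus-response
period of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Exact definition of the pound-force in newtons (NIST).
LBF_TO_N = 4.4482216152605

#: Default acquisition rate, Hz.  Comfortably above the ~13.33 Hz Nyquist
#: minimum implied by a 150 ms stimulus-response period.
DEFAULT_SAMPLING_FREQUENCY = 20.0

#: Default length of the pre-task window averaged when zeroing, seconds.
DEFAULT_ZERO_WINDOW = 0.5


def conversion_factor(voltage_range_total: float, force_range_total: float) -> float:
    """Volts-per-newton factor of a linear load cell.

    Parameters
    ----------
    voltage_range_total : float
        Full analogue output span of the gauge, volts (e.g. +/-1 V -> 2.0).
    force_range_total : float
        Full rated force span, newtons (e.g. +/-500 N -> 1000.0).

    Returns
    -------
    float
        ``voltage_range_total / force_range_total`` at full precision.
    """
    if not voltage_range_total > 0:
        raise ValueError(
            f"voltage_range_total must be > 0, got {voltage_range_total!r}"
        )
    if not force_range_total > 0:
        raise ValueError(f"force_range_total must be > 0, got {force_range_total!r}")
    return voltage_range_total / force_range_total


def pounds_force_to_newtons(value: float) -> float:
    """Convert pound-force to newtons; sign is preserved (tension/compression)."""
    if not np.isfinite(value):
        raise ValueError(f"value must be finite, got {value!r}")
    return value * LBF_TO_N


@dataclass(frozen=True)
class GaugeSpec:
    """Static description of a force gauge's transduction characteristics.

    Attributes
    ----------
    voltage_range_total : float
        Full analogue voltage span, volts.
    force_range_total : float
        Full rated force span, newtons.
    tip_contact_area : float | None
        Contact-tip area in cm^2, when a tip is fitted.
    """

    voltage_range_total: float
    force_range_total: float
    tip_contact_area: float | None = None

    def __post_init__(self) -> None:
        conversion_factor(self.voltage_range_total, self.force_range_total)
        if self.tip_contact_area is not None and not self.tip_contact_area > 0:
            raise ValueError(
                f"tip_contact_area must be > 0, got {self.tip_contact_area!r}"
            )

    @property
    def conversion_factor(self) -> float:
        """Volts per newton, derived from the two rated spans."""
        return self.voltage_range_total / self.force_range_total


@dataclass(frozen=True)
class AcquisitionConfig:
    """Sampling rate and channel layout of the multi-channel recording."""

    sampling_frequency: float = DEFAULT_SAMPLING_FREQUENCY
    channels: tuple[str, ...] = ("force", "evas", "trigger")

    def __post_init__(self) -> None:
        if not self.sampling_frequency > 0:
            raise ValueError(
                f"sampling_frequency must be > 0, got {self.sampling_frequency!r}"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError(f"channel names must be unique, got {self.channels!r}")

    @property
    def dt(self) -> float:
        """Sample interval, seconds."""
        return 1.0 / self.sampling_frequency


def volts_to_force(
    voltage: float, spec: GaugeSpec, baseline_force: float = 0.0
) -> float:
    """Invert the gauge's linear transduction and subtract a task baseline."""
    return voltage / spec.conversion_factor - baseline_force


def force_to_pressure(force: float, tip_contact_area: float) -> float:
    """Contact pressure in kPa for a force in newtons on an area in cm^2.

    Exact SI arithmetic: F / (A * 1e-4 m^2) Pa, divided by 1000.
    """
    if not tip_contact_area > 0:
        raise ValueError(f"tip_contact_area must be > 0, got {tip_contact_area!r}")
    return force / (tip_contact_area * 1e-4) / 1000.0


def zero_baseline(pre_task_samples) -> float:
    """Task baseline force: arithmetic mean of the pre-task force samples.

    The returned value is recorded with the task and subtracted from all
    subsequent readings, so that preparatory load and accessory weight
    (spacer, contact tip) do not contaminate the measurement.
    """
    samples = np.asarray(pre_task_samples, dtype=float)
    if samples.size == 0:
        raise ValueError("zero_baseline requires at least one pre-task sample")
    return float(samples.mean())


def min_sampling_frequency(stimulus_response_period: float) -> float:
    """Nyquist minimum sampling rate for a stimulus-response period in seconds.

    The fastest signal of interest has frequency ``1 / period``; sampling must
    exceed twice that, i.e. ``2 / period`` Hz.
    """
    if not stimulus_response_period > 0:
        raise ValueError(
            f"stimulus_response_period must be > 0, got {stimulus_response_period!r}"
        )
    return 2.0 / stimulus_response_period
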