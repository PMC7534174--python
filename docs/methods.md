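# Methods

## Scope and model

The engine implements guided manual pressure loading for quantitative
sensory testing. Two test modes are modelled:

* **Ascending** (pressure pain threshold): force rises linearly at a
  configured rate from zero; the guideline terminates at a safety limit
  (default 150 N). The limit is guidance — crossing it is flagged with the
  first crossing time, but acquisition never aborts, matching its role as
  advanced notice to the tester rather than a hard stop.
* **Train** (temporal summation): `n` identical trapezoidal cycles
  (ascent `a`, hold `p`, descent `d`, peak force `f`, inter-cycle baseline
  ≥ 0) separated by an inter-stimulus interval (ISI). The ISI is defined
  **end-of-descent to start-of-next-ascent**; cycle `k` starts at
  `k·(a+p+d+isi)` and the guided duration is `n(a+p+d) + (n−1)·isi`.

Impulse (force-time area, N·s) per cycle has two closed forms. With constant
phase durations: `f·a/2 + f·p + f·d/2 = f(a+2p+d)/2`, linear in `f`. With
constant loading rates `r_a`, `r_d`: `f²/(2r_a) + f·p + f²/(2r_d)`, quadratic
in `f` for the ramp phases. The two parameterizations produce identical
cycles exactly at the reference peak force (`a = f/r_a`, `d = f/r_d`). These
closed forms are the dosimetry core; recorded traces are integrated
numerically (trapezoidal quadrature of the baseline-subtracted force over
per-cycle windows) and the two routes are required to agree in tests.

Calibration is strictly linear: conversion factor = rated voltage span /
rated force span (V/N); force = voltage / factor − task baseline. The
baseline is the mean force over a pre-task window (default 0.5 s), recorded
with the task and subtracted from all readings. Pressure conversion is exact
SI arithmetic (`kPa = N / (cm²·10⁻⁴) / 1000`): a 150 N limit on a 1.2 cm²
tip is 1250 kPa; on a 1.5 cm² tip, 1000 kPa. The Nyquist minimum sampling
rate for a stimulus-response period `T` is `2/T` (13.33 Hz at 150 ms); the
default acquisition rate is 20 Hz.

## Key parameters

| parameter | unit | default | rationale |
| --- | --- | --- | --- |
| sampling frequency | Hz | 20 | above the 13.33 Hz Nyquist bound for 150 ms responses |
| safety limit | N | 150 | comparable to commercial devices, well below skin-failure estimates |
| stimuli per train | — | 10 | standard temporal-summation train length |
| peak hold `p` | s | 1 | typical suprathreshold hold |
| inter-stimulus interval | s | 2 | short enough for summation (wind-up) |
| trigger debounce | s | 0.05 | one sample at 20 Hz; momentary push-button bounce |
| pre-task zeroing window | s | 0.5 | 10 samples; standard error of the baseline mean ≪ 1 N at realistic noise |

All are overridable per protocol/config.

## Numerical choices

* **Instantaneous descent** (`d = 0`) is a documented sentinel, not an
  infinite rate. On the guideline it becomes a vertical drop spanning half a
  sample interval, **centred on the nominal hold end** when the hold is at
  least half a sample long. Centring makes trapezoidal quadrature through
  the drop reproduce the closed form exactly when breakpoints lie on the
  sampling grid; the train pathway additionally settles to baseline on the
  next grid point so the sampled trace covers the final drop. The residual
  disagreement from a cycle truncated at the nominal trace end is bounded by
  `f·dt/4`; closed-form vs quadrature agreement is therefore asserted at
  `max(0.5 %, f·dt/4)`.
* **Grid generation** includes the endpoint when `end × fs` is integral to
  1e-9, else stops at the last grid point below the end.
* **Trigger detection** maps a raw trigger voltage to pressed when it
  exceeds 50 % of the button supply, then emits one event per
  released→pressed transition, ignoring transitions within the debounce
  window of the last accepted event.
* **Safety comparison** is strict (`force > limit`), applied both to target
  peaks at validation time and to live samples at run time.
* **Multi-cycle trains with instantaneous descent** require a positive ISI
  (the drop encoding needs room before the next ascent); validation rejects
  the degenerate `isi = 0` combination.
* Peak force reports the **first** occurrence of the maximum; forces are
  stored in newtons throughout (lbf only at the unit-conversion boundary);
  conversion factors keep full floating precision internally, rounding only
  in display layers.

## The simulator

The virtual operator is a first-order lag with additive white noise:
`F[i+1] = F[i] + (dt/τ)(G(t_i) − F[i]) + ε_i`, `ε_i ~ N(0, σ)`, `F[0] = G(0)`,
clipped at 0. `τ = 0` means exact tracking plus noise; a lag shorter than
one sample interval is clamped to one-step catch-up (`dt/τ ≤ 1`), which is
behaviourally identical at the sampling rate and keeps the explicit update
stable. The model was chosen for its closed-form ramp response — a
steady-state deficit of `τ × rate` below the guideline — which doubles as a
test oracle.

The virtual subject holds ordered thresholds (detection ≤ pain ≤ tolerance).
Each threshold produces a one-sample trigger press at its first upward
crossing of the **actual** (not guided) force, delayed by the reaction time
rounded to the nearest sample — so on a ramp the recorded first-trigger
force is `threshold + rate × reaction_time`. The continuous rating is
`eVAS = clip(slope × (force − pain_threshold), 0, 100)`: piecewise-linear and
saturating. Linearity is a declared simulation assumption (the scale anchors
are 0 = no pain, 100 = worst imaginable), not a psychophysical claim.
Operator and subject use independent seeded generators so either can be held
fixed.

What the simulator does **not** emulate: habituation/sensitization dynamics
across cycles (the ratings of successive identical stimuli are identical),
nonlinear or history-dependent pain transduction, tremor spectra or
correlated operator error, gauge nonlinearity and temperature drift. Passing
tests therefore demonstrate that the engine's arithmetic, event capture and
bookkeeping are correct under a plausible idealization of manual testing —
not that human sessions will show these statistics.

## Design decisions taken where the design was open

* The ascending test's end condition is configurable (guided duration by
  default, optionally the Nth trigger or source stop) rather than fixed at
  first trigger, tolerance or limit.
* Inter-test intervals are runner pauses; all repetitions of a session are
  stored in one datafile, separated by a repetition column.
* The session datafile's default directory is the current working directory
  (portability), with commented (`#`) header lines so the continuous block
  stays readable by generic CSV tools; times are seconds from task start
  plus one absolute ISO 8601 timestamp in the header.
* Train totals in the method-comparison report multiply the per-cycle
  closed form by the number of stimuli (cycles within a train are
  identical); per-cycle numeric values are still reported individually for
  recorded traces.
* Configs are YAML (read/write); TOML is read via the stdlib parser but not
  written (no TOML writer in the standard library).

## Problem sizes and determinism

All simulations run at the default 20 Hz: an ascending repetition is 151
samples (7.5 s to the 150 N limit at 20 N/s) and a 10-cycle train is 1561
samples (78 s). The stochastic recovery check uses 100 repetitions with
noise 2 N, lag 0.2 s and reaction 0.2 s, and recovers the mean first-trigger
force within 2 N of `threshold + rate × reaction`. Every random draw is
seeded; property tests are derandomised.

## Known limitations

* Calibration is linear and single-axis; no temperature compensation.
* The quadrature tolerance argument assumes cycle breakpoints on the
  sampling grid; off-grid cycles are still integrated but only the 0.5 %
  relative band applies.
* No real DAQ drivers and no real-time rendering: the feedback data contract
  (`FeedbackFrame`) is renderer-agnostic, and hard real-time behaviour is
  out of scope.
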