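# algometry

A hardware-agnostic pressure-algometry engine for quantitative sensory
testing (QST). Pressure algometers apply a manually generated, measured force
to a body site to evoke and quantify pressure pain — pressure pain thresholds
(PPT, ascending method of limits) and temporal summation (trains of identical
suprathreshold trapezoidal stimuli). This package provides the software core
of such a system for researchers and clinicians: guided force-time loading
pathways, load-cell voltage-to-force calibration, multi-channel response
capture (trigger button, continuous 0–100 eVAS), impulse dosimetry per
loading cycle, and multi-repetition session summaries — with a virtual
operator/subject simulator standing in for physical hardware.

## The model

A loading cycle is a trapezoid on the force-time diagram: a linear ascent to
peak force *f* over duration *a*, a hold of duration *p*, and a descent over
*d*. Its impulse (force-time area, N·s) decomposes by phase:

* constant phase **durations** (Method 1):
  `I = f·a/2 + f·p + f·d/2 = f(a + 2p + d)/2` — linear in *f*;
* constant loading **rates** `r_a`, `r_d` (Method 2):
  `I = f²/(2r_a) + f·p + f²/(2r_d)` — the ascent/descent areas grow with the
  *square* of *f*, because a higher peak also lengthens the phase.

When temporal-summation trains are individualized to each participant's PPT,
the choice between the two methods changes the delivered dose: under
Method 2 a 10% higher threshold receives ~17.9% more impulse per cycle and a
21% higher threshold ~39% more, so the dose is no longer proportional to the
individualization variable. `compare_methods` quantifies this; the
closed forms are cross-checked against trapezoidal quadrature of the sampled
guideline.

Calibration is linear: the gauge's conversion factor (V/N) is its rated
voltage span over its rated force span (e.g. 2 V / 1000 N = 0.002 V/N), and
the Nyquist bound `2/period` sets the minimum sampling rate (13.33 Hz for a
150 ms stimulus-response period; the engine samples at 20 Hz by default).

## Worked example

Per-cycle impulse of the constant-rate cycle used for a participant whose
PPT is 110 N (20 N/s ascent, 1-s hold, instantaneous descent):

```text
$ algometry impulse --f 110 --ra 20 --p 1
ascending_Ns: 302.5
peak_Ns: 110
descending_Ns: 0
total_Ns: 412.5
cycle_duration_s: 6.5
```

Dosimetry for three participants whose PPTs are 100, 110 and 121 N
(10-stimulus trains, 2-s inter-stimulus interval):

```text
$ algometry compare-methods --ppts 100,110,121
participant          method  peak_force_N  cycle_impulse_Ns  ...  train_impulse_Ns  train_duration_s  pct_diff_vs_reference
          A fixed_durations       100.000           350.000  ...          3500.000            78.000                  0.000
          B fixed_durations       110.000           385.000  ...          3850.000            78.000                 10.000
          C fixed_durations       121.000           423.500  ...          4235.000            78.000                 21.000
          A     fixed_rates       100.000           350.000  ...          3500.000            78.000                  0.000
          B     fixed_rates       110.000           412.500  ...          4125.000            83.000                 17.857
          C     fixed_rates       121.000           487.025  ...          4870.250            88.500                 39.150
```

Under constant durations (Method 1) the impulse stays proportional to peak
force (+10%, +21%) and every train lasts 78 s; under constant rates
(Method 2) the same participants receive +17.9% and +39.2% more impulse and
their tests lengthen with their thresholds.

A complete simulated PPT session (virtual operator tracking the guideline,
virtual subject pressing the trigger at threshold) runs from a YAML config:

```text
$ algometry simulate examples/ascending.yaml --out session.csv --seed 7
n_repetitions: 3
mean_peak_force_N: 150.000
mean_first_trigger_force_N: 40.000 (n=3)
```

The datafile is a sectioned CSV — a commented settings header (baseline,
participant id, timestamp), the timestamped continuous force/eVAS/trigger
block, and a summary block (peaks, trigger instants, per-cycle AUC) — and
`algometry summarize session.csv` recomputes the summary from it.

In Python the same pieces compose directly:

```python
from algometry import (individualize_train, OperatorModel, SubjectModel,
                       SimulatedSource, run_test)

train = individualize_train(100.0, "fixed_durations", dict(a=5, p=1, d=0))
source = SimulatedSource(train,
                         OperatorModel(tracking_time_constant=0.2, noise_sd=2.0),
                         SubjectModel(detection_threshold=40, pain_threshold=80,
                                      tolerance_threshold=120))
result = run_test(train, source)
result.per_cycle_impulses   # ~330-345 N·s per cycle: the operator's 0.2 s
                            # tracking lag trims the ideal 350 N·s slightly
```

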