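"""Impulse closed forms, numeric quadrature and method comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from algometry import (
    INSTANTANEOUS,
    AcquisitionConfig,
    TimeSeries,
    compare_methods,
    cycle_impulse_fixed_durations,
    cycle_impulse_fixed_rates,
    individualize_train,
    numeric_impulse,
    sample_pathway,
    segment_cycles,
    train_pathway,
)


@pytest.mark.parametrize(
    "f, a, p, d, total",
    [(100.0, 5.0, 1.0, 0.0, 350.0), (110.0, 5.0, 1.0, 0.0, 385.0),
     (0.0, 5.0, 1.0, 0.0, 0.0)],
)
def test_fixed_durations_totals(f, a, p, d, total):
    br = cycle_impulse_fixed_durations(f, a, p, d)
    assert br.total == pytest.approx(total)
    assert br.total == pytest.approx(f * (a + 2 * p + d) / 2.0)
    assert br.total == pytest.approx(br.ascending + br.peak + br.descending, rel=1e-9)


@pytest.mark.parametrize(
    "f, total",
    [(100.0, 350.0), (110.0, 412.5), (121.0, 487.025)],
)
def test_fixed_rates_totals(f, total):
    br = cycle_impulse_fixed_rates(f, 20.0, 1.0, INSTANTANEOUS)
    assert br.total == pytest.approx(total)
    assert br.cycle_duration == pytest.approx(f / 20.0 + 1.0)


def test_fixed_rates_c_rounds_to_one_decimal():
    assert round(cycle_impulse_fixed_rates(121.0, 20.0, 1.0).total, 1) == 487.0


def test_fixed_rates_finite_descent_adds_mirror_area():
    br = cycle_impulse_fixed_rates(100.0, 20.0, 1.0, 20.0)
    assert br.descending == pytest.approx(br.ascending)
    assert br.total == pytest.approx(600.0)


@pytest.mark.parametrize(
    "kwargs",
    [dict(f=-1.0, a=5.0, p=1.0, d=0.0), dict(f=100.0, a=0.0, p=1.0, d=0.0)],
)
def test_fixed_durations_rejects_invalid(kwargs):
    with pytest.raises(ValueError):
        cycle_impulse_fixed_durations(**kwargs)


def test_fixed_rates_rejects_invalid():
    with pytest.raises(ValueError):
        cycle_impulse_fixed_rates(0.0, 20.0, 1.0)
    with pytest.raises(ValueError):
        cycle_impulse_fixed_rates(100.0, 20.0, 1.0, -5.0)


def test_numeric_impulse_constant_force_and_baseline():
    ts = TimeSeries(times=np.arange(0, 2.05, 0.05),
                    channels={"force": np.full(41, 10.0)})
    assert numeric_impulse(ts, 0.0, [(0.0, 2.0)])[0] == pytest.approx(20.0)
    assert numeric_impulse(ts, 10.0, [(0.0, 2.0)])[0] == pytest.approx(0.0)


def test_numeric_impulse_window_outside_trace():
    ts = TimeSeries(times=np.arange(0, 1.05, 0.05),
                    channels={"force": np.zeros(21)})
    with pytest.raises(ValueError, match="outside the trace span"):
        numeric_impulse(ts, 0.0, [(0.0, 5.0)])


def test_numeric_matches_closed_form_on_sampled_guideline(train_a):
    ts = sample_pathway(train_pathway(train_a), train_a.acquisition)
    windows = segment_cycles(ts, train_a)
    impulses = numeric_impulse(ts, 0.0, windows)
    # f*dt/4 absorbs the instantaneous-descent encoding at the trace end
    tol = max(0.005 * 350.0, 100.0 * 0.05 / 4.0)
    for value in impulses:
        assert value == pytest.approx(350.0, abs=tol)


def test_segment_cycles_windows(train_a):
    ts = sample_pathway(train_pathway(train_a), train_a.acquisition)
    windows = segment_cycles(ts, train_a)
    assert len(windows) == 10
    starts = [w[0] for w in windows]
    np.testing.assert_allclose(starts[1:], [8 * k - 0.05 for k in range(1, 10)])


def test_segment_cycles_single_cycle():
    train = individualize_train(
        100.0, "fixed_durations", dict(a=5.0, p=1.0, d=1.0), n_stimuli=1
    )
    ts = sample_pathway(train_pathway(train), train.acquisition)
    assert len(segment_cycles(ts, train)) == 1


def test_segment_cycles_truncated_trace_errors(train_a):
    ts = sample_pathway(train_pathway(train_a), train_a.acquisition)
    short = TimeSeries(times=ts.times[:800], channels={"force": ts["force"][:800]})
    with pytest.raises(ValueError, match="guided train"):
        segment_cycles(short, train_a)


def test_compare_methods_worked_example():
    cmp_ = compare_methods(
        [100.0, 110.0, 121.0],
        method1_params=dict(a=5.0, p=1.0, d=0.0),
        method2_params=dict(r_a=20.0, p=1.0),
    )
    t = cmp_.table
    m2 = t[t.method == "fixed_rates"]
    np.testing.assert_allclose(m2.cycle_impulse_Ns, [350.0, 412.5, 487.025])
    assert m2.pct_diff_vs_reference.iloc[1] == pytest.approx(17.857142857)
    m1 = t[t.method == "fixed_durations"]
    np.testing.assert_allclose(m1.cycle_impulse_Ns, [350.0, 385.0, 423.5])
    # Method 1 impulse ratios equal peak-force ratios
    np.testing.assert_allclose(
        m1.cycle_impulse_Ns / m1.cycle_impulse_Ns.iloc[0], [1.0, 1.10, 1.21]
    )
    # reference participant's relative difference is 0 under both methods
    assert (t[t.participant == "A"].pct_diff_vs_reference == 0).all()


def test_compare_methods_single_participant_and_empty():
    cmp_ = compare_methods([100.0], dict(a=5, p=1, d=0), dict(r_a=20, p=1))
    assert (cmp_.table.pct_diff_vs_reference == 0).all()
    with pytest.raises(ValueError):
        compare_methods([], dict(a=5, p=1, d=0), dict(r_a=20, p=1))


def test_compare_methods_coincide_at_reference():
    cmp_ = compare_methods(
        [100.0, 110.0], dict(a=5.0, p=1.0, d=0.0), dict(r_a=20.0, p=1.0)
    )
    ref = cmp_.table[cmp_.table.participant == "A"]
    cols = [c for c in ref.columns if c != "method"]
    assert ref.iloc[0][cols].equals(ref.iloc[1][cols])


def test_compare_methods_csv_export(tmp_path):
    out = tmp_path / "report.csv"
    compare_methods([100.0, 110.0], dict(a=5, p=1, d=0), dict(r_a=20, p=1)).to_csv(out)
    lines = out.read_text().splitlines()
    assert lines[0].startswith("participant,method,peak_force_N")
    assert len(lines) == 1 + 4  # 2 participants x 2 methods


@settings(derandomize=True, max_examples=50)
@given(f=st.floats(1.0, 150.0), alpha=st.floats(0.1, 3.0))
def test_method1_linearity(f, alpha):
    base = cycle_impulse_fixed_durations(f, 5.0, 1.0, 2.0).total
    scaled = cycle_impulse_fixed_durations(alpha * f, 5.0, 1.0, 2.0).total
    assert scaled == pytest.approx(alpha * base, rel=1e-9)


@settings(derandomize=True, max_examples=50)
@given(f=st.floats(1.0, 75.0), r_a=st.floats(1.0, 100.0))
def test_method2_quadratic_ascending(f, r_a):
    assert cycle_impulse_fixed_rates(2 * f, r_a, 0.0).ascending == pytest.approx(
        4 * cycle_impulse_fixed_rates(f, r_a, 0.0).ascending, rel=1e-9
    )


@settings(derandomize=True, max_examples=50)
@given(f=st.floats(1.0, 150.0), a=st.floats(0.1, 10.0))
def test_triangle_reduction(f, a):
    """p = d = 0: impulse is half the product of duration and peak force."""
    assert cycle_impulse_fixed_durations(f, a, 0.0, 0.0).total == pytest.approx(
        f * a / 2.0, rel=1e-9
    )


@settings(derandomize=True, max_examples=100, deadline=None)
@given(
    f=st.integers(10, 150),
    a_ticks=st.integers(10, 120),   # 0.5 - 6 s on the 0.05 s grid
    p_ticks=st.integers(1, 60),
    d_ticks=st.integers(0, 80),
)
def test_oracle_equivalence_randomized_cycles(f, a_ticks, p_ticks, d_ticks):
    """Quadrature on the sampled guideline matches the closed form within
    max(0.5%, f*dt/4) for random grid-aligned cycles."""
    dt = 0.05
    f = float(f)
    a, p, d = a_ticks * dt, p_ticks * dt, d_ticks * dt
    train = individualize_train(
        f, "fixed_durations", dict(a=a, p=p, d=d),
        n_stimuli=1, isi=0.0, safety_limit=200.0,
    )
    ts = sample_pathway(train_pathway(train), train.acquisition)
    numeric = numeric_impulse(ts, 0.0, segment_cycles(ts, train))[0]
    closed = cycle_impulse_fixed_durations(f, a, p, d).total
    tol = max(0.005 * closed, f * dt / 4.0)
    assert numeric == pytest.approx(closed, abs=tol)
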