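"""Single-neuron dynamics: presets, resting states, stepping, resets."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dbsnet.neuron import (
    IzhikevichParams,
    NeuronState,
    make_preset,
    resting_state,
    step_neuron,
)


@pytest.mark.parametrize(
    "name, expected",
    [
        ("regular_spiking", (0.02, 0.2, -65.0, 8.0, 30.0)),
        ("fast_spiking", (0.1, 0.2, -65.0, 2.0, 30.0)),
        ("thalamocortical", (0.02, 0.25, -65.0, 0.05, 30.0)),
    ],
)
def test_presets_are_canonical(name, expected):
    p = make_preset(name)
    assert (p.a, p.b, p.c, p.d, p.v_peak) == expected


def test_unknown_preset_lists_valid_names():
    with pytest.raises(ValueError, match="thalamocortical"):
        make_preset("bursting")


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        IzhikevichParams(a=-0.02, b=0.2, c=-65, d=8)
    with pytest.raises(ValueError):
        IzhikevichParams(a=0.02, b=0.2, c=40, d=8, v_peak=30)
    with pytest.raises(ValueError):
        IzhikevichParams(a=math.nan, b=0.2, c=-65, d=8)


@pytest.mark.parametrize(
    "name, v_expected",
    [
        # lower roots of 0.04 v^2 + (5 - b) v + 140 = 0
        ("regular_spiking", -70.0),
        ("fast_spiking", -70.0),
        ("thalamocortical", (-4.75 - math.sqrt(4.75**2 - 4 * 0.04 * 140)) / 0.08),
    ],
)
def test_resting_state_matches_quadratic_root(name, v_expected):
    p = make_preset(name)
    r = resting_state(p)
    assert r.v == pytest.approx(v_expected, abs=1e-9)
    assert r.u == pytest.approx(p.b * v_expected, abs=1e-9)
    # direct substitution into both nullclines
    assert 0.04 * r.v**2 + 5 * r.v + 140 - r.u == pytest.approx(0.0, abs=1e-9)


def test_thalamocortical_rest_value():
    r = resting_state(make_preset("thalamocortical"))
    assert r.v == pytest.approx(-64.41, abs=0.01)
    assert r.u == pytest.approx(-16.10, abs=0.01)


def test_no_resting_state_for_large_b():
    # b = 5 - 2*sqrt(0.04*140) makes the discriminant exactly 0; beyond it,
    # negative
    p = IzhikevichParams(a=0.02, b=1.0, c=-65, d=8)
    with pytest.raises(ValueError, match="discriminant"):
        resting_state(p)


def test_rest_is_fixed_point_of_stepping():
    for name in ("regular_spiking", "fast_spiking", "thalamocortical"):
        p = make_preset(name)
        s0 = resting_state(p)
        s1, spiked = step_neuron(s0, p, I=0.0, dt=0.1)
        assert not spiked
        assert abs(s1.v - s0.v) < 1e-6
        assert abs(s1.u - s0.u) < 1e-6


def test_reset_rule_exact():
    p = make_preset("regular_spiking")
    u0 = -10.0
    s1, spiked = step_neuron(NeuronState(v=30.0, u=u0), p, I=0.0, dt=0.1)
    assert spiked
    assert s1.v == p.c  # exact, not approximate
    assert s1.u == pytest.approx(u0 + p.a * (p.b * 30.0 - u0) * 0.1 + p.d, abs=1e-12)


def test_constant_current_spikes_within_50_ms():
    p = make_preset("regular_spiking")
    s = resting_state(p)
    spiked_any = False
    for _ in range(int(50 / 0.1)):
        s, spiked = step_neuron(s, p, I=10.0, dt=0.1)
        spiked_any = spiked_any or spiked
    assert spiked_any


def test_step_rejects_bad_inputs():
    p = make_preset("regular_spiking")
    with pytest.raises(ValueError):
        step_neuron(NeuronState(-70, -14), p, I=0.0, dt=0.0)
    with pytest.raises(ValueError):
        step_neuron(NeuronState(-70, -14), p, I=0.0, dt=1.5)
    with pytest.raises(ValueError):
        step_neuron(NeuronState(math.inf, -14), p, I=0.0, dt=0.1)


def _spike_times(preset, I, dt, t_max=500.0):
    p = make_preset(preset)
    s = resting_state(p)
    out = []
    for k in range(int(round(t_max / dt))):
        s, spiked = step_neuron(s, p, I, dt)
        if spiked:
            out.append((k + 1) * dt)
    return np.asarray(out)


def test_dt_convergence_against_fine_oracle():
    """Per-spike timing (first-spike latency and every inter-spike interval)
    changes by < 1 ms when dt is refined from 0.1 toward a 0.01 ms oracle."""
    ref = _spike_times("regular_spiking", I=10.0, dt=0.01)
    for dt in (0.1, 0.05):
        t = _spike_times("regular_spiking", I=10.0, dt=dt)
        n = min(len(t), len(ref))
        assert n > 3
        assert abs(t[0] - ref[0]) < 1.0
        assert np.max(np.abs(np.diff(t[:n]) - np.diff(ref[:n]))) < 1.0


def test_fast_spiking_outrates_regular_spiking():
    n_fs = len(_spike_times("fast_spiking", I=10.0, dt=0.1, t_max=1000.0))
    n_rs = len(_spike_times("regular_spiking", I=10.0, dt=0.1, t_max=1000.0))
    assert n_fs > n_rs


@settings(deadline=None, max_examples=200, derandomize=True)
@given(
    v=st.floats(-90, 40),
    u=st.floats(-30, 30),
    I=st.floats(-50, 50),
    dt=st.floats(0.01, 1.0),
)
def test_step_invariants(v, u, I, dt):
    """After any completed step v <= v_peak, and a spike resets v to c exactly."""
    p = make_preset("regular_spiking")
    s1, spiked = step_neuron(NeuronState(v, u), p, I, dt)
    assert math.isfinite(s1.v) and math.isfinite(s1.u)
    assert s1.v <= p.v_peak
    if spiked:
        assert s1.v == p.c
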