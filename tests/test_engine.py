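"""Engine contracts: determinism, causality, drive, delivery, rates."""

import numpy as np
import pandas as pd
import pytest

from dbsnet.engine import (
    DriveConfig,
    SimulationConfig,
    SimulationBlowupError,
    calibrate_drive,
    deliver_spike,
    run_simulation,
)
from dbsnet.network import ConnectionSpec, Edges, build_default_network
from dbsnet.stimulation import make_pulse_train


def test_no_input_no_spikes(calibrated_net):
    cfg = SimulationConfig(
        duration=1000.0, burn_in=0.0, seed=0,
        drive=DriveConfig(bias={}, sigma={}),
    )
    sp = run_simulation(calibrated_net, None, cfg)
    assert sp.n_events == 0


def test_same_seed_identical_events(calibrated_net):
    cfg = SimulationConfig(duration=600.0, burn_in=0.0, seed=7)
    a = run_simulation(calibrated_net, None, cfg)
    b = run_simulation(calibrated_net, None, cfg)
    pd.testing.assert_frame_equal(a.events, b.events)
    assert a.config_fingerprint == b.config_fingerprint


def test_different_seed_different_events(calibrated_net):
    cfg1 = SimulationConfig(duration=600.0, burn_in=0.0, seed=7)
    cfg2 = SimulationConfig(duration=600.0, burn_in=0.0, seed=8)
    a = run_simulation(calibrated_net, None, cfg1)
    b = run_simulation(calibrated_net, None, cfg2)
    assert not a.events.equals(b.events)


def test_zero_amplitude_train_equals_dbs_off(calibrated_net):
    """A zero-amplitude train must be bit-identical to no stimulation."""
    cfg = SimulationConfig(duration=600.0, burn_in=0.0, seed=3)
    train = make_pulse_train(130.0, 180.0, amplitude_model=0.0,
                             t_start=0.0, t_end=600.0)
    on = run_simulation(calibrated_net, train, cfg)
    off = run_simulation(calibrated_net, None, cfg)
    pd.testing.assert_frame_equal(on.events, off.events)


def test_baseline_rates_in_operating_bands(calibrated_net):
    """DBS off: thalamus in the 10-40 Hz band, cortex relaying (> 0)."""
    cfg = SimulationConfig(duration=2000.0, burn_in=500.0, seed=0)
    sp = run_simulation(calibrated_net, None, cfg)
    thal = sp.rate_hz("thalamus", 500.0)
    assert 10.0 <= thal <= 40.0
    assert sp.rate_hz("cortex_exc", 500.0) > 0.0
    assert sp.rate_hz("motor_out", 500.0) > 0.0


def test_drive_bias_scaling_monotone(calibrated_net):
    """Doubling the thalamic bias never decreases the thalamic rate."""
    rates = []
    for bias in (1.0, 2.0):
        cfg = SimulationConfig(
            duration=1000.0, burn_in=200.0, seed=0,
            drive=DriveConfig(bias={"thalamus": bias}, sigma={"thalamus": 0.15}),
        )
        sp = run_simulation(calibrated_net, None, cfg)
        rates.append(sp.rate_hz("thalamus", 200.0))
    assert rates[1] >= rates[0]


def test_refractory_suppression_at_185hz(calibrated_net):
    """Sub-2-ms thalamic ISIs are no more common at 185 Hz than DBS off."""
    cfg = SimulationConfig(duration=1200.0, burn_in=200.0, seed=0)
    amp = 121.0
    train = make_pulse_train(185.0, 180.0, amp, 0.0, 1200.0)
    on = run_simulation(calibrated_net, train, cfg)
    off = run_simulation(calibrated_net, None, cfg)

    def frac_short(sp):
        ev = sp.for_population("thalamus")
        ev = ev[ev["time_ms"] >= 200.0]
        isis = []
        for _, sub in ev.groupby("neuron"):
            isis.append(np.diff(np.sort(sub["time_ms"].to_numpy())))
        isis = np.concatenate(isis) if isis else np.array([])
        return (isis < 2.0).mean() if len(isis) else 0.0

    assert frac_short(on) <= frac_short(off) + 1e-12


def test_numeric_blowup_detected(calibrated_net):
    cfg = SimulationConfig(
        duration=100.0, burn_in=0.0, seed=0,
        drive=DriveConfig(bias={"thalamus": 1e7}, sigma={}),
    )
    with pytest.raises(SimulationBlowupError, match="step"):
        run_simulation(calibrated_net, None, cfg)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(dt=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(duration=100.0, burn_in=100.0)
    with pytest.raises(ValueError):
        DriveConfig(sigma={"thalamus": -1.0})


def test_deliver_spike_schedule_and_signs():
    conn = ConnectionSpec("cortex_inh", "motor_out", "diffuse", -16.0, delay=0.5)
    edges = Edges(pre_idx=np.array([0, 0, 1]), post_idx=np.array([2, 3, 2]))
    out = deliver_spike(conn, edges, pre_neuron=0, t=10.0, dt=0.1)
    assert [(p, w) for p, _, w in out] == [(2, -16.0), (3, -16.0)]
    for _, due, _ in out:
        assert due == pytest.approx(10.5)
        assert due > 10.0  # causality: delivery strictly after the spike


def test_deliver_spike_excitatory_and_scaled():
    conn = ConnectionSpec("thalamus", "cortex_exc", "one_to_one", 100.0, delay=0.5)
    edges = Edges(pre_idx=np.arange(3), post_idx=np.arange(3))
    (post, due, w), = deliver_spike(conn, edges, 1, t=0.25, dt=0.1, scale=2.0)
    assert post == 1
    assert w == pytest.approx(200.0)
    assert due == pytest.approx(0.8)  # snapped up to the grid


def test_spike_times_sorted_and_bounded(calibrated_net):
    cfg = SimulationConfig(duration=600.0, burn_in=0.0, seed=5)
    sp = run_simulation(calibrated_net, None, cfg)
    t = sp.events["time_ms"].to_numpy()
    assert (np.diff(t) >= 0).all()
    assert (t >= 0).all() and (t <= 600.0).all()
    for pop, size in sp.population_sizes.items():
        ev = sp.for_population(pop)
        assert (ev["neuron"] >= 0).all() and (ev["neuron"] < size).all()


def test_calibrate_drive_returns_default_bias():
    assert calibrate_drive(seed=0) == pytest.approx(1.0)
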