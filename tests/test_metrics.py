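"""Attribution rules, propagation metrics, regime classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dbsnet.engine import SpikeTrainSet
from dbsnet.metrics import (
    AttributionConfig,
    FrequencyMetrics,
    attribute_spikes,
    background_propagation_rate,
    classify_regime,
    coincidence_expectation,
    frequency_sweep,
    per_pulse_propagation,
    DEFAULT_SWEEP_FREQUENCIES,
)
from dbsnet.stimulation import make_pulse_train


def _spikes(times, pop="thalamus", size=400, duration=1000.0):
    ev = pd.DataFrame(
        {
            "population": pop,
            "neuron": np.zeros(len(times), dtype=int),
            "time_ms": np.asarray(times, dtype=float),
            "label": "unlabeled",
        }
    )
    return SpikeTrainSet(ev, {pop: size}, duration)


def test_window_labeling_rules():
    train = make_pulse_train(10.0, 180.0, 1.0, 0.0, 1000.0)
    sp = _spikes([101.0, 910.0])  # 1 ms after onset 100; 10 ms after onset 900
    lab = attribute_spikes(sp, train, AttributionConfig(window=3.0))
    assert list(lab.events["label"]) == ["stimulus_locked", "background"]


def test_empty_train_all_background():
    sp = _spikes([10.0, 20.0, 30.0])
    lab = attribute_spikes(sp, None, AttributionConfig())
    assert (lab.events["label"] == "background").all()


def test_degenerate_window_rejected():
    train = make_pulse_train(250.0, 180.0, 1.0, 0.0, 1000.0)
    with pytest.raises(ValueError, match="inter-pulse"):
        attribute_spikes(_spikes([1.0]), train, AttributionConfig(window=5.0))


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    times=st.lists(st.floats(0.0, 999.0), max_size=200),
    f=st.sampled_from([5.0, 20.0, 60.0, 185.0]),
)
def test_label_conservation(times, f):
    """#stimulus_locked + #background always equals #spikes."""
    train = make_pulse_train(f, 180.0, 1.0, 0.0, 1000.0)
    lab = attribute_spikes(_spikes(sorted(times)), train, AttributionConfig())
    counts = lab.events["label"].value_counts()
    assert counts.get("stimulus_locked", 0) + counts.get("background", 0) == len(times)
    # independently check each label against the rule
    for _, row in lab.events.iterrows():
        k = np.searchsorted(train.onsets, row.time_ms, side="right") - 1
        inside = k >= 0 and (row.time_ms - train.onsets[k]) < 3.0
        assert (row.label == "stimulus_locked") == inside


def test_per_pulse_full_population_fixture():
    """All 400 neurons spiking once in every pulse window -> 400 per pulse."""
    train = make_pulse_train(10.0, 180.0, 1.0, 0.0, 1000.0)
    rows = []
    for o in train.onsets:
        for n in range(400):
            rows.append(("thalamus", n, o + 1.0, "unlabeled"))
    ev = pd.DataFrame(rows, columns=["population", "neuron", "time_ms", "label"])
    sp = SpikeTrainSet(ev, {"thalamus": 400}, 1000.0)
    lab = attribute_spikes(sp, train, AttributionConfig())
    assert per_pulse_propagation(lab, "thalamus", train) == pytest.approx(400.0)


def test_per_pulse_requires_pulses_after_burn_in():
    train = make_pulse_train(10.0, 180.0, 1.0, 0.0, 100.0)
    lab = attribute_spikes(_spikes([1.0], duration=1000.0), train, AttributionConfig())
    with pytest.raises(ValueError, match="burn_in"):
        per_pulse_propagation(lab, "thalamus", train, burn_in=500.0)


def test_background_rate_dbs_off_equals_total():
    sp = _spikes(np.linspace(0, 999, 200))
    lab = attribute_spikes(sp, None, AttributionConfig())
    assert background_propagation_rate(lab, "thalamus") == pytest.approx(200.0)


def test_background_rate_all_locked_fixture_is_zero():
    train = make_pulse_train(10.0, 180.0, 1.0, 0.0, 1000.0)
    lab = attribute_spikes(_spikes(train.onsets + 1.0), train, AttributionConfig())
    assert background_propagation_rate(lab, "thalamus") == 0.0


def test_background_rate_short_epoch_rejected():
    lab = attribute_spikes(_spikes([1.0], duration=600.0), None, AttributionConfig())
    with pytest.raises(ValueError, match="short"):
        background_propagation_rate(lab, "thalamus", burn_in=200.0)


def test_coincidence_expectation_formula():
    # 6400 spikes/s aggregate, 3 ms windows -> 19.2 coincident per pulse
    assert coincidence_expectation(6400.0, 3.0, 60.0) == pytest.approx(19.2)


def test_default_sweep_contains_raster_frequencies():
    assert {10, 60, 185} <= set(DEFAULT_SWEEP_FREQUENCIES)


def test_degenerate_sweep_matches_single_run(calibrated_net):
    """One frequency, one seed: the sweep is exactly that run's metrics."""
    from dbsnet.engine import SimulationConfig, run_simulation
    from dbsnet.metrics import _metrics_for_run

    cfg = SimulationConfig(duration=1200.0, burn_in=500.0, seed=4)
    res = frequency_sweep(
        calibrated_net, frequencies=(60.0,), seeds=(4,), cfg=cfg,
        amplitude_model=121.0, include_baseline=False,
    )
    train = make_pulse_train(60.0, 180.0, 121.0, 0.0, 1200.0)
    spikes = run_simulation(calibrated_net, train, cfg)
    lab = attribute_spikes(spikes, train, AttributionConfig())
    m = _metrics_for_run(lab, train, 60.0, 500.0, 3.0)
    only = res.entries[0]
    assert only.stim_per_pulse == m.stim_per_pulse
    assert only.background_rate_hz == m.background_rate_hz


def test_sweep_input_validation(calibrated_net):
    with pytest.raises(ValueError, match="seed"):
        frequency_sweep(calibrated_net, frequencies=(60.0,), seeds=())


def _fm(freq, stim, back, tot):
    pops = ("thalamus", "cortex_exc", "cortex_inh", "motor_out")
    return FrequencyMetrics(
        frequency=freq,
        stim_per_pulse=dict(zip(pops, stim)),
        background_rate_hz=dict(zip(pops, back)),
        total_rate_hz=dict(zip(pops, tot)),
    )


BASE = _fm(0.0, (0, 0, 0, 0), (8000, 7000, 600, 3500), (8000, 7000, 600, 3500))


def test_regime_equal_to_baseline_is_additive():
    m = _fm(5.0, (0, 0, 0, 0), (8000, 7000, 600, 3500), (8000, 7000, 600, 3500))
    assert classify_regime(m, BASE) == "additive"


def test_regime_silent_thalamus():
    m = _fm(500.0, (0, 0, 0, 0), (0, 0, 0, 0), (100, 0, 0, 0))
    assert classify_regime(m, BASE) == "silent"


def test_regime_blockade_vs_substitution():
    blocked = _fm(185.0, (400, 400, 100, 0), (0, 0, 0, 0), (70000, 70000, 18000, 100))
    assert classify_regime(blocked, BASE) == "blockade"
    substituting = _fm(60.0, (400, 400, 100, 50), (0, 0, 0, 0),
                       (24000, 24000, 6000, 3000))
    assert classify_regime(substituting, BASE) == "substitution"


def test_regime_zero_baseline_rejected():
    zero_base = _fm(0.0, (0, 0, 0, 0), (0, 0, 0, 0), (0, 0, 0, 0))
    with pytest.raises(ValueError, match="baseline"):
        classify_regime(BASE, zero_base)
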