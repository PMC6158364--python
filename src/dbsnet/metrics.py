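"""Spike attribution and frequency-sweep propagation metrics.

The central measurement question of the model: of the spikes a population
fires during stimulation, which are *caused by* the DBS pulses and which are
endogenous ("background") activity that still propagates?  Attribution is by
a peristimulus window: a spike is stimulus-locked iff it falls within
``window`` ms after some pulse onset (stimulus takes precedence on overlap);
everything else is background.  From the labels come the two sweep curves:

- stimulus-locked spikes per pulse, per population (how far does each DBS
  pulse propagate?), and
- background spikes per second, per population (how much endogenous signal
  still gets through?).

A paired-run oracle (`excess_spikes`) — same drive seed with DBS on versus
off, excess count = stimulus-attributable — ships as a validation-only
cross-check of the window rule, not as the primary metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
import pandas as pd

from .engine import SimulationConfig, SpikeTrainSet, run_simulation
from .network import NetworkSpec  # noqa: F401  (public signature type)
from .stimulation import PulseTrainSpec, make_pulse_train

__all__ = [
    "AttributionConfig",
    "FrequencyMetrics",
    "SweepResult",
    "attribute_spikes",
    "per_pulse_propagation",
    "background_propagation_rate",
    "frequency_sweep",
    "classify_regime",
    "coincidence_expectation",
    "excess_spikes",
    "DEFAULT_SWEEP_FREQUENCIES",
]

#: Default sweep grid (Hz): spans the clinical 5-250 Hz range and contains
#: the three raster frequencies 10, 60, 185.
DEFAULT_SWEEP_FREQUENCIES = (5, 10, 20, 30, 40, 60, 80, 100, 125, 150, 185, 250)


@dataclass(frozen=True)
class AttributionConfig:
    """Attribution rule: the peristimulus window length in ms (default 3)."""

    window: float = 3.0

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError(f"window must be positive, got {self.window}")


@dataclass(frozen=True)
class FrequencyMetrics:
    """Per-frequency propagation metrics for every population.

    ``stim_per_pulse`` and ``background_rate_hz`` are population aggregates
    (summed over neurons); ``total_rate_hz`` = stim + background spike count
    per second.  All computed over the post-burn-in epoch.
    """

    frequency: float
    stim_per_pulse: dict
    background_rate_hz: dict
    total_rate_hz: dict
    n_seeds: int = 1


@dataclass
class SweepResult:
    """Seed-averaged metrics over a frequency sweep.

    ``entries`` holds one seed-averaged `FrequencyMetrics` per frequency in
    strictly increasing order; ``per_seed`` is a tidy DataFrame retaining
    the per-seed values (columns: frequency_hz, population, stim_per_pulse,
    background_rate_hz, total_rate_hz, seed).
    """

    entries: list
    seeds: list
    per_seed: pd.DataFrame
    config_fingerprint: str = ""

    def frame(self) -> pd.DataFrame:
        """Seed-averaged metrics as a tidy DataFrame."""
        rows = []
        for m in self.entries:
            for pop in m.stim_per_pulse:
                rows.append(
                    {
                        "frequency_hz": m.frequency,
                        "population": pop,
                        "stim_per_pulse": m.stim_per_pulse[pop],
                        "background_rate_hz": m.background_rate_hz[pop],
                        "total_rate_hz": m.total_rate_hz[pop],
                        "n_seeds": m.n_seeds,
                    }
                )
        return pd.DataFrame(rows)


def attribute_spikes(
    spikes: SpikeTrainSet,
    train: PulseTrainSpec | None,
    cfg: AttributionConfig = AttributionConfig(),
) -> SpikeTrainSet:
    """Label every spike stimulus-locked or background.

    A spike at time t is stimulus-locked iff some pulse onset o satisfies
    ``o <= t < o + window``; otherwise background.  With an empty (or
    absent) train all spikes are background.

    Raises
    ------
    ValueError
        If the window is not shorter than the train's inter-pulse interval
        (labels would be degenerate).
    """
    ev = spikes.events.copy()
    if train is None or train.n_pulses == 0:
        ev["label"] = "background"
    else:
        if cfg.window >= train.period_ms:
            raise ValueError(
                f"attribution window {cfg.window} ms >= inter-pulse interval "
                f"{train.period_ms:.3f} ms"
            )
        t = ev["time_ms"].to_numpy()
        k = np.searchsorted(train.onsets, t, side="right") - 1
        valid = k >= 0
        offs = np.where(valid, t - train.onsets[np.clip(k, 0, None)], np.inf)
        locked = offs < cfg.window
        ev["label"] = np.where(locked, "stimulus_locked", "background")
    return SpikeTrainSet(
        events=ev,
        population_sizes=spikes.population_sizes,
        duration_ms=spikes.duration_ms,
        config_fingerprint=spikes.config_fingerprint,
    )


def _complete_window_epoch(
    train: PulseTrainSpec, burn_in: float, duration_ms: float, window: float
):
    """Analysis epoch covered by fully observed attribution windows.

    Only pulses after burn-in whose whole window fits inside the recording
    are counted (a censored window would bias per-pulse statistics), and
    stimulus-locked spikes are counted over exactly the epoch those windows
    span.  Returns ``(t0, t1, n_pulses)`` or ``None`` if no complete pulse.
    """
    if train is None or train.n_pulses == 0:
        return None
    ok = train.onsets[
        (train.onsets >= burn_in) & (train.onsets + window <= duration_ms)
    ]
    if len(ok) == 0:
        return None
    return float(ok[0]), float(ok[-1] + window), len(ok)


def _complete_pulses(
    train: PulseTrainSpec, burn_in: float, duration_ms: float, window: float
) -> int:
    epoch = _complete_window_epoch(train, burn_in, duration_ms, window)
    return 0 if epoch is None else epoch[2]


def per_pulse_propagation(
    labeled: SpikeTrainSet,
    population: str,
    train: PulseTrainSpec,
    burn_in: float = 0.0,
    window: float = 3.0,
) -> float:
    """Stimulus-locked spikes per pulse in one population (post burn-in)."""
    epoch = _complete_window_epoch(train, burn_in, labeled.duration_ms, window)
    if epoch is None:
        raise ValueError("no pulses after burn_in: per-pulse metric undefined")
    t0, t1, n_pulses = epoch
    ev = labeled.for_population(population)
    n = int(
        (
            (ev["label"] == "stimulus_locked")
            & (ev["time_ms"] >= t0)
            & (ev["time_ms"] < t1)
        ).sum()
    )
    return n / n_pulses


def background_propagation_rate(
    labeled: SpikeTrainSet,
    population: str,
    burn_in: float = 0.0,
) -> float:
    """Background-labeled spikes per second in one population (post burn-in).

    Population aggregate: total background spike count divided by elapsed
    seconds.  Requires at least 500 ms of post-burn-in data.
    """
    span_ms = labeled.duration_ms - burn_in
    if span_ms < 500.0:
        raise ValueError(
            f"analysis epoch of {span_ms} ms is too short (need >= 500 ms)"
        )
    ev = labeled.for_population(population)
    n = int(((ev["label"] == "background") & (ev["time_ms"] >= burn_in)).sum())
    return n / (span_ms / 1000.0)


def coincidence_expectation(
    total_rate_hz: float, window_ms: float, frequency_hz: float
) -> float:
    """Chance-level stimulus-locked spikes per pulse for unrelated activity.

    For background activity with population-aggregate rate R (spikes/s) and
    pulse windows of length w covering a fraction ``w * f`` of time, the
    expected coincidental count per pulse is ``R * w`` (w in seconds).
    """
    del frequency_hz  # rate per pulse is independent of pulse count
    return total_rate_hz * window_ms / 1000.0


def _metrics_for_run(
    labeled: SpikeTrainSet,
    train: PulseTrainSpec | None,
    frequency: float,
    burn_in: float,
    window: float = 3.0,
) -> FrequencyMetrics:
    span_s = (labeled.duration_ms - burn_in) / 1000.0
    stim, back, tot = {}, {}, {}
    for pop in labeled.population_sizes:
        ev = labeled.for_population(pop)
        ev = ev[ev["time_ms"] >= burn_in]
        n_back = int((ev["label"] == "background").sum())
        epoch = _complete_window_epoch(train, burn_in, labeled.duration_ms, window)
        if epoch is None:
            n_stim = int((ev["label"] == "stimulus_locked").sum())
            n_pulses = 0
        else:
            t0, t1, n_pulses = epoch
            n_stim = int(
                (
                    (ev["label"] == "stimulus_locked")
                    & (ev["time_ms"] >= t0)
                    & (ev["time_ms"] < t1)
                ).sum()
            )
        stim[pop] = n_stim / n_pulses if n_pulses else 0.0
        back[pop] = n_back / span_s
        tot[pop] = (n_stim + n_back) / span_s
    return FrequencyMetrics(
        frequency=frequency,
        stim_per_pulse=stim,
        background_rate_hz=back,
        total_rate_hz=tot,
    )


def frequency_sweep(
    net: NetworkSpec,
    frequencies=DEFAULT_SWEEP_FREQUENCIES,
    seeds=(0,),
    cfg: SimulationConfig = SimulationConfig(),
    att: AttributionConfig = AttributionConfig(),
    amplitude_model: float | None = None,
    pulse_width_us: float = 180.0,
    include_baseline: bool = True,
) -> SweepResult:
    """Run the full frequency sweep: simulate, attribute, and summarize.

    For each frequency x seed the network is simulated for ``cfg.duration``
    ms with stimulation on throughout, spikes are labeled, and the per-
    population metrics are computed over the post-burn-in epoch.  Entries
    are seed averages; per-seed values are retained.  With
    ``include_baseline`` a DBS-off (frequency 0) condition is prepended.

    ``amplitude_model=None`` auto-calibrates the pulse amplitude from the
    thalamic preset (see `stimulation.calibrate_pulse_amplitude`).
    """
    from .stimulation import calibrate_pulse_amplitude
    from .neuron import make_preset

    freqs = sorted(float(f) for f in frequencies)
    if len(set(freqs)) != len(freqs):
        raise ValueError("sweep frequencies must be strictly increasing")
    if not seeds:
        raise ValueError("at least one seed is required")
    if amplitude_model is None:
        amplitude_model = calibrate_pulse_amplitude(
            make_preset(net.population("thalamus").preset), dt=cfg.dt,
            pulse_width_us=pulse_width_us,
        )
    if include_baseline and 0.0 not in freqs:
        freqs = [0.0] + freqs

    entries = []
    rows = []
    for f in freqs:
        if f > 0:
            train = make_pulse_train(
                frequency=f, pulse_width=pulse_width_us,
                amplitude_model=amplitude_model,
                t_start=0.0, t_end=cfg.duration,
            )
        else:
            train = None
        per_seed_metrics = []
        for seed in seeds:
            run_cfg = _dc_replace(cfg, seed=int(seed))
            try:
                spikes = run_simulation(net, train, run_cfg)
                labeled = attribute_spikes(spikes, train, att)
            except Exception as exc:
                raise RuntimeError(
                    f"sweep run failed at frequency={f} Hz, seed={seed}: {exc}"
                ) from exc
            m = _metrics_for_run(labeled, train, f, cfg.burn_in, att.window)
            per_seed_metrics.append(m)
            for pop in m.stim_per_pulse:
                rows.append(
                    {
                        "frequency_hz": f,
                        "population": pop,
                        "stim_per_pulse": m.stim_per_pulse[pop],
                        "background_rate_hz": m.background_rate_hz[pop],
                        "total_rate_hz": m.total_rate_hz[pop],
                        "seed": int(seed),
                    }
                )
        pops = per_seed_metrics[0].stim_per_pulse.keys()
        entries.append(
            FrequencyMetrics(
                frequency=f,
                stim_per_pulse={
                    p: float(np.mean([m.stim_per_pulse[p] for m in per_seed_metrics]))
                    for p in pops
                },
                background_rate_hz={
                    p: float(
                        np.mean([m.background_rate_hz[p] for m in per_seed_metrics])
                    )
                    for p in pops
                },
                total_rate_hz={
                    p: float(np.mean([m.total_rate_hz[p] for m in per_seed_metrics]))
                    for p in pops
                },
                n_seeds=len(seeds),
            )
        )
    return SweepResult(
        entries=entries,
        seeds=list(seeds),
        per_seed=pd.DataFrame(rows),
        config_fingerprint=net.fingerprint(),
    )


@dataclass(frozen=True)
class RegimeThresholds:
    """Configurable cutoffs for the qualitative regime labels (fractions of
    the DBS-off baseline)."""

    additive_background: float = 0.5
    suppressed_background: float = 0.1
    blocked_output: float = 0.1
    silent_thalamus: float = 0.05


def classify_regime(
    metrics: FrequencyMetrics,
    baseline: FrequencyMetrics,
    thresholds: RegimeThresholds = RegimeThresholds(),
) -> str:
    """Map one frequency's metrics onto a qualitative propagation regime.

    Labels, checked in order (first match wins):

    - ``silent``: thalamic total rate < 5% of baseline (stimulation has
      shut the target down entirely);
    - ``blockade``: cortical background < 10% of baseline and motor output
      total rate < 10% of baseline (endogenous signal replaced and output
      gated);
    - ``substitution``: cortical background < 10% of baseline while
      stimulus-locked spikes still propagate into cortex;
    - ``additive``: cortical background propagates at >= 50% of baseline
      (stimulation rides on top of endogenous activity);
    - ``attenuated``: none of the above (partial suppression).

    Baseline rates of zero cannot be normalized and are rejected.
    """
    thal_base = baseline.total_rate_hz["thalamus"]
    ce_base = baseline.total_rate_hz["cortex_exc"]
    out_base = baseline.total_rate_hz["motor_out"]
    if thal_base <= 0 or ce_base <= 0 or out_base <= 0:
        raise ValueError("baseline rates must be positive to normalize against")

    thal_frac = metrics.total_rate_hz["thalamus"] / thal_base
    back_frac = metrics.background_rate_hz["cortex_exc"] / ce_base
    out_frac = metrics.total_rate_hz["motor_out"] / out_base
    stim_in_cortex = metrics.stim_per_pulse["cortex_exc"] > 0

    if thal_frac < thresholds.silent_thalamus:
        return "silent"
    if back_frac < thresholds.suppressed_background and out_frac < thresholds.blocked_output:
        return "blockade"
    if back_frac < thresholds.suppressed_background and stim_in_cortex:
        return "substitution"
    if back_frac >= thresholds.additive_background:
        return "additive"
    return "attenuated"


def excess_spikes(
    net: NetworkSpec,
    train: PulseTrainSpec,
    cfg: SimulationConfig,
    population: str,
) -> float:
    """Paired-run attribution oracle: DBS-on minus DBS-off spike count.

    Runs the same configuration (identical seed, hence identical background
    drive realization) with and without the stimulus and returns the excess
    post-burn-in spike count per pulse in ``population``.  A validation-only
    alternative to window attribution.
    """
    on = run_simulation(net, train, cfg)
    off = run_simulation(net, None, cfg)
    n_pulses = int((train.onsets >= cfg.burn_in).sum())
    if n_pulses == 0:
        raise ValueError("no pulses after burn_in")

    def _count(s: SpikeTrainSet) -> int:
        ev = s.for_population(population)
        return int((ev["time_ms"] >= cfg.burn_in).sum())

    return (_count(on) - _count(off)) / n_pulses
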