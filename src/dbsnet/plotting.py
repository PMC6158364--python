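"""Raster and frequency-sweep figures.

Rasters follow the usual layout for this model family: one row per neuron,
populations stacked in the order thalamus, cortex_inh, cortex_exc,
motor_out, each in its own color.  Figures are conveniences — every
quantitative result lives in the CSV/JSON outputs.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .engine import SpikeTrainSet

#: Raster stacking order (bottom to top) and colors.
RASTER_ORDER = ("thalamus", "cortex_inh", "cortex_exc", "motor_out")
RASTER_COLORS = {
    "thalamus": "tab:blue",
    "cortex_inh": "tab:red",
    "cortex_exc": "tab:green",
    "motor_out": "black",
}


def plot_raster(
    spikes: SpikeTrainSet,
    path,
    title: str = "",
    t0: float = 0.0,
    t1: float | None = None,
    order=RASTER_ORDER,
    colors=None,
) -> None:
    """Save a population-stacked spike raster to ``path``."""
    colors = dict(RASTER_COLORS, **(colors or {}))
    if t1 is None:
        t1 = spikes.duration_ms
    fig, ax = plt.subplots(figsize=(10, 6))
    offset = 0
    yticks, ylabels = [], []
    for pop in order:
        size = spikes.population_sizes[pop]
        ev = spikes.for_population(pop)
        ev = ev[(ev["time_ms"] >= t0) & (ev["time_ms"] < t1)]
        ax.plot(
            ev["time_ms"], ev["neuron"] + offset,
            ".", ms=1.0, color=colors.get(pop, "gray"), rasterized=True,
        )
        yticks.append(offset + size / 2)
        ylabels.append(pop)
        offset += size
    ax.set_xlim(t0, t1)
    ax.set_ylim(0, offset)
    ax.set_yticks(yticks, ylabels)
    ax.set_xlabel("time (ms)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_sweep_curves(sweep_frame, stim_path, background_path) -> None:
    """Save the two sweep figures: stim-locked/pulse and background rate.

    ``sweep_frame`` is the tidy seed-averaged DataFrame from
    `SweepResult.frame` (the frequency-0 baseline row set is drawn as a
    dashed reference on the background plot).
    """
    df = sweep_frame[sweep_frame["frequency_hz"] > 0]
    base = sweep_frame[sweep_frame["frequency_hz"] == 0]

    fig, ax = plt.subplots(figsize=(7, 5))
    for pop, sub in df.groupby("population"):
        sub = sub.sort_values("frequency_hz")
        ax.plot(sub["frequency_hz"], sub["stim_per_pulse"], "o-",
                color=RASTER_COLORS.get(pop, None), label=pop)
    ax.set_xlabel("DBS frequency (Hz)")
    ax.set_ylabel("stimulus-locked spikes per pulse")
    ax.legend()
    fig.tight_layout()
    fig.savefig(stim_path, dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 5))
    for pop, sub in df.groupby("population"):
        sub = sub.sort_values("frequency_hz")
        ax.plot(sub["frequency_hz"], sub["background_rate_hz"], "o-",
                color=RASTER_COLORS.get(pop, None), label=pop)
        if len(base):
            b = base[base["population"] == pop]["background_rate_hz"]
            if len(b):
                ax.axhline(float(b.iloc[0]), ls="--", lw=0.8,
                           color=RASTER_COLORS.get(pop, "gray"), alpha=0.5)
    ax.set_xlabel("DBS frequency (Hz)")
    ax.set_ylabel("background spikes per second")
    ax.legend()
    fig.tight_layout()
    fig.savefig(background_path, dpi=150)
    plt.close(fig)
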