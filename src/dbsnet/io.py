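"""Spike-train and sweep-result file I/O.

Spike trains are stored as plain CSV (columns ``population, neuron,
time_ms, label``) preceded by ``#``-comment header lines carrying the
configuration fingerprint, the population sizes, and the simulated
duration, so a file round-trips to an identical `SpikeTrainSet`.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .engine import SpikeTrainSet

__all__ = ["write_spikes", "read_spikes", "SpikeFileError"]

_COLUMNS = ["population", "neuron", "time_ms", "label"]
_LABELS = {"unlabeled", "stimulus_locked", "background"}


class SpikeFileError(ValueError):
    """A spike CSV violated the documented schema."""


def write_spikes(spikes: SpikeTrainSet, path) -> None:
    """Write a spike train to CSV with provenance headers."""
    path = Path(path)
    header = (
        f"# config_fingerprint: {spikes.config_fingerprint}\n"
        f"# population_sizes: {json.dumps(spikes.population_sizes, sort_keys=True)}\n"
        f"# duration_ms: {spikes.duration_ms}\n"
    )
    with open(path, "w", newline="") as fh:
        fh.write(header)
        spikes.events.to_csv(fh, index=False, columns=_COLUMNS)


def read_spikes(path) -> SpikeTrainSet:
    """Read a spike CSV written by `write_spikes`.

    Malformed rows (wrong columns, negative times, unknown labels,
    out-of-range neuron indices) are rejected with their line numbers.
    """
    path = Path(path)
    fingerprint = ""
    sizes: dict = {}
    duration = None
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            key, _, val = line[1:].partition(":")
            key = key.strip()
            if key == "config_fingerprint":
                fingerprint = val.strip()
            elif key == "population_sizes":
                sizes = json.loads(val)
            elif key == "duration_ms":
                duration = float(val)

    events = pd.read_csv(path, comment="#", dtype={"population": str, "label": str})
    if list(events.columns) != _COLUMNS:
        raise SpikeFileError(
            f"{path}: expected columns {_COLUMNS}, found {list(events.columns)}"
        )
    # +2: one for the column header line, one for 1-based numbering
    line_of = lambda i: i + n_header + 2
    bad = events.index[events["time_ms"] < 0]
    if len(bad):
        raise SpikeFileError(f"{path}: negative time_ms at line {line_of(bad[0])}")
    bad = events.index[~events["label"].isin(_LABELS)]
    if len(bad):
        raise SpikeFileError(f"{path}: unknown label at line {line_of(bad[0])}")
    if sizes:
        bad = events.index[~events["population"].isin(sizes)]
        if len(bad):
            raise SpikeFileError(
                f"{path}: unknown population at line {line_of(bad[0])}"
            )
        limit = events["population"].map(sizes)
        bad = events.index[(events["neuron"] < 0) | (events["neuron"] >= limit)]
        if len(bad):
            raise SpikeFileError(
                f"{path}: neuron index out of range at line {line_of(bad[0])}"
            )
    if duration is None:
        duration = float(events["time_ms"].max()) if len(events) else 0.0
    return SpikeTrainSet(
        events=events,
        population_sizes=sizes,
        duration_ms=duration,
        config_fingerprint=fingerprint,
    )
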