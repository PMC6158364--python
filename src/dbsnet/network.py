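"""Construction and calibration of the four-population circuit.

The model circuit is a deliberately minimal relay chain:

    thalamus (400 TC, excitatory)
        -> cortex_exc (400 RS, excitatory), one-to-one
    cortex_exc -> motor_out (400 RS, excitatory), one-to-one
    cortex_exc -> cortex_inh (100 FS) random, recruiting inhibition
    cortex_inh -> cortex_exc, cortex_inh random (inhibition throughout cortex)
    cortex_inh -> motor_out diffuse (all-to-all: the coordinated volley of
        inhibition that gates the output)
    every population has sparse random recurrent connections

Connection strengths are not free parameters taken from data; they are set
operationally, as in the hypothesis the model expresses: strong enough that
a single synchronous thalamic volley propagates through cortex to the motor
output ("excitability"), weak enough that activity dies out once external
drive stops ("no sustained oscillation").  `calibrate_weights` performs that
search over global excitatory/inhibitory scale factors.

Base weights are expressed per connection type and normalized by typical
in-degree, so a one-to-one synapse (in-degree 1) is strong while a recurrent
synapse (in-degree ~40) is weak; the calibration scales all excitatory and
all inhibitory weights by global factors g_E and g_I.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PopulationSpec",
    "ConnectionSpec",
    "Edges",
    "NetworkSpec",
    "build_default_network",
    "calibrate_weights",
    "detect_sustained_oscillation",
    "CalibrationError",
]

#: Erdos-Renyi probability for every "random" connection in the model.
RECURRENT_P = 0.1

#: Base synaptic weights (model charge units) by connection, before global
#: scaling.  One-to-one feedforward synapses carry a whole relay step on a
#: single afferent and are therefore strong; convergent connections are
#: normalized down by their expected in-degree.
DEFAULT_BASE_WEIGHTS = {
    ("thalamus", "thalamus"): 0.01,
    ("cortex_exc", "cortex_exc"): 0.2,
    ("motor_out", "motor_out"): 0.2,
    ("cortex_inh", "cortex_inh"): -1.0,
    ("thalamus", "cortex_exc"): 100.0,
    ("cortex_exc", "motor_out"): 80.0,
    ("cortex_exc", "cortex_inh"): 1.0,
    ("cortex_inh", "cortex_exc"): -2.0,
    ("cortex_inh", "motor_out"): -40.0,
}

#: Connection probability of the inhibition-recruitment path; denser than
#: the within-population recurrence so that even partial cortical volleys
#: reliably drive the fast-spiking population, while asynchronous baseline
#: activity does not.
CE_CI_P = 0.25

#: Calibration search grids for the global scales (first feasible pair in
#: lexicographic order wins).
G_EXC_GRID = (1.0, 2.0, 4.0, 8.0)
G_INH_GRID = (1.0, 2.0, 4.0, 8.0, 16.0)


class CalibrationError(RuntimeError):
    """No point of the calibration grid met both operational criteria."""

    def __init__(self, message: str, near_misses: pd.DataFrame | None = None):
        super().__init__(message)
        self.near_misses = near_misses


@dataclass(frozen=True)
class PopulationSpec:
    """One neuron population: name, size, parameter preset, synaptic role."""

    name: str
    size: int
    preset: str
    role: str  # "excitatory" | "inhibitory"

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError(f"population size must be > 0, got {self.size}")
        if self.role not in ("excitatory", "inhibitory"):
            raise ValueError(f"unknown role {self.role!r}")


@dataclass(frozen=True)
class ConnectionSpec:
    """A typed projection between two populations.

    ``weight`` is the synaptic charge delivered per presynaptic spike
    (signed: positive for excitatory sources, negative for inhibitory).
    ``connect_prob`` applies to the random topologies only.
    """

    pre: str
    post: str
    topology: str  # "one_to_one" | "diffuse" | "random_recurrent"
    weight: float
    connect_prob: float | None = None
    delay: float = 0.4  # ms

    def __post_init__(self) -> None:
        if self.topology not in ("one_to_one", "diffuse", "random_recurrent"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.topology == "random_recurrent":
            if self.connect_prob is None or not (0.0 < self.connect_prob <= 1.0):
                raise ValueError(
                    f"random_recurrent requires connect_prob in (0, 1], "
                    f"got {self.connect_prob}"
                )
        if self.delay <= 0:
            raise ValueError(f"delay must be positive, got {self.delay}")


@dataclass(frozen=True)
class Edges:
    """Realized edge list of one connection (local neuron indices)."""

    pre_idx: np.ndarray
    post_idx: np.ndarray

    def __len__(self) -> int:
        return len(self.pre_idx)


@dataclass(frozen=True)
class NetworkSpec:
    """The realized network: populations, connections, adjacency, scales."""

    populations: tuple[PopulationSpec, ...]
    connections: tuple[ConnectionSpec, ...]
    adjacency: tuple[Edges, ...]
    seed: int
    g_exc: float = 1.0
    g_inh: float = 1.0
    tau_inh_ms: float = 10.0  # decay of inhibitory synaptic current
    calibrated: bool = False

    def population(self, name: str) -> PopulationSpec:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def population_sizes(self) -> dict[str, int]:
        return {p.name: p.size for p in self.populations}

    @property
    def n_neurons(self) -> int:
        return sum(p.size for p in self.populations)

    def scale_for(self, conn: ConnectionSpec) -> float:
        role = self.population(conn.pre).role
        return self.g_exc if role == "excitatory" else self.g_inh

    def fingerprint(self) -> str:
        """Stable hash of the structural description (not the edge lists)."""
        doc = {
            "populations": [
                (p.name, p.size, p.preset, p.role) for p in self.populations
            ],
            "connections": [
                (c.pre, c.post, c.topology, c.weight, c.connect_prob, c.delay)
                for c in self.connections
            ],
            "seed": self.seed,
            "g_exc": self.g_exc,
            "g_inh": self.g_inh,
            "tau_inh_ms": self.tau_inh_ms,
        }
        payload = json.dumps(doc, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def edge_frame(self) -> pd.DataFrame:
        """Realized adjacency as a tidy edge list (one row per synapse)."""
        rows = []
        for conn, edges in zip(self.connections, self.adjacency):
            w = conn.weight * self.scale_for(conn)
            rows.append(
                pd.DataFrame(
                    {
                        "pre_pop": conn.pre,
                        "pre_id": edges.pre_idx,
                        "post_pop": conn.post,
                        "post_id": edges.post_idx,
                        "weight": w,
                        "delay_ms": conn.delay,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


DEFAULT_POPULATIONS = (
    PopulationSpec("thalamus", 400, "thalamocortical", "excitatory"),
    PopulationSpec("cortex_exc", 400, "regular_spiking", "excitatory"),
    PopulationSpec("cortex_inh", 100, "fast_spiking", "inhibitory"),
    PopulationSpec("motor_out", 400, "regular_spiking", "excitatory"),
)


def _default_connections(base_weights: dict | None = None) -> tuple[ConnectionSpec, ...]:
    w = dict(DEFAULT_BASE_WEIGHTS)
    if base_weights:
        w.update(base_weights)
    p = RECURRENT_P
    return (
        ConnectionSpec("thalamus", "thalamus", "random_recurrent",
                       w[("thalamus", "thalamus")], p),
        ConnectionSpec("cortex_exc", "cortex_exc", "random_recurrent",
                       w[("cortex_exc", "cortex_exc")], p),
        ConnectionSpec("cortex_inh", "cortex_inh", "random_recurrent",
                       w[("cortex_inh", "cortex_inh")], p),
        ConnectionSpec("motor_out", "motor_out", "random_recurrent",
                       w[("motor_out", "motor_out")], p),
        ConnectionSpec("thalamus", "cortex_exc", "one_to_one",
                       w[("thalamus", "cortex_exc")]),
        ConnectionSpec("cortex_exc", "motor_out", "one_to_one",
                       w[("cortex_exc", "motor_out")]),
        ConnectionSpec("cortex_exc", "cortex_inh", "random_recurrent",
                       w[("cortex_exc", "cortex_inh")], CE_CI_P),
        ConnectionSpec("cortex_inh", "cortex_exc", "random_recurrent",
                       w[("cortex_inh", "cortex_exc")], p),
        ConnectionSpec("cortex_inh", "motor_out", "diffuse",
                       w[("cortex_inh", "motor_out")]),
    )


def _realize_edges(
    conn: ConnectionSpec,
    n_pre: int,
    n_post: int,
    rng: np.random.Generator,
) -> Edges:
    if conn.topology == "one_to_one":
        if n_pre != n_post:
            raise ValueError(
                f"one_to_one connection {conn.pre}->{conn.post} requires equal "
                f"sizes, got {n_pre} vs {n_post}"
            )
        idx = np.arange(n_pre)
        return Edges(pre_idx=idx, post_idx=idx.copy())
    if conn.topology == "diffuse":
        pre, post = np.meshgrid(np.arange(n_pre), np.arange(n_post), indexing="ij")
        return Edges(pre_idx=pre.ravel(), post_idx=post.ravel())
    # random_recurrent: Erdos-Renyi, no self-edges when pre == post
    mask = rng.random((n_pre, n_post)) < conn.connect_prob
    if conn.pre == conn.post:
        np.fill_diagonal(mask, False)
    pre, post = np.nonzero(mask)
    return Edges(pre_idx=pre, post_idx=post)


def build_default_network(
    seed: int,
    base_weights: dict | None = None,
    tau_inh_ms: float = 10.0,
) -> NetworkSpec:
    """Build the default four-population network with realized adjacency.

    The random topologies are realized deterministically from ``seed``;
    the same seed always yields bit-identical edge lists.

    Parameters
    ----------
    seed : int
        RNG seed for the adjacency realization.
    base_weights : dict, optional
        Overrides for entries of ``DEFAULT_BASE_WEIGHTS``, keyed by
        ``(pre, post)`` population names.
    tau_inh_ms : float
        Decay time constant of the inhibitory synaptic current (ms).
    """
    pops = DEFAULT_POPULATIONS
    sizes = {p.name: p.size for p in pops}
    conns = _default_connections(base_weights)
    rng = np.random.default_rng(seed)
    adjacency = tuple(
        _realize_edges(c, sizes[c.pre], sizes[c.post], rng) for c in conns
    )
    net = NetworkSpec(
        populations=pops,
        connections=conns,
        adjacency=adjacency,
        seed=seed,
        tau_inh_ms=tau_inh_ms,
    )
    _check_signs(net)
    return net


def _check_signs(net: NetworkSpec) -> None:
    for c in net.connections:
        role = net.population(c.pre).role
        if role == "excitatory" and c.weight <= 0:
            raise ValueError(f"excitatory connection {c.pre}->{c.post} has weight <= 0")
        if role == "inhibitory" and c.weight >= 0:
            raise ValueError(f"inhibitory connection {c.pre}->{c.post} has weight >= 0")


def detect_sustained_oscillation(
    spikes,
    offset_time: float,
    window: float,
    threshold_hz: float = 0.1,
) -> bool:
    """Did activity persist after all external drive ceased?

    True iff any population's mean rate over the last half of
    ``[offset_time, offset_time + window]`` exceeds ``threshold_hz``
    spikes/s/neuron.  The first half of the window is granted as transient.

    Parameters
    ----------
    spikes : SpikeTrainSet
        Must carry population sizes and cover the window.
    offset_time : float
        Time (ms) at which external drive was switched off.
    window : float
        Evaluation window length (ms); must be >= 100 ms.
    """
    if window < 100.0:
        raise ValueError(f"window must be >= 100 ms for evidence, got {window}")
    t0 = offset_time + window / 2.0
    t1 = offset_time + window
    ev = spikes.events
    late = ev[(ev["time_ms"] >= t0) & (ev["time_ms"] < t1)]
    span_s = (t1 - t0) / 1000.0
    for name, size in spikes.population_sizes.items():
        n = int((late["population"] == name).sum())
        if n / (size * span_s) > threshold_hz:
            return True
    return False


def calibrate_weights(
    net: NetworkSpec,
    drive=None,
    seed: int = 0,
    g_exc_grid=G_EXC_GRID,
    g_inh_grid=G_INH_GRID,
    min_volley_spikes: int = 50,
) -> NetworkSpec:
    """Choose global weight scales meeting the two operational criteria.

    For each (g_E, g_I) on the grid, in lexicographic order, two short
    protocol simulations are run:

    excitability
        With background drive off and the network at rest, a single
        suprathreshold pulse is delivered to all thalamic cells at t=10 ms.
        The volley must elicit at least ``min_volley_spikes`` motor_out
        spikes within 50 ms.
    no sustained oscillation
        Background drive runs for 500 ms and is then switched off; every
        population must fall below 0.1 spikes/s/neuron within 200 ms of
        drive offset.

    The first pair satisfying both wins (deterministic tie-break).  Returns
    a copy of ``net`` with the chosen scales and ``calibrated=True``.

    Raises
    ------
    CalibrationError
        If no grid point satisfies both criteria; carries a DataFrame of
        near-misses (per-point criterion outcomes).
    """
    from .engine import DriveConfig, SimulationConfig, run_simulation
    from .stimulation import calibrate_pulse_amplitude, make_pulse_train
    from .neuron import make_preset

    if drive is None:
        drive = DriveConfig()

    thal_preset = make_preset(net.population("thalamus").preset)
    dt = 0.1
    amp = calibrate_pulse_amplitude(thal_preset, dt=dt)

    results = []
    for g_e in g_exc_grid:
        for g_i in g_inh_grid:
            cand = replace(net, g_exc=g_e, g_inh=g_i)

            # criterion (i): single-volley excitability, drive off, from rest
            volley = make_pulse_train(
                frequency=10.0, pulse_width=180.0, amplitude_model=amp,
                t_start=10.0, t_end=20.0,
            )  # one pulse at t=10
            cfg_i = SimulationConfig(
                dt=dt, duration=60.0, burn_in=0.0, seed=seed,
                drive=DriveConfig(bias={}, sigma={}), init_jitter_mv=1.0,
            )
            sp = run_simulation(cand, volley, cfg_i)
            ev = sp.events
            n_out = int(
                (
                    (ev["population"] == "motor_out")
                    & (ev["time_ms"] >= 10.0)
                    & (ev["time_ms"] < 60.0)
                ).sum()
            )
            excitable = n_out >= min_volley_spikes

            # criterion (ii): silence within 200 ms of drive offset
            quiescent = False
            if excitable:
                cfg_ii = SimulationConfig(
                    dt=dt, duration=900.0, burn_in=0.0, seed=seed,
                    drive=drive, drive_t_end=500.0,
                )
                sp2 = run_simulation(cand, None, cfg_ii)
                quiescent = not detect_sustained_oscillation(
                    sp2, offset_time=500.0, window=400.0
                )

            results.append(
                {"g_exc": g_e, "g_inh": g_i,
                 "volley_motor_spikes": n_out, "excitable": excitable,
                 "quiescent": quiescent}
            )
            if excitable and quiescent:
                return replace(net, g_exc=g_e, g_inh=g_i, calibrated=True)

    frontier = pd.DataFrame(results)
    raise CalibrationError(
        "no (g_exc, g_inh) on the grid satisfies both excitability and "
        "quiescence; see .near_misses for per-point outcomes",
        near_misses=frontier,
    )
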