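"""DBS pulse trains and their conversion to injected current.

Clinical DBS delivers brief (~180 microsecond) current pulses at rates from
a few Hz up to 250 Hz.  Here the stimulus is a monophasic rectangular
depolarizing current applied identically and synchronously to every thalamic
neuron — the synchrony is the point: it is what makes the stimulated volley
"massively synchronous" downstream.  The clinical amplitude (mA) has no
direct mapping into the dimensionless current of the Izhikevich model, so a
calibration routine maps "clinically suprathreshold" to model units: twice
the minimal single-pulse amplitude that fires a resting thalamocortical cell.

Pulse currents are rasterized onto the integration grid with exact charge
conservation: each grid step receives the amplitude scaled by the fraction
of the step covered by the pulse, so the delivered charge per pulse equals
``amplitude * pulse_width`` for any step size and any (non-grid-aligned)
onset time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .neuron import IzhikevichParams, resting_state, step_neuron

__all__ = [
    "PulseTrainSpec",
    "make_pulse_train",
    "pulse_current",
    "pulse_current_array",
    "calibrate_pulse_amplitude",
]


@dataclass(frozen=True)
class PulseTrainSpec:
    """A periodic DBS pulse train over a half-open epoch [t_start, t_end).

    Attributes
    ----------
    frequency : float
        Pulse rate in Hz; 0 denotes stimulation off (empty train).
    pulse_width : float
        Pulse duration in microseconds (clinical convention; default 180).
    amplitude_model : float
        Pulse amplitude in model current units.
    t_start, t_end : float
        Stimulation epoch in ms.
    onsets : np.ndarray
        Realized pulse onset times (ms), ``t_start + k * 1000/frequency``.
    """

    frequency: float
    pulse_width: float
    amplitude_model: float
    t_start: float
    t_end: float
    onsets: np.ndarray = field(repr=False, compare=False, default=None)

    @property
    def pulse_width_ms(self) -> float:
        return self.pulse_width * 1e-3

    @property
    def period_ms(self) -> float:
        return np.inf if self.frequency == 0 else 1000.0 / self.frequency

    @property
    def n_pulses(self) -> int:
        return 0 if self.onsets is None else len(self.onsets)


def make_pulse_train(
    frequency: float,
    pulse_width: float = 180.0,
    amplitude_model: float = 1.0,
    t_start: float = 0.0,
    t_end: float = 1000.0,
) -> PulseTrainSpec:
    """Construct a pulse train with realized onset times.

    Parameters
    ----------
    frequency : float
        Pulse rate (Hz), in [0, 1000].  0 yields an empty train.
    pulse_width : float
        Pulse duration in microseconds.
    amplitude_model : float
        Amplitude in model current units.
    t_start, t_end : float
        Half-open stimulation epoch [t_start, t_end) in ms.

    Raises
    ------
    ValueError
        For out-of-range frequency, pulses overlapping (width >= period),
        non-positive width, or an empty epoch.
    """
    if not (0.0 <= frequency <= 1000.0):
        raise ValueError(f"frequency must lie in [0, 1000] Hz, got {frequency}")
    if pulse_width <= 0:
        raise ValueError(f"pulse width must be positive, got {pulse_width}")
    if t_end <= t_start:
        raise ValueError(f"empty epoch: t_end={t_end} <= t_start={t_start}")
    if frequency > 0:
        period_ms = 1000.0 / frequency
        if pulse_width * 1e-3 >= period_ms:
            raise ValueError(
                f"pulse width {pulse_width} us >= inter-pulse interval "
                f"{period_ms:.3f} ms: pulses overlap"
            )
        n = int(np.ceil((t_end - t_start) / period_ms))
        onsets = t_start + period_ms * np.arange(n)
        onsets = onsets[onsets < t_end]
    else:
        onsets = np.empty(0)
    return PulseTrainSpec(
        frequency=frequency,
        pulse_width=pulse_width,
        amplitude_model=amplitude_model,
        t_start=t_start,
        t_end=t_end,
        onsets=onsets,
    )


def pulse_current(train: PulseTrainSpec, t: float, dt: float) -> float:
    """Mean injected current over the step [t, t + dt) (model units).

    The rectangular pulse occupies [onset, onset + width); the returned
    current is the pulse amplitude scaled by the overlap fraction of the
    step with the pulse, which conserves delivered charge per pulse
    (``amplitude * width``) for any dt.
    """
    if train.n_pulses == 0:
        return 0.0
    w = train.pulse_width_ms
    # only the nearest onset can overlap [t, t+dt) since width < period
    k = np.searchsorted(train.onsets, t + dt) - 1
    total = 0.0
    for idx in (k, k + 1):
        if 0 <= idx < train.n_pulses:
            o = train.onsets[idx]
            overlap = min(t + dt, o + w) - max(t, o)
            if overlap > 0:
                total += train.amplitude_model * overlap / dt
    return total


def pulse_current_array(train: PulseTrainSpec, n_steps: int, dt: float) -> np.ndarray:
    """Rasterize the train onto an ``n_steps`` grid of step size ``dt``.

    Returns the per-step mean current; exactly charge-conserving
    (sum(I) * dt == amplitude * width * n_pulses for pulses inside the grid).
    """
    I = np.zeros(n_steps)
    if train.n_pulses == 0:
        return I
    w = train.pulse_width_ms
    amp = train.amplitude_model
    for o in train.onsets:
        s0 = int(np.floor(o / dt))
        s1 = int(np.floor((o + w) / dt))
        for s in range(s0, s1 + 1):
            if 0 <= s < n_steps:
                overlap = min((s + 1) * dt, o + w) - max(s * dt, o)
                if overlap > 0:
                    I[s] += amp * overlap / dt
    return I


def _spikes_from_single_pulse(
    params: IzhikevichParams, amplitude: float, pulse_width_us: float, dt: float,
    horizon_ms: float = 3.0,
) -> int:
    """Count spikes within ``horizon_ms`` of a single pulse from rest."""
    train = make_pulse_train(
        frequency=100.0, pulse_width=pulse_width_us, amplitude_model=amplitude,
        t_start=0.0, t_end=5.0,
    )
    # keep only the first pulse
    state = resting_state(params)
    n_steps = int(round(horizon_ms / dt))
    I = pulse_current_array(train, n_steps, dt)
    count = 0
    for s in range(n_steps):
        state, spiked = step_neuron(state, params, I[s], dt)
        count += int(spiked)
    return count


def calibrate_pulse_amplitude(
    params: IzhikevichParams,
    dt: float = 0.1,
    pulse_width_us: float = 180.0,
    safety_factor: float = 2.0,
    rel_tol: float = 0.01,
    max_amplitude: float = 1e4,
) -> float:
    """Map a clinically suprathreshold pulse into model current units.

    Finds, by bisection to ``rel_tol`` relative precision, the smallest
    amplitude for which a single pulse of the given width fires a neuron at
    rest within 3 ms, then returns ``safety_factor`` times that threshold.
    The factor (default 2) encodes "clinically suprathreshold": therapeutic
    stimulation reliably drives the target cells.

    Raises
    ------
    RuntimeError
        If no amplitude up to ``max_amplitude`` elicits a spike.
    """
    lo, hi = 0.0, 1.0
    while _spikes_from_single_pulse(params, hi, pulse_width_us, dt) == 0:
        hi *= 2.0
        if hi > max_amplitude:
            raise RuntimeError(
                f"no amplitude <= {max_amplitude} fires a resting neuron "
                f"(pulse width {pulse_width_us} us)"
            )
    while (hi - lo) > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if _spikes_from_single_pulse(params, mid, pulse_width_us, dt) > 0:
            hi = mid
        else:
            lo = mid
    return safety_factor * hi
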