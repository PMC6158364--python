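"""Single-neuron Izhikevich dynamics.

The Izhikevich model reduces a spiking neuron to two variables: the membrane
potential ``v`` (mV) and a recovery variable ``u`` that lumps together the
slow ionic currents responsible for adaptation and refractoriness.  Between
spikes the dynamics are

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I
    du/dt = a (b v - u)

and whenever ``v`` reaches the peak cutoff ``v_peak`` (30 mV) the neuron is
said to have spiked and the state is reset: ``v <- c``, ``u <- u + d``.

Three canonical parameter presets are provided, matching the published
phenotypes used throughout the package: cortical regular-spiking (RS)
excitatory cells, cortical fast-spiking (FS) inhibitory cells, and bursting
thalamocortical (TC) relay cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "IzhikevichParams",
    "NeuronState",
    "PRESETS",
    "make_preset",
    "step_neuron",
    "resting_state",
]


@dataclass(frozen=True)
class IzhikevichParams:
    """Parameters of a single Izhikevich neuron.

    Parameters
    ----------
    a : float
        Recovery time scale (1/ms).  Smaller values give slower recovery.
    b : float
        Sensitivity of the recovery variable to subthreshold ``v``
        (dimensionless).
    c : float
        Post-spike reset potential (mV).
    d : float
        Post-spike increment of the recovery variable (model units).
    v_peak : float
        Spike cutoff voltage (mV); fixed at 30 in the canonical model.
    """

    a: float
    b: float
    c: float
    d: float
    v_peak: float = 30.0

    def __post_init__(self) -> None:
        fields = (self.a, self.b, self.c, self.d, self.v_peak)
        if not all(math.isfinite(x) for x in fields):
            raise ValueError("all Izhikevich parameters must be finite")
        if self.a <= 0:
            raise ValueError(f"recovery time-scale a must be > 0, got {self.a}")
        if self.v_peak <= self.c:
            raise ValueError(
                f"spike cutoff v_peak={self.v_peak} must exceed reset c={self.c}"
            )


@dataclass
class NeuronState:
    """Dynamical state (membrane potential ``v`` in mV, recovery ``u``)."""

    v: float
    u: float


#: Canonical published parameter sets for the three cell classes in the model.
PRESETS: dict[str, IzhikevichParams] = {
    "regular_spiking": IzhikevichParams(a=0.02, b=0.2, c=-65.0, d=8.0),
    "fast_spiking": IzhikevichParams(a=0.1, b=0.2, c=-65.0, d=2.0),
    "thalamocortical": IzhikevichParams(a=0.02, b=0.25, c=-65.0, d=0.05),
}


def make_preset(name: str) -> IzhikevichParams:
    """Return the canonical parameter set for a named cell class.

    Parameters
    ----------
    name : {"regular_spiking", "fast_spiking", "thalamocortical"}

    Raises
    ------
    ValueError
        If ``name`` is not a known preset (the message lists valid names).
    """
    try:
        return PRESETS[name]
    except KeyError:
        valid = ", ".join(sorted(PRESETS))
        raise ValueError(f"unknown preset {name!r}; valid presets: {valid}") from None


def step_neuron(
    state: NeuronState,
    params: IzhikevichParams,
    I: float,
    dt: float,
) -> tuple[NeuronState, bool]:
    """Advance one neuron by a single forward-Euler step of size ``dt``.

    Both ``v`` and ``u`` are advanced with one full Euler step evaluated at
    the pre-step state.  Spike detection (``v >= v_peak``) is applied to the
    updated voltage; on a spike the returned state is the reset state.

    Parameters
    ----------
    state : NeuronState
    params : IzhikevichParams
    I : float
        Total input current over this step (model units).
    dt : float
        Step size in ms; must lie in (0, 1].

    Returns
    -------
    (NeuronState, bool)
        The post-step (possibly reset) state and a spike flag.
    """
    if not (0.0 < dt <= 1.0):
        raise ValueError(f"dt must lie in (0, 1] ms, got {dt}")
    if not (math.isfinite(state.v) and math.isfinite(state.u) and math.isfinite(I)):
        raise ValueError("non-finite state or input current (integration blow-up?)")

    v, u = state.v, state.u
    v_new = v + dt * (0.04 * v * v + 5.0 * v + 140.0 - u + I)
    u_new = u + dt * params.a * (params.b * v - u)
    spiked = v_new >= params.v_peak
    if spiked:
        v_new = params.c
        u_new = u_new + params.d
    return NeuronState(v=v_new, u=u_new), spiked


def resting_state(params: IzhikevichParams) -> NeuronState:
    """Analytic resting state: the stable root of the subthreshold system.

    Setting du/dt = 0 gives u = b v; substituting into dv/dt = 0 yields the
    quadratic 0.04 v^2 + (5 - b) v + 140 = 0.  The lower root is the stable
    equilibrium (the upper root is the instability threshold).

    Raises
    ------
    ValueError
        If the discriminant is negative (no resting state: the neuron is
        intrinsically active at zero input).
    """
    A, B, C = 0.04, 5.0 - params.b, 140.0
    disc = B * B - 4.0 * A * C
    if disc < 0:
        raise ValueError(
            f"no resting state: discriminant {disc:.6g} < 0 for b={params.b}"
        )
    v_star = (-B - math.sqrt(disc)) / (2.0 * A)
    return NeuronState(v=v_star, u=params.b * v_star)


def instability_threshold(params: IzhikevichParams) -> float:
    """Upper (unstable) root of the subthreshold nullcline system (mV).

    A voltage excursion beyond this value triggers a regenerative spike at
    zero input; the gap between resting state and this root is the kick a
    single synaptic event must overcome to fire the cell from rest.
    """
    A, B, C = 0.04, 5.0 - params.b, 140.0
    disc = B * B - 4.0 * A * C
    if disc < 0:
        raise ValueError("no threshold root: discriminant < 0")
    return (-B + math.sqrt(disc)) / (2.0 * A)
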