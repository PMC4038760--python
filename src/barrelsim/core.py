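"""Single-neuron dynamics: leaky integrate-and-fire with exponential-current synapses.

The membrane obeys ``tau_m dV/dt = E_L - V + R_m I`` and each synaptic
accumulator obeys ``tau_s dI/dt = -I`` between spikes, with every arriving
spike adding its weight to the accumulator as a discrete impulse. Two
accumulators are kept per neuron: ``I_e`` (excitatory, tau_se, always >= 0)
and ``I_i`` (inhibitory, tau_si, always <= 0); weights are signed at network
construction so the accumulators never change sign.

All quantities are carried in mV / nA / ms / MOhm, so that R_m * I is in mV
and w * tau_s is in pC.

Time advances on a fixed 1-ms clock. The per-step contract, shared with the
network engine, is:

1. deliver spikes emitted at the previous step into I_e / I_i;
2. advance V across the step;
3. decay I_e and I_i;
4. apply threshold and reset (inclusive comparison, ``V >= V_theta``).

Two membrane advances are provided. :func:`step_membrane` holds the total
current constant across the step (single-variable closed form).
:func:`propagate_membrane` uses the exact solution of the coupled
membrane/synapse linear system with the accumulators decaying within the
step; the grid trajectory it produces equals the continuous-time solution
sampled at grid points, and it is what the simulation engine uses.

Refractory convention: a spike at step t starts an absolute refractory
period of t_ref ms during which V is clamped to V_reset while the synaptic
currents continue to decay and accumulate. The timer is decremented at the
start of each membrane advance and the clamp applies only while the timer
remains positive afterwards, so the earliest possible re-spike is at
t + t_ref and the maximum sustained rate is 1000 / t_ref Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Tuple

import numpy as np

__all__ = [
    "as_seed_sequence",
    "InvalidParameterError",
    "NumericalError",
    "NeuronParams",
    "NeuronState",
    "L4E_PARAMS",
    "L23E_PARAMS",
    "decay_current",
    "add_spike_weights",
    "step_membrane",
    "propagate_membrane",
    "threshold_and_reset",
    "psc_charge",
    "membrane_coefficients",
]


def as_seed_sequence(seed) -> "np.random.SeedSequence":
    """Coerce an int / entropy list / SeedSequence into a SeedSequence."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


class InvalidParameterError(ValueError):
    """A physical parameter violates its domain (non-positive time constant, ...)."""


class NumericalError(RuntimeError):
    """A state variable became non-finite during integration."""


@dataclass(frozen=True)
class NeuronParams:
    """Biophysical constants of one LIF neuron.

    Attributes
    ----------
    E_L : float
        Equilibrium (resting) potential, mV.
    V_reset : float
        Post-spike reset potential, mV. Must lie below ``V_theta``.
    V_theta : float
        Spike threshold, mV (inclusive: V >= V_theta fires).
    tau_m : float
        Membrane time constant, ms.
    R_m : float
        Membrane resistance, MOhm.
    tau_se, tau_si : float
        Excitatory / inhibitory synaptic-current time constants, ms.
    t_ref : float
        Absolute refractory period, ms.
    """

    E_L: float
    V_reset: float
    V_theta: float
    tau_m: float
    R_m: float
    tau_se: float
    tau_si: float
    t_ref: float

    def __post_init__(self) -> None:
        for name in ("tau_m", "R_m", "tau_se", "tau_si"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be positive, got {getattr(self, name)}")
        if self.t_ref < 0:
            raise InvalidParameterError(f"t_ref must be non-negative, got {self.t_ref}")
        if not self.V_reset < self.V_theta:
            raise InvalidParameterError(
                f"V_reset ({self.V_reset}) must lie below V_theta ({self.V_theta})"
            )


#: Layer-4 excitatory cell constants (paired-recording estimates for the
#: granular layer of the rat barrel column). Inhibitory cells of the same
#: layer reuse these values.
L4E_PARAMS = NeuronParams(
    E_L=-66.0, V_reset=-66.0, V_theta=-40.0, tau_m=35.0, R_m=300.0,
    tau_se=5.0, tau_si=15.0, t_ref=10.0,
)

#: Layer-2/3 excitatory cell constants (supragranular layer).
L23E_PARAMS = NeuronParams(
    E_L=-72.0, V_reset=-72.0, V_theta=-40.0, tau_m=30.0, R_m=190.0,
    tau_se=5.0, tau_si=15.0, t_ref=10.0,
)


@dataclass
class NeuronState:
    """Dynamical variables of one neuron.

    ``I_e >= 0`` and ``I_i <= 0`` at all times (weights are signed at
    construction); while ``refrac_remaining > 0`` the membrane is clamped at
    ``V_reset``.
    """

    V: float
    I_e: float = 0.0
    I_i: float = 0.0
    refrac_remaining: float = 0.0


def decay_current(I: float, tau_s: float, dt: float) -> float:
    """Exponential decay of a synaptic-current accumulator over one step.

    Returns ``I * exp(-dt / tau_s)``; the sign of ``I`` is preserved.
    """
    if not tau_s > 0:
        raise InvalidParameterError(f"tau_s must be positive, got {tau_s}")
    if not dt > 0:
        raise InvalidParameterError(f"dt must be positive, got {dt}")
    return I * math.exp(-dt / tau_s)


def add_spike_weights(I: float, incoming_weights: Iterable[float]) -> float:
    """Deliver arriving spikes: each adds its synaptic weight to the accumulator.

    All weights must share the sign convention of the accumulator they
    target; an empty sequence returns ``I`` unchanged.
    """
    return I + sum(incoming_weights)


def step_membrane(state: NeuronState, params: NeuronParams, dt: float) -> NeuronState:
    """Advance V across one step with the total current held constant.

    If the neuron is refractory the timer is decremented by ``dt`` (floored
    at 0) and, while it remains positive, V stays clamped at ``V_reset``.
    Otherwise ``V' = E_L + R_m I_tot + (V - E_L - R_m I_tot) exp(-dt/tau_m)``
    with ``I_tot = I_e + I_i``. Synaptic currents are not modified here.
    """
    if not dt > 0:
        raise InvalidParameterError(f"dt must be positive, got {dt}")
    if not (math.isfinite(state.V) and math.isfinite(state.I_e) and math.isfinite(state.I_i)):
        raise NumericalError(f"non-finite neuron state: {state}")
    if state.refrac_remaining > 0:
        remaining = max(0.0, state.refrac_remaining - dt)
        if remaining > 0:
            return replace(state, V=params.V_reset, refrac_remaining=remaining)
        # refractory period elapses at this step boundary: integrate from reset
        state = replace(state, V=params.V_reset, refrac_remaining=0.0)
    V_inf = params.E_L + params.R_m * (state.I_e + state.I_i)
    V = V_inf + (state.V - V_inf) * math.exp(-dt / params.tau_m)
    return replace(state, V=V)


def membrane_coefficients(params: NeuronParams, dt: float) -> Tuple[float, float, float]:
    """Propagator coefficients (alpha, c_e, c_i) of the exact one-step map.

    With ``u = V - E_L`` and start-of-step accumulators I_e, I_i decaying at
    their own time constants within the step, the exact solution of the
    coupled linear system gives ``u' = alpha u + c_e I_e + c_i I_i`` where
    ``alpha = exp(-dt/tau_m)`` and, for each synapse class,
    ``c = R_m * tau_s/(tau_s - tau_m) * (exp(-dt/tau_s) - alpha)``
    (limit ``R_m * dt/tau_m * alpha`` when tau_s == tau_m).
    """
    alpha = math.exp(-dt / params.tau_m)

    def coeff(tau_s: float) -> float:
        if math.isclose(tau_s, params.tau_m, rel_tol=1e-12):
            return params.R_m * (dt / params.tau_m) * alpha
        return params.R_m * tau_s / (tau_s - params.tau_m) * (math.exp(-dt / tau_s) - alpha)

    return alpha, coeff(params.tau_se), coeff(params.tau_si)


def propagate_membrane(state: NeuronState, params: NeuronParams, dt: float) -> NeuronState:
    """Advance V across one step with the accumulators decaying within it.

    Exact coupled-system solution (exponential integration); refractory
    handling is identical to :func:`step_membrane`. Currents themselves are
    decayed separately by :func:`decay_current` per the step ordering.
    """
    if not dt > 0:
        raise InvalidParameterError(f"dt must be positive, got {dt}")
    if not (math.isfinite(state.V) and math.isfinite(state.I_e) and math.isfinite(state.I_i)):
        raise NumericalError(f"non-finite neuron state: {state}")
    if state.refrac_remaining > 0:
        remaining = max(0.0, state.refrac_remaining - dt)
        if remaining > 0:
            return replace(state, V=params.V_reset, refrac_remaining=remaining)
        state = replace(state, V=params.V_reset, refrac_remaining=0.0)
    alpha, c_e, c_i = membrane_coefficients(params, dt)
    u = state.V - params.E_L
    V = params.E_L + alpha * u + c_e * state.I_e + c_i * state.I_i
    return replace(state, V=V)


def threshold_and_reset(state: NeuronState, params: NeuronParams) -> Tuple[NeuronState, bool]:
    """Fire if ``V >= V_theta``: reset V and start the refractory period.

    Only called on non-refractory neurons; returns ``(new_state, spiked)``.
    """
    if state.V >= params.V_theta:
        return replace(state, V=params.V_reset, refrac_remaining=params.t_ref), True
    return state, False


def psc_charge(w: float, tau_s: float) -> float:
    """Charge of one exponential postsynaptic current: integral w exp(-t/tau_s) = w tau_s (pC)."""
    if not tau_s > 0:
        raise InvalidParameterError(f"tau_s must be positive, got {tau_s}")
    return w * tau_s
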