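"""Clock-driven network simulation on a fixed 1-ms grid.

At each step t the engine (1) delivers stimulus spikes stamped t and network
spikes emitted at t-1 through the realised connectivity into the target
accumulators, (2) advances every membrane across the step with the exact
propagator of the coupled membrane/synapse system, (3) decays the synaptic
accumulators, and (4) applies threshold and reset, recording cortical
spikes. Every projection has a one-step conduction delay, so a spike never
affects its targets at its own step.

Membranes start at E_L with zero synaptic currents unless an initial
voltage vector is supplied; the run is a pure function of (model, stimulus,
config).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np

from .core import (InvalidParameterError, NumericalError, as_seed_sequence,
                   membrane_coefficients)
from .network import NetworkModel
from .records import SpikeRecord

__all__ = ["SimConfig", "run", "run_trials"]

logger = logging.getLogger("barrelsim")


@dataclass(frozen=True)
class SimConfig:
    """Run parameters. ``dt`` is fixed at 1 ms by the clocked delivery contract."""

    duration: float
    dt: float = 1.0
    check_finite: bool = True
    initial_V: Optional[np.ndarray] = None   # per-cortical-neuron override, model order
    include_stimulus_in_record: bool = False  # merge source spikes into the output

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise InvalidParameterError("duration must be positive")
        if self.dt != 1.0:
            raise InvalidParameterError("the engine runs on a fixed 1-ms clock")


class _Compiled:
    """Connectivity in CSR-by-source form plus flattened per-neuron constants.

    Source (thalamic) neurons participate in the global index space with
    inert dynamics (infinite threshold, zero coupling) so that all state
    arrays are flat; they are never postsynaptic in the models built here.
    """

    def __init__(self, model: NetworkModel, dt: float):
        n = model.n_total
        self.n = n
        # per-neuron constants
        self.E_L = np.zeros(n)
        self.V_reset = np.zeros(n)
        self.V_theta = np.full(n, np.inf)
        self.t_ref = np.zeros(n)
        self.alpha = np.ones(n)
        self.c_e = np.zeros(n)
        self.c_i = np.zeros(n)
        self.beta_e = np.zeros(n)
        self.beta_i = np.zeros(n)
        self.cortical = np.zeros(n, dtype=bool)
        for pop in model.populations:
            if pop.params is None:
                continue
            sl = slice(model.offset(pop.name), model.offset(pop.name) + pop.size)
            p = pop.params
            alpha, c_e, c_i = membrane_coefficients(p, dt)
            self.E_L[sl] = p.E_L
            self.V_reset[sl] = p.V_reset
            self.V_theta[sl] = p.V_theta
            self.t_ref[sl] = p.t_ref
            self.alpha[sl] = alpha
            self.c_e[sl] = c_e
            self.c_i[sl] = c_i
            self.beta_e[sl] = np.exp(-dt / p.tau_se)
            self.beta_i[sl] = np.exp(-dt / p.tau_si)
            self.cortical[sl] = True
        # CSR adjacency per accumulator sign, keyed by global source id
        self.exc = self._csr(model, positive=True)
        self.inh = self._csr(model, positive=False)

    @staticmethod
    def _csr(model: NetworkModel, positive: bool):
        pres, posts, ws = [], [], []
        for cs in model.connections:
            if len(cs) == 0 or cs.spec.w == 0.0:
                continue
            if (cs.spec.w > 0) != positive:
                continue
            pres.append(cs.pre_idx.astype(np.int64) + model.offset(cs.spec.pre))
            posts.append(cs.post_idx.astype(np.int32) + np.int32(model.offset(cs.spec.post)))
            ws.append(np.full(len(cs), cs.spec.w, dtype=np.float32))
        n = model.n_total
        if not pres:
            return (np.zeros(n + 1, dtype=np.int64),
                    np.empty(0, dtype=np.int32), np.empty(0, dtype=np.float32))
        pre = np.concatenate(pres)
        order = np.argsort(pre, kind="stable")
        post = np.concatenate(posts)[order]
        w = np.concatenate(ws)[order]
        indptr = np.zeros(n + 1, dtype=np.int64)
        np.cumsum(np.bincount(pre, minlength=n), out=indptr[1:])
        return indptr, post, w


def _compiled(model: NetworkModel, dt: float) -> _Compiled:
    cached = getattr(model, "_compiled_cache", None)
    if cached is None:
        cached = _Compiled(model, dt)
        model._compiled_cache = cached
    return cached


def _deliver(acc: np.ndarray, csr, spikers: np.ndarray) -> None:
    indptr, post, w = csr
    if post.size == 0 or spikers.size == 0:
        return
    starts = indptr[spikers]
    stops = indptr[spikers + 1]
    nz = stops > starts
    if not np.any(nz):
        return
    posts = np.concatenate([post[a:b] for a, b in zip(starts[nz], stops[nz])])
    ws = np.concatenate([w[a:b] for a, b in zip(starts[nz], stops[nz])])
    acc += np.bincount(posts, weights=ws, minlength=acc.size)


def run(model: NetworkModel, stimulus: Optional[SpikeRecord],
        config: SimConfig) -> SpikeRecord:
    """Simulate a model under a pre-generated stimulus record.

    ``stimulus`` holds source-population spikes with global ids; its
    duration must cover the configured one. Returns the cortical
    :class:`SpikeRecord` (source spikes are inputs, not outputs).
    """
    dt = config.dt
    n_steps = int(round(config.duration / dt))
    comp = _compiled(model, dt)
    n = comp.n

    if stimulus is not None and stimulus.duration < config.duration:
        raise InvalidParameterError(
            f"stimulus covers {stimulus.duration} ms but the run needs {config.duration} ms")
    if stimulus is not None and len(stimulus):
        stim_steps = np.round(stimulus.times / dt).astype(np.int64)
        stim_ptr = np.searchsorted(stim_steps, np.arange(n_steps + 1))
        stim_ids = stimulus.ids.astype(np.int64)
    else:
        stim_ptr = np.zeros(n_steps + 1, dtype=np.int64)
        stim_ids = np.empty(0, dtype=np.int64)

    V = comp.E_L.copy()
    if config.initial_V is not None:
        init = np.asarray(config.initial_V, dtype=np.float64)
        if init.size != int(np.count_nonzero(comp.cortical)):
            raise InvalidParameterError("initial_V must have one entry per cortical neuron")
        V[comp.cortical] = init
    I_e = np.zeros(n)
    I_i = np.zeros(n)
    refrac = np.zeros(n)

    prev_spikes = np.empty(0, dtype=np.int64)
    spike_times: List[np.ndarray] = []
    spike_ids: List[np.ndarray] = []

    for t in range(n_steps):
        # 1. deliver: stimulus spikes stamped t plus network spikes from t-1
        src = stim_ids[stim_ptr[t]:stim_ptr[t + 1]]
        spikers = np.concatenate([src, prev_spikes]) if prev_spikes.size else src
        _deliver(I_e, comp.exc, spikers)
        _deliver(I_i, comp.inh, spikers)

        # 2. membrane update (exact propagator; post-delivery currents)
        was_refrac = refrac > 0
        np.maximum(refrac - dt, 0.0, out=refrac)
        clamped = refrac > 0
        V = comp.E_L + comp.alpha * (V - comp.E_L) + comp.c_e * I_e + comp.c_i * I_i
        V[clamped] = comp.V_reset[clamped]
        if config.check_finite and not np.all(np.isfinite(V[comp.cortical])):
            bad = int(np.flatnonzero(~np.isfinite(V) & comp.cortical)[0])
            raise NumericalError(f"non-finite membrane potential at step {t}, neuron {bad}")

        # 3. decay the synaptic accumulators
        I_e *= comp.beta_e
        I_i *= comp.beta_i

        # 4. threshold and reset
        spk = np.flatnonzero((V >= comp.V_theta) & ~clamped)
        if spk.size:
            V[spk] = comp.V_reset[spk]
            refrac[spk] = comp.t_ref[spk]
            spike_times.append(np.full(spk.size, t * dt))
            spike_ids.append(spk.astype(np.int32))
        prev_spikes = spk

    times = np.concatenate(spike_times) if spike_times else np.empty(0)
    ids = np.concatenate(spike_ids) if spike_ids else np.empty(0, dtype=np.int32)
    if config.include_stimulus_in_record and stimulus is not None and len(stimulus):
        keep = stimulus.times < config.duration
        times = np.concatenate([times, stimulus.times[keep]])
        ids = np.concatenate([ids, stimulus.ids[keep].astype(np.int32)])
    record = SpikeRecord.from_events(times, ids, config.duration,
                                     model.population_entries(), dt)
    if logger.isEnabledFor(logging.INFO):
        counts = record.counts_per_population()
        logger.info("run complete: %d ms, spikes per population %s",
                    n_steps, {k: v for k, v in counts.items() if v})
    return record


def run_trials(model: NetworkModel, stimulus_factory: Callable[[object], SpikeRecord],
               n_trials: int, config: SimConfig,
               base_seed=0) -> List[SpikeRecord]:
    """Repeat a run over fresh stimulus realisations with fixed connectivity.

    ``stimulus_factory(seed)`` builds one trial's stimulus record. Per-trial
    seeds are spawned up front from ``base_seed``, and each trial restarts
    from the standard initial state, so trial outputs are independent of
    execution order.
    """
    if n_trials < 1:
        raise InvalidParameterError("n_trials must be >= 1")
    seeds = as_seed_sequence(base_seed).spawn(n_trials)
    return [run(model, stimulus_factory(s), config) for s in seeds]
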