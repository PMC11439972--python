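"""LIF + short-term-plasticity dynamics and the network simulation front end.

The scalar operations (`lif_update`, `stp_spike_update`) define the single
step contracts and serve as readable references; `simulate_network` executes
the same dynamics over a whole network through the numba kernel in
``_kernel``. Subthreshold integration is exact per step (exponential
propagators); threshold crossings are detected at step boundaries; a spike
resets the membrane to ``v_reset`` and clamps it there for the 2.0 ms
refractory period while synaptic currents keep evolving.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import math

import numpy as np
import pandas as pd

from . import _kernel
from .params import SIM_RESOLUTION_MS, NeuronParams, ParameterError

STP_VARIANT_DECAY_TO_ZERO = _kernel.VARIANT_DECAY_TO_ZERO
STP_VARIANT_DECAY_TO_U = _kernel.VARIANT_DECAY_TO_U


@dataclass(frozen=True)
class STPParams:
    """Tsodyks synapse parameters: release parameter U, facilitation time
    constant F (ms), depression time constant D (ms). F or D equal to zero
    means instantaneous relaxation of the corresponding state variable."""

    U: float
    F: float
    D: float

    def __post_init__(self):
        if not 0.0 < self.U <= 1.0:
            raise ParameterError("U must be in (0, 1]")
        if self.F < 0.0 or self.D < 0.0:
            raise ParameterError("F and D must be non-negative")


@dataclass
class STPState:
    """Running release probability u, available resources x, and the time of
    the last presynaptic spike (-inf before the first spike). u starts at 0
    so that the facilitation bump at the first spike yields release U."""

    u: float = 0.0
    x: float = 1.0
    t_last: float = -math.inf


@dataclass
class NeuronState:
    v: float
    i_exc: float = 0.0
    i_inh: float = 0.0
    refr_remaining: float = 0.0


def stp_spike_update(
    state: STPState,
    params: STPParams,
    dt_since_last_spike: float,
    w_static: float,
    variant: int = STP_VARIANT_DECAY_TO_ZERO,
) -> tuple[float, STPState]:
    """Advance an STP synapse across one presynaptic spike.

    Between spikes u relaxes (toward 0 in the default variant, toward U in
    the alternative) with time constant F and x recovers toward 1 with time
    constant D. At the spike the facilitation bump u <- u + U(1-u) is applied
    first, the transmitted amplitude is w_static * u * x, and resources are
    consumed, x <- x(1-u). The first spike therefore transmits w_static * U.
    """
    if dt_since_last_spike < 0:
        raise ParameterError("dt_since_last_spike must be >= 0")
    u, x = state.u, state.x
    if math.isfinite(state.t_last):
        if variant == STP_VARIANT_DECAY_TO_ZERO:
            u = u * math.exp(-dt_since_last_spike / params.F) if params.F > 0 else 0.0
        else:
            u = (
                params.U + (u - params.U) * math.exp(-dt_since_last_spike / params.F)
                if params.F > 0
                else params.U
            )
        x = 1.0 + (x - 1.0) * math.exp(-dt_since_last_spike / params.D) if params.D > 0 else 1.0
    u = u + params.U * (1.0 - u)
    amp = w_static * u * x
    x = x * (1.0 - u)
    t = (state.t_last if math.isfinite(state.t_last) else 0.0) + dt_since_last_spike
    return amp, STPState(u=u, x=x, t_last=t)


def stp_amplitude_sequence(
    params: STPParams,
    spike_times: Sequence[float],
    w_static: float = 1.0,
    variant: int = STP_VARIANT_DECAY_TO_ZERO,
) -> np.ndarray:
    """Transmitted amplitudes of an STP synapse over a spike train (exact
    event-based recursion; the oracle form of the kernel's update)."""
    amps = np.empty(len(spike_times))
    state = STPState()
    prev = None
    for i, t in enumerate(spike_times):
        gap = 0.0 if prev is None else t - prev
        amps[i], state = stp_spike_update(state, params, gap, w_static, variant)
        prev = t
    return amps


def _propagators(params: NeuronParams, tau_syn: float, dt: float) -> tuple[float, float]:
    """(current->voltage coupling, current decay) over one step."""
    pm = math.exp(-dt / params.tau_m)
    ps = math.exp(-dt / tau_syn)
    if abs(params.tau_m - tau_syn) < 1e-9:
        k = dt / params.c_m * pm
    else:
        k = (
            tau_syn
            * params.tau_m
            / (params.c_m * (tau_syn - params.tau_m))
            * (ps - pm)
        )
    return k, ps


def lif_update(
    state: NeuronState,
    params: NeuronParams,
    dt: float,
    delivered_exc: float = 0.0,
    delivered_inh: float = 0.0,
    tau_syn_exc: float = 2.0,
    tau_syn_inh: float = 4.0,
) -> tuple[NeuronState, bool]:
    """One exact-propagator step of a LIF neuron with exponential PSCs.

    Delivered PSC amplitudes (pA) add instantaneously to the matching
    current at the start of the step. Returns the new state and a spike flag.
    """
    i_e = state.i_exc + delivered_exc
    i_i = state.i_inh + delivered_inh
    k_e, d_e = _propagators(params, tau_syn_exc, dt)
    k_i, d_i = _propagators(params, tau_syn_inh, dt)
    if state.refr_remaining > 0:
        v = params.v_reset
        refr = max(0.0, state.refr_remaining - dt)
    else:
        pm = math.exp(-dt / params.tau_m)
        v = params.v_rest + (state.v - params.v_rest) * pm + i_e * k_e + i_i * k_i
        refr = 0.0
    i_e *= d_e
    i_i *= d_i
    spike = refr == 0.0 and state.refr_remaining == 0.0 and v >= params.v_th
    if spike:
        v = params.v_reset
        refr = params.tau_ref
    return NeuronState(v=v, i_exc=i_e, i_inh=i_i, refr_remaining=refr), spike


@dataclass
class SpikeTrainSet:
    """All spike times of one simulation with population labels.

    times are in ms, sorted chronologically as emitted by the simulator;
    ``pop_of[i]`` indexes ``pop_names`` for neuron i.
    """

    times: np.ndarray
    senders: np.ndarray
    n_neurons: int
    pop_of: np.ndarray
    pop_names: tuple[str, ...]
    t_start: float
    t_stop: float

    def in_window(self, t0: float, t1: float) -> "SpikeTrainSet":
        m = (self.times >= t0) & (self.times < t1)
        return SpikeTrainSet(
            self.times[m], self.senders[m], self.n_neurons, self.pop_of,
            self.pop_names, t0, t1,
        )

    def neurons_of_population(self, name: str) -> np.ndarray:
        idx = self.pop_names.index(name)
        return np.nonzero(self.pop_of == idx)[0]

    def spike_times_by_neuron(self) -> list[np.ndarray]:
        out = [np.empty(0)] * self.n_neurons
        order = np.argsort(self.senders, kind="stable")
        senders = self.senders[order]
        times = self.times[order]
        bounds = np.searchsorted(senders, np.arange(self.n_neurons + 1))
        for i in range(self.n_neurons):
            out[i] = np.sort(times[bounds[i] : bounds[i + 1]])
        return out

    def save(self, path: str | Path) -> None:
        path = Path(path)
        pd.DataFrame({"neuron": self.senders, "time_ms": self.times}).to_csv(
            path, sep="\t", index=False
        )
        sidecar = path.with_suffix(path.suffix + ".populations.tsv")
        pd.DataFrame(
            {"neuron": np.arange(self.n_neurons),
             "population": [self.pop_names[i] for i in self.pop_of]}
        ).to_csv(sidecar, sep="\t", index=False)


@dataclass
class Network:
    """An assembled network in kernel-ready array form.

    Sources ``0..n_neurons-1`` are cortical LIF neurons; ids from
    ``n_neurons`` up are external spike sources (thalamic relay cells). All
    delays are on the 0.1 ms grid (in steps).
    """

    pop_of: np.ndarray
    pop_names: tuple[str, ...]
    tau_m: np.ndarray
    c_m: np.ndarray
    v_rest: np.ndarray
    v_th: np.ndarray
    v_reset: np.ndarray
    tau_ref: np.ndarray
    # CSR synapses over n_sources = n_neurons + n_external
    indptr: np.ndarray
    syn_tgt: np.ndarray
    syn_w: np.ndarray
    syn_delay_steps: np.ndarray
    syn_is_exc: np.ndarray
    syn_has_stp: np.ndarray
    syn_U: np.ndarray
    syn_F: np.ndarray
    syn_D: np.ndarray
    n_external: int = 0
    stp_variant: int = STP_VARIANT_DECAY_TO_ZERO
    tau_syn_exc: float = 2.0
    tau_syn_inh: float = 4.0
    # per-neuron background drive
    bg_rate: np.ndarray | None = None
    bg_w: np.ndarray | None = None

    @property
    def n_neurons(self) -> int:
        return self.pop_of.shape[0]

    def population_sizes(self) -> dict[str, int]:
        return {
            name: int(np.sum(self.pop_of == i)) for i, name in enumerate(self.pop_names)
        }


@dataclass
class SimulationInputs:
    """Time-varying inputs for one run: an optional gated Poisson stimulus
    (per-step rate, spikes/s, shared by all masked neurons) and scheduled
    external-source spikes (step indices paired with source ids)."""

    stim_rate_per_step: np.ndarray | None = None
    stim_mask: np.ndarray | None = None
    stim_w: np.ndarray | None = None
    ext_steps: np.ndarray | None = None
    ext_ids: np.ndarray | None = None


def simulate_network(
    network: Network,
    duration: float,
    seed: int,
    inputs: SimulationInputs | None = None,
    initial_v: str | np.ndarray = "uniform",
    record_v: Sequence[int] = (),
    dt: float = SIM_RESOLUTION_MS,
) -> tuple[SpikeTrainSet, np.ndarray]:
    """Simulate ``duration`` ms; returns (spikes, recorded voltages).

    Bitwise reproducible for a given (network, inputs, seed). Initial
    membrane potentials are drawn uniformly between rest and threshold
    (seeded) unless ``initial_v`` is "rest" or an explicit array.
    """
    n = network.n_neurons
    n_steps = int(round(duration / dt))
    if np.any(network.syn_delay_steps < 1):
        raise ParameterError("all delays must be at least one simulation step")

    p_v = np.exp(-dt / network.tau_m)
    k_e = np.empty(n)
    k_i = np.empty(n)
    for i in range(n):
        prm = NeuronParams(
            tau_m=network.tau_m[i], c_m=network.c_m[i],
            v_rest=network.v_rest[i], v_th=network.v_th[i],
            v_reset=network.v_reset[i],
        )
        k_e[i], _ = _propagators(prm, network.tau_syn_exc, dt)
        k_i[i], _ = _propagators(prm, network.tau_syn_inh, dt)
    d_e = np.full(n, math.exp(-dt / network.tau_syn_exc))
    d_i = np.full(n, math.exp(-dt / network.tau_syn_inh))
    ref_steps = np.rint(network.tau_ref / dt).astype(np.int64)

    rng = np.random.default_rng(seed)
    if isinstance(initial_v, str):
        if initial_v == "uniform":
            v0 = network.v_rest + rng.random(n) * (network.v_th - network.v_rest)
        elif initial_v == "rest":
            v0 = network.v_rest.copy()
        else:
            raise ParameterError(f"unknown initial_v mode {initial_v!r}")
    else:
        v0 = np.asarray(initial_v, float).copy()

    bg_lam = (
        network.bg_rate * dt / 1000.0 if network.bg_rate is not None else np.zeros(n)
    )
    bg_w = network.bg_w if network.bg_w is not None else np.zeros(n)

    inputs = inputs or SimulationInputs()
    if inputs.stim_rate_per_step is not None:
        stim_lam_t = np.asarray(inputs.stim_rate_per_step, float) * dt / 1000.0
        if stim_lam_t.shape[0] != n_steps:
            raise ParameterError("stimulus schedule length must match n_steps")
        stim_mask = np.asarray(inputs.stim_mask, np.uint8)
        stim_w = np.asarray(inputs.stim_w, float)
    else:
        stim_lam_t = np.zeros(n_steps)
        stim_mask = np.zeros(n, np.uint8)
        stim_w = np.zeros(n)

    if inputs.ext_steps is not None:
        order = np.argsort(inputs.ext_steps, kind="stable")
        ext_steps = np.asarray(inputs.ext_steps, np.int64)[order]
        ext_ids = np.asarray(inputs.ext_ids, np.int64)[order]
    else:
        ext_steps = np.empty(0, np.int64)
        ext_ids = np.empty(0, np.int64)

    n_syn = network.syn_w.shape[0]
    kernel_seed = int(seed) % (2**31 - 1)
    spk_t, spk_id, v_rec = _kernel.run_network(
        n_steps, dt, kernel_seed,
        p_v, k_e, k_i, d_e, d_i,
        network.v_rest, network.v_th, network.v_reset, ref_steps,
        v0,
        network.indptr, network.syn_tgt, network.syn_w,
        network.syn_delay_steps, network.syn_is_exc,
        network.syn_has_stp, network.syn_U, network.syn_F, network.syn_D,
        np.zeros(n_syn), np.ones(n_syn), np.full(n_syn, -1.0),
        network.stp_variant,
        bg_lam, bg_w, stim_lam_t, stim_mask, stim_w,
        ext_steps, ext_ids,
        np.asarray(record_v, np.int64),
    )
    spikes = SpikeTrainSet(
        times=spk_t, senders=spk_id, n_neurons=n, pop_of=network.pop_of,
        pop_names=network.pop_names, t_start=0.0, t_stop=duration,
    )
    return spikes, (v_rec if len(record_v) else np.empty((0, 0)))
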