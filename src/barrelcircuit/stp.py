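"""Fitting Tsodyks parameters to PSP-amplitude trains and calibrating
synaptic weight scaling for the STP model version.

The fitter reproduces the experimental protocol: a presynaptic neuron fires
at a fixed rate onto a subthreshold postsynaptic neuron, the PSP amplitudes
are measured (with or without subtraction of the preceding-PSP overlap),
normalized to the first amplitude, and (U, F, D) are found by exhaustive
grid search minimizing the RMSE to the observed train.

Because the postsynaptic membrane is linear below threshold, the subtracted
amplitude of the n-th PSP is exactly proportional to the transmitted synaptic
amplitude u_n * x_n; subtraction-mode fitting therefore runs on the exact
event recursion, while onset-mode amplitudes are measured on the superposed
voltage trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dynamics import STPParams, stp_amplitude_sequence
from .params import NeuronParams, ParameterError, SynapseClass, psp_to_psc

U_GRID = np.round(np.arange(0.05, 1.0001, 0.05), 10)
FD_GRID = np.arange(0.0, 1000.0 + 1e-9, 20.0)


class MeasurementError(RuntimeError):
    """Postsynaptic neuron crossed threshold during a PSP-train measurement."""


@dataclass(frozen=True)
class PSPTrainObservation:
    presyn_rate: float  # spikes/s
    normalized_amplitudes: tuple[float, ...]
    subtraction_applied: bool = True

    def __post_init__(self):
        if self.presyn_rate <= 0:
            raise ParameterError("presyn_rate must be positive")
        if len(self.normalized_amplitudes) < 2:
            raise ParameterError("need at least two PSP amplitudes to fit")
        if abs(self.normalized_amplitudes[0] - 1.0) > 1e-9:
            raise ParameterError("amplitudes must be normalized to the first PSP")


@dataclass(frozen=True)
class STPFitResult:
    best: STPParams
    rmse: float
    grid_spec: str = "U: 0.05-1.0 step 0.05; F, D: 0-1000 ms step 20 ms"


@dataclass(frozen=True)
class WeightScalingResult:
    factor: float
    converged: bool
    final_deviation: float  # pA
    iterations: int = 0


def _psp_kernel(t: np.ndarray, post: NeuronParams, tau_syn: float) -> np.ndarray:
    """Voltage response (mV) to a unit (1 pA) exponential PSC at t = 0."""
    tm, ts, cm = post.tau_m, tau_syn, post.c_m
    t = np.asarray(t, float)
    if abs(tm - ts) < 1e-9:
        k = t / cm * np.exp(-t / tm)
    else:
        k = ts * tm / (cm * (ts - tm)) * (np.exp(-t / ts) - np.exp(-t / tm))
    return np.where(t >= 0, k, 0.0)


def simulate_psp_train(
    stp: STPParams | None,
    post_params: NeuronParams,
    synapse_class: SynapseClass,
    presyn_rate: float,
    n_spikes: int,
    subtraction: bool = True,
    weight_psp: float | None = None,
    dt: float = 0.1,
) -> np.ndarray:
    """Normalized PSP amplitudes of a presynaptic train at fixed rate.

    ``stp=None`` simulates a static synapse. The synaptic weight defaults to
    the class's mean PSP and must stay subthreshold from rest.
    """
    if presyn_rate <= 0 or n_spikes < 2:
        raise ParameterError("presyn_rate must be > 0 and n_spikes >= 2")
    interval = 1000.0 / presyn_rate
    spike_times = np.arange(n_spikes) * interval
    w_static = psp_to_psc(
        weight_psp if weight_psp is not None else synapse_class.psp_mean,
        post_params.c_m, post_params.tau_m, synapse_class.tau_syn,
    )
    if stp is None:
        amps = np.full(n_spikes, w_static)
    else:
        amps = stp_amplitude_sequence(stp, spike_times, w_static)

    window = np.arange(0.0, min(interval, 100.0) + dt, dt)
    kernel_win = _psp_kernel(window, post_params, synapse_class.tau_syn)

    if subtraction:
        # V_{n-train} - V_{(n-1)-train} is, by linearity, the response to the
        # n-th PSC alone: peak = a_n * max(kernel)
        peaks = amps * kernel_win.max()
    else:
        t_end = spike_times[-1] + window[-1]
        grid = np.arange(0.0, t_end + dt, dt)
        v = np.zeros_like(grid)
        for t_sp, a in zip(spike_times, amps):
            v += a * _psp_kernel(grid - t_sp, post_params, synapse_class.tau_syn)
        if np.any(post_params.v_rest + v >= post_params.v_th):
            raise MeasurementError("postsynaptic neuron crossed threshold")
        peaks = np.empty(n_spikes)
        for i, t_sp in enumerate(spike_times):
            i0 = int(round(t_sp / dt))
            seg = v[i0 : i0 + window.size]
            peaks[i] = seg.max() - v[i0]
    if np.any(post_params.v_rest + peaks >= post_params.v_th):
        raise MeasurementError("postsynaptic neuron crossed threshold")
    return peaks / peaks[0]


def _grid_amplitude_matrix(n_spikes: int, interval: float) -> tuple[np.ndarray, ...]:
    """Normalized u_n x_n sequences for every (U, F, D) grid point.

    Returns (U_flat, F_flat, D_flat, amp_norm[G, n_spikes]) with the grid
    flattened in U-major, then F, then D order (deterministic tie-breaking:
    np.argmin picks the first minimal entry, i.e. smallest U, then F, then D).
    """
    Ug, Fg, Dg = np.meshgrid(U_GRID, FD_GRID, FD_GRID, indexing="ij")
    U = Ug.ravel()
    eF = np.where(Fg.ravel() > 0, np.exp(-interval / np.where(Fg.ravel() > 0, Fg.ravel(), 1.0)), 0.0)
    eD = np.where(Dg.ravel() > 0, np.exp(-interval / np.where(Dg.ravel() > 0, Dg.ravel(), 1.0)), 0.0)
    G = U.size
    u = np.zeros(G)
    x = np.ones(G)
    amps = np.empty((G, n_spikes))
    for n in range(n_spikes):
        if n > 0:
            u = u * eF
            x = 1.0 + (x - 1.0) * eD
        u = u + U * (1.0 - u)
        amps[:, n] = u * x
        x = x * (1.0 - u)
    amps /= amps[:, :1]
    return U, Fg.ravel(), Dg.ravel(), amps


def fit_stp_parameters(
    observation: PSPTrainObservation,
    post_params: NeuronParams | None = None,
    synapse_class: SynapseClass | None = None,
) -> STPFitResult:
    """Exhaustive (U, F, D) grid search minimizing amplitude RMSE.

    Subtraction-mode observations are fitted on the exact event recursion
    (normalized subtracted amplitudes equal normalized u_n x_n). Onset-mode
    observations additionally require the postsynaptic membrane parameters to
    evaluate the overlapping voltage trace for each candidate.
    """
    obs = np.asarray(observation.normalized_amplitudes, float)
    n_spikes = obs.size
    interval = 1000.0 / observation.presyn_rate
    U, F, D, amps = _grid_amplitude_matrix(n_spikes, interval)

    if not observation.subtraction_applied:
        if post_params is None or synapse_class is None:
            raise ParameterError("onset-mode fitting needs postsynaptic parameters")
        dt = 0.1
        window = np.arange(0.0, min(interval, 100.0) + dt, dt)
        m = window.size
        # response matrix R[k, j]: onset-referenced contribution of a PSC
        # fired k intervals before the measured one, evaluated on the window
        ker = lambda t: _psp_kernel(t, post_params, synapse_class.tau_syn)
        R = np.empty((n_spikes, m))
        for k in range(n_spikes):
            off = k * interval
            R[k] = ker(window + off) - ker(np.array([off]))
        sim = np.empty((amps.shape[0], n_spikes))
        for n in range(n_spikes):
            # windows of spike n superpose contributions of spikes <= n
            contrib = amps[:, : n + 1] @ R[: n + 1][::-1]
            sim[:, n] = contrib.max(axis=1)
        sim /= sim[:, :1]
        amps = sim

    rmse = np.sqrt(np.mean((amps - obs[None, :]) ** 2, axis=1))
    i = int(np.argmin(rmse))
    return STPFitResult(
        best=STPParams(U=float(U[i]), F=float(F[i]), D=float(D[i])),
        rmse=float(rmse[i]),
    )


def calibrate_weight_scaling(
    stp: STPParams | None,
    presyn_rate: float,
    target_psc: float,
    window_ms: float = 5000.0,
    tol_pa: float = 0.1,
    max_iter: int = 100,
) -> WeightScalingResult:
    """Scale the initial weight so the effective amplitude at the final spike
    of a fixed-ISI 5 s pair simulation matches the static-model PSC.

    Static projections return factor 1 without calibration. Uses proportional
    updates factor <- factor * target/observed; reports the best iterate if
    the 0.1 pA tolerance is not reached within ``max_iter``.
    """
    if stp is None:
        return WeightScalingResult(1.0, True, 0.0, 0)
    if presyn_rate > 0.2:
        interval = 1000.0 / presyn_rate
        spike_times = np.arange(interval, window_ms + 1e-9, interval)
    else:
        spike_times = np.array([window_ms / 2.0])  # effectively a single spike
    factor = 1.0
    best = (math.inf, 1.0, 0)
    for it in range(1, max_iter + 1):
        w = factor * target_psc
        observed = stp_amplitude_sequence(stp, spike_times, w)[-1]
        dev = abs(observed - target_psc)
        if dev < best[0]:
            best = (dev, factor, it)
        if dev < tol_pa:
            return WeightScalingResult(factor, True, float(dev), it)
        factor *= target_psc / observed
    return WeightScalingResult(best[1], False, float(best[0]), best[2])


def scale_thalamic_weight(w: float, u_initial: float) -> float:
    """Initial-weight scaling for the transient thalamic input: w' = w/u so
    that the first transmitted amplitude u * w' equals w."""
    if u_initial <= 0:
        raise ParameterError("u_initial must be positive")
    return w / u_initial


def steady_state_release(stp: STPParams, presyn_rate: float) -> float:
    """lim u_n x_n for a periodic train (fixed point of the per-spike map)."""
    T = 1000.0 / presyn_rate
    eF = math.exp(-T / stp.F) if stp.F > 0 else 0.0
    eD = math.exp(-T / stp.D) if stp.D > 0 else 0.0
    u = 0.0
    x = 1.0
    amp_prev = math.inf
    for _ in range(100000):
        u = u * eF + stp.U * (1.0 - u * eF)
        x = 1.0 + (x - 1.0) * eD
        amp = u * x
        x = x * (1.0 - u)
        if abs(amp - amp_prev) < 1e-14:
            return amp
        amp_prev = amp
    return amp_prev
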