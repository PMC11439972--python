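"""External drive: background Poisson input, cell-type-specific stimulation,
and the transient thalamic (VPM) relay population.

Background input is one independent homogeneous Poisson source per neuron
with a fixed 0.5 mV EPSP and a cell-type-specific rate; it is present in
every simulation. Stimulation adds a second, gated Poisson source to one
cell type in one layer (1 s on / 1 s off, repeated per level). Thalamic
input is a population of relay cells firing inhomogeneous-Poisson trains
that follow a log-normal-shaped transient rate profile, repeated every
second.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .params import (
    SIM_RESOLUTION_MS,
    ConfigurationError,
    ParameterError,
    load_table,
)

STIM_MAX_RATE = {"Exc": 1000.0, "PV": 1000.0, "SOM": 200.0, "VIP": 200.0}


@dataclass(frozen=True)
class BackgroundConfig:
    """Cell-type-specific background rates (spikes/s), fixed EPSP and delay."""

    rates: dict
    epsp: float = 0.5
    delay: float = 0.1

    def rate_of(self, cell_type: str) -> float:
        if cell_type not in self.rates:
            raise ConfigurationError(f"missing background rate for {cell_type}")
        return self.rates[cell_type]


def generate_poisson_trains(
    rate: float, n_sources: int, duration_ms: float, seed: int
) -> list[np.ndarray]:
    """Independent homogeneous Poisson spike trains (ms), one per source.

    This is the explicit-train form of the background generator (used for
    replay and statistical tests); during network simulation the same drive
    is drawn step-wise inside the kernel from the identical per-neuron rate.
    """
    rng = np.random.default_rng(seed)
    lam = rate / 1000.0
    out = []
    for _ in range(n_sources):
        n = rng.poisson(lam * duration_ms)
        out.append(np.sort(rng.random(n) * duration_ms))
    return out


def default_stimulus_levels(cell_type: str) -> tuple[float, ...]:
    """Nine stimulation rates: zero plus eight equally spaced levels up to
    the cell-type maximum (1000 spikes/s for Exc and PV, 200 for SOM and
    VIP)."""
    top = STIM_MAX_RATE[cell_type]
    return tuple(top * i / 8.0 for i in range(9))


@dataclass(frozen=True)
class StimulusProtocol:
    target_population: str  # e.g. "L2/3 SOM"
    levels: tuple[float, ...]
    on_duration: float = 1000.0
    off_duration: float = 1000.0
    repeats: int = 20
    epsp: float = 0.5

    def __post_init__(self):
        if 0.0 not in self.levels:
            raise ParameterError("levels must include 0")
        if max(self.levels) > 1000.0:
            raise ParameterError("stimulation rate must not exceed 1000 spikes/s")

    @property
    def cycle_ms(self) -> float:
        return self.on_duration + self.off_duration

    def total_duration(self, warmup_ms: float) -> float:
        return warmup_ms + len(self.levels) * self.repeats * self.cycle_ms


def build_stimulus_schedule(
    protocol: StimulusProtocol, warmup_ms: float, dt: float = SIM_RESOLUTION_MS
) -> np.ndarray:
    """Per-step stimulus rate (spikes/s): levels in ascending order, each
    repeated ``repeats`` times as 1 s on / 1 s off cycles after the warmup."""
    n_steps = int(round(protocol.total_duration(warmup_ms) / dt))
    sched = np.zeros(n_steps)
    t = warmup_ms
    for level in sorted(protocol.levels):
        for _ in range(protocol.repeats):
            i0 = int(round(t / dt))
            i1 = int(round((t + protocol.on_duration) / dt))
            sched[i0:i1] = level
            t += protocol.cycle_ms
    return sched


def stimulus_onsets(protocol: StimulusProtocol, warmup_ms: float) -> dict[float, np.ndarray]:
    """On-window start times (ms) per level, in schedule order."""
    out = {}
    t = warmup_ms
    for level in sorted(protocol.levels):
        out[level] = np.array([t + k * protocol.cycle_ms for k in range(protocol.repeats)])
        t += protocol.repeats * protocol.cycle_ms
    return out


# ---------------------------------------------------------------------------
# thalamic input


def lognormal_rate(t_ms: np.ndarray, amplitude: float, t0: float, mu: float,
                   sigma: float) -> np.ndarray:
    """r(t) = A exp(-(ln(t-t0)-mu)^2/(2 sigma^2))/(t-t0) for t > t0, else 0."""
    t = np.asarray(t_ms, float)
    tau = t - t0
    out = np.zeros_like(t)
    m = tau > 0
    out[m] = amplitude * np.exp(-((np.log(tau[m]) - mu) ** 2) / (2 * sigma**2)) / tau[m]
    return out


def fit_thalamic_time_course(
    t_ms: np.ndarray, rates: np.ndarray
) -> tuple[float, float, float, float]:
    """Least-squares fit of the log-normal rate form; returns (A, t0, mu, sigma)."""
    t_ms = np.asarray(t_ms, float)
    rates = np.asarray(rates, float)
    if t_ms.size < 4:
        raise ParameterError("need at least 4 samples")
    if np.any(rates < 0):
        raise ParameterError("rates must be non-negative")
    if np.all(rates == 0):
        return 0.0, float(t_ms.min()), 0.0, 1.0
    peak_t = float(t_ms[np.argmax(rates)])
    p0 = [float(rates.max() * max(peak_t, 1.0)), max(t_ms.min() - 1.0, 0.0),
          math.log(max(peak_t, 1.0)), 0.7]
    popt, _ = curve_fit(
        lognormal_rate, t_ms, rates, p0=p0,
        bounds=([0.0, -np.inf, -10.0, 1e-3], [np.inf, t_ms.min() - 1e-9, 10.0, 10.0]),
        maxfev=20000,
    )
    return tuple(float(v) for v in popt)


def default_thalamic_profile() -> dict[str, float]:
    df = load_table("thalamic_profile.csv")
    return {row["param"]: float(row["value"]) for _, row in df.iterrows()}


@dataclass(frozen=True)
class ThalamicInputSpec:
    n_th: int = 230
    amplitude: float = 0.0
    t0: float = 1.0
    mu: float = 1.6
    sigma: float = 0.7
    inter_stimulus_interval: float = 1000.0
    repeats: int = 10
    time_factor: float = 1.0
    som_attenuation: float = 0.5

    @classmethod
    def from_packaged_profile(cls, n_th: int = 230, repeats: int = 10,
                              time_factor: float = 1.0) -> "ThalamicInputSpec":
        p = default_thalamic_profile()
        return cls(n_th=n_th, amplitude=p["amplitude"], t0=p["t0_ms"],
                   mu=p["mu"], sigma=p["sigma"], repeats=repeats,
                   time_factor=time_factor)

    def rate_profile(self, t_ms: np.ndarray) -> np.ndarray:
        """Single-stimulus rate course; the time axis is stretched by
        time_factor: r'(t) = r(t / time_factor)."""
        return lognormal_rate(
            np.asarray(t_ms, float) / self.time_factor,
            self.amplitude, self.t0, self.mu, self.sigma,
        )


def generate_thalamic_spikes(
    spec: ThalamicInputSpec,
    first_onset_ms: float,
    seed: int,
    dt: float = SIM_RESOLUTION_MS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inhomogeneous Poisson realizations (thinning) of the shared rate
    profile for every relay cell and stimulus repeat.

    Returns (step indices, source indices 0..n_th-1, onset times in ms).
    """
    onsets = first_onset_ms + spec.inter_stimulus_interval * np.arange(spec.repeats)
    window = spec.inter_stimulus_interval
    grid = np.arange(0.0, window, dt)
    profile = spec.rate_profile(grid)
    r_max = float(profile.max())
    rng = np.random.default_rng(seed)
    steps, ids = [], []
    if r_max > 0:
        for i in range(spec.n_th):
            for onset in onsets:
                n = rng.poisson(r_max * window / 1000.0)
                t_cand = np.sort(rng.random(n) * window)
                accept = rng.random(n) < spec.rate_profile(t_cand) / r_max
                t_sp = onset + t_cand[accept]
                steps.append(np.rint(t_sp / dt).astype(np.int64))
                ids.append(np.full(int(accept.sum()), i, np.int64))
    if steps:
        steps = np.concatenate(steps)
        ids = np.concatenate(ids)
    else:
        steps = np.empty(0, np.int64)
        ids = np.empty(0, np.int64)
    return steps, ids, onsets


def l23_probability_from_l4(p_l4: float, ratio_l23_l4: float) -> float:
    """Estimate the L2/3 thalamocortical connection probability from the L4
    one via the relative thalamocortical synapse count per neuron."""
    if not 0 <= p_l4 <= 1 or ratio_l23_l4 < 0:
        raise ParameterError("invalid probability or ratio")
    return min(1.0, p_l4 * ratio_l23_l4)


def validate_thalamic_targets(matrix) -> None:
    """Thalamic rows must never target VIP and target SOM only in L4."""
    for (src, tgt) in matrix:
        if src != "TH":
            continue
        if tgt.endswith("VIP"):
            raise ConfigurationError("thalamic input must not target VIP cells")
        if tgt.endswith("SOM") and not tgt.startswith("L4"):
            raise ConfigurationError("thalamic input targets SOM cells only in L4")
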