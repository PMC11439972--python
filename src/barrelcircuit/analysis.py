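"""Activity statistics: firing rates, pairwise spike-count correlations,
CV ISI, peristimulus time histograms with peak extraction, peak RMSE against
reference tables, and normalized stimulus-response curves with one-sample
t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import SpikeTrainSet
from .params import ParameterError


def compute_population_rates(
    spikes: SpikeTrainSet, t0: float, t1: float
) -> pd.DataFrame:
    """Per-population firing-rate statistics over [t0, t1).

    Per-neuron rate = spike count / window; mean, SD, median and quartiles
    are taken across neurons.
    """
    if t1 <= t0:
        raise ParameterError("empty analysis window")
    win = spikes.in_window(t0, t1)
    seconds = (t1 - t0) / 1000.0
    counts = np.bincount(win.senders, minlength=spikes.n_neurons)
    rates = counts / seconds
    rows = []
    for i, name in enumerate(spikes.pop_names):
        r = rates[spikes.pop_of == i]
        rows.append({
            "population": name, "mean": r.mean(), "sd": r.std(ddof=0),
            "median": float(np.median(r)), "q25": float(np.percentile(r, 25)),
            "q75": float(np.percentile(r, 75)), "n": r.size,
        })
    return pd.DataFrame(rows).set_index("population")


def _layer_neurons(spikes: SpikeTrainSet, layer: str) -> np.ndarray:
    idx = [i for i, n in enumerate(spikes.pop_names) if n.startswith(layer + " ")]
    return np.nonzero(np.isin(spikes.pop_of, idx))[0]


def compute_pairwise_correlation(
    spikes: SpikeTrainSet,
    layer: str,
    t0: float,
    t1: float,
    n_sample: int = 200,
    bin_ms: float = 10.0,
    seed: int = 0,
) -> float:
    """Mean Pearson correlation of binned spike counts over sampled pairs.

    Neurons are pooled across cell types within the layer; silent neurons
    are excluded before the (seeded) sampling of up to ``n_sample`` neurons.
    """
    win = spikes.in_window(t0, t1)
    counts = np.bincount(win.senders, minlength=spikes.n_neurons)
    eligible = _layer_neurons(spikes, layer)
    eligible = eligible[counts[eligible] > 0]
    if eligible.size < 2:
        return float("nan")
    rng = np.random.default_rng(seed)
    if eligible.size > n_sample:
        eligible = rng.choice(eligible, n_sample, replace=False)
    edges = np.arange(t0, t1 + 1e-9, bin_ms)
    mat = np.zeros((eligible.size, edges.size - 1))
    sel = np.isin(win.senders, eligible)
    idx_of = {n: i for i, n in enumerate(eligible)}
    rows = np.array([idx_of[s] for s in win.senders[sel]], int)
    cols = np.minimum(((win.times[sel] - t0) // bin_ms).astype(int), edges.size - 2)
    np.add.at(mat, (rows, cols), 1.0)
    c = np.corrcoef(mat)
    iu = np.triu_indices(eligible.size, k=1)
    vals = c[iu]
    return float(np.nanmean(vals))


def compute_cv_isi(
    spikes: SpikeTrainSet,
    layer: str,
    t0: float,
    t1: float,
    n_sample: int = 200,
    min_rate: float = 1.0,
    seed: int = 0,
) -> float:
    """Mean coefficient of variation of inter-spike intervals in a layer.

    Neurons firing below ``min_rate`` (spikes/s) in the window are excluded
    before the seeded sampling; a separate draw from the correlation sample.
    """
    win = spikes.in_window(t0, t1)
    seconds = (t1 - t0) / 1000.0
    counts = np.bincount(win.senders, minlength=spikes.n_neurons)
    eligible = _layer_neurons(spikes, layer)
    eligible = eligible[counts[eligible] / seconds >= min_rate]
    # CV needs at least two ISIs
    eligible = eligible[counts[eligible] >= 3]
    if eligible.size == 0:
        return float("nan")
    rng = np.random.default_rng(seed)
    if eligible.size > n_sample:
        eligible = rng.choice(eligible, n_sample, replace=False)
    by_neuron = win.spike_times_by_neuron()
    cvs = []
    for n in eligible:
        isi = np.diff(by_neuron[n])
        cvs.append(isi.std(ddof=0) / isi.mean())
    return float(np.mean(cvs))


@dataclass(frozen=True)
class PSTHResult:
    population: str
    bin_ms: float
    edges: np.ndarray  # ms relative to stimulus onset
    rates: np.ndarray  # spikes/s per neuron
    a_peak: float
    t_peak: float


def compute_psth_and_peaks(
    spikes: SpikeTrainSet,
    stimulus_onsets: np.ndarray,
    bin_ms: float = 0.5,
    window_ms: float = 50.0,
    search_window_ms: float = 50.0,
) -> dict[str, PSTHResult]:
    """Population PSTHs in 0.5 ms bins, normalized per neuron and repeat
    (counts / (bin * N_neurons * N_repeats), in spikes/s), with the peak
    amplitude and time searched from 0 to 50 ms after stimulus onset.
    Peak ties break toward the earliest bin.
    """
    onsets = np.asarray(stimulus_onsets, float)
    if onsets.size == 0:
        raise ParameterError("need at least one stimulus onset")
    edges = np.arange(0.0, window_ms + 1e-9, bin_ms)
    out = {}
    for i, name in enumerate(spikes.pop_names):
        neurons = spikes.pop_of[spikes.senders] == i
        t = spikes.times[neurons]
        counts = np.zeros(edges.size - 1)
        for onset in onsets:
            rel = t - onset
            m = (rel >= 0) & (rel < window_ms)
            counts += np.histogram(rel[m], bins=edges)[0]
        n_neurons = int(np.sum(spikes.pop_of == i))
        rates = counts / (bin_ms / 1000.0) / max(n_neurons, 1) / onsets.size
        n_search = int(round(search_window_ms / bin_ms))
        k = int(np.argmax(rates[:n_search]))
        out[name] = PSTHResult(
            population=name, bin_ms=bin_ms, edges=edges, rates=rates,
            a_peak=float(rates[k]), t_peak=float(edges[k] + bin_ms / 2.0),
        )
    return out


def compute_peak_rmse(
    simulated: dict[str, PSTHResult],
    reference: pd.DataFrame,
    vip_population: str = "L2/3 VIP",
) -> tuple[float, float]:
    """(amplitude RMSE, time RMSE) of PSTH peaks against a reference table
    with columns population, a_peak, t_peak.

    The amplitude comparison uses zero as the VIP criterion; the time
    comparison omits the VIP population (no observable VIP response in the
    reference data).
    """
    ref = reference.set_index("population") if "population" in reference else reference
    a_err, t_err = [], []
    for name, res in simulated.items():
        if name == vip_population:
            a_err.append(res.a_peak - 0.0)
            continue
        if name not in ref.index:
            raise ParameterError(f"missing reference row for {name}")
        a_err.append(res.a_peak - float(ref.loc[name, "a_peak"]))
        t_err.append(res.t_peak - float(ref.loc[name, "t_peak"]))
    return (
        float(np.sqrt(np.mean(np.square(a_err)))),
        float(np.sqrt(np.mean(np.square(t_err)))),
    )


@dataclass(frozen=True)
class ResponseCurve:
    population: str
    levels: tuple[float, ...]
    r_norm: tuple[float, ...]  # mean normalized rate per level
    per_instance: np.ndarray  # (n_levels, n_instances)
    p_values: tuple[float, ...]
    flags: tuple[str, ...]


def normalize_responses_and_test(
    per_instance_rates: pd.DataFrame,
) -> dict[str, ResponseCurve]:
    """Normalize per-instance rates to the zero-stimulation level and test
    each level against 1 (two-tailed one-sample t-test across instances).

    ``per_instance_rates`` columns: population, level, instance, rate.
    Instances whose zero-level rate is zero are flagged and excluded from
    that population's normalization. Zero-variance levels return p = 1 with
    a flag. The percentage change convention is (r_norm - 1) * 100.
    """
    out = {}
    for pop, grp in per_instance_rates.groupby("population"):
        piv = grp.pivot_table(index="level", columns="instance", values="rate")
        if 0.0 not in piv.index:
            raise ParameterError("zero stimulation level missing")
        base = piv.loc[0.0]
        valid = base > 0
        flags = [] if valid.all() else [f"excluded {int((~valid).sum())} zero-baseline instances"]
        norm = piv.loc[:, valid.values] / base[valid]
        levels, means, ps = [], [], []
        for level, row in norm.iterrows():
            vals = row.to_numpy(float)
            levels.append(float(level))
            means.append(float(vals.mean()))
            if np.allclose(vals.std(ddof=1) if vals.size > 1 else 0.0, 0.0):
                ps.append(1.0)
                flags.append(f"zero variance at level {level:g}")
            else:
                ps.append(float(stats.ttest_1samp(vals, 1.0).pvalue))
        out[pop] = ResponseCurve(
            population=pop, levels=tuple(levels), r_norm=tuple(means),
            per_instance=norm.to_numpy(float), p_values=tuple(ps),
            flags=tuple(flags),
        )
    return out


def percent_change(r_norm: float) -> float:
    return (r_norm - 1.0) * 100.0
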