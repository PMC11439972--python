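"""Protocol orchestration: resting state, cell-type-specific stimulation,
and thalamic stimulation, plus the published model variants expressed as
configuration.

Every run derives per-instance seeds deterministically from a base seed, so
rerunning a configuration reproduces all tables bit for bit. The first part
of every simulation (default 10 s) is discarded as warmup.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from . import analysis, inputs, stp as stp_mod
from .dynamics import SimulationInputs, simulate_network
from .model import ModelConfig, build_network, load_stp_table, stp_params_for
from .params import (
    ConfigurationError,
    ParameterError,
    load_table,
    psp_to_psc,
)


def instance_seed(seed_base: int, instance: int) -> int:
    """Deterministic per-instance seed below 2**31."""
    return (seed_base * 1_000_003 + 7919 * instance + 1) % (2**31 - 1)


@dataclass
class RunConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    duration_s: float = 15.0
    warmup_s: float = 10.0
    n_instances: int = 20
    seed_base: int = 1

    def __post_init__(self):
        if self.warmup_s >= self.duration_s:
            raise ParameterError("warmup must be shorter than the simulation")


@dataclass
class ScanConfig:
    """Grids for the thalamic-response adjustment scans."""

    exc_factors: tuple[float, ...] = (1.0,)
    som_factors: tuple[float, ...] = (1.0,)
    vip_factors: tuple[float, ...] = (1.0,)
    weight_factors: tuple[float, ...] = (1.0,)
    time_factors: tuple[float, ...] = (1.0,)
    delay_factors: tuple[float, ...] = (1.0,)


def run_resting_state(config: RunConfig, ai_criteria: pd.DataFrame | None = None):
    """Resting state under background drive only.

    Returns (rates table aggregated across instances, layer statistics table
    with pairwise correlations and CV ISI plus pass/fail flags against the
    configured asynchronous-irregular criteria).
    """
    t0 = config.warmup_s * 1000.0
    t1 = config.duration_s * 1000.0
    if ai_criteria is None:
        ai_criteria = load_table("ai_criteria.csv")
    crit = ai_criteria.set_index("metric")

    per_neuron_rates: dict[str, list[np.ndarray]] = {}
    corr_rows = []
    model_cfg = replace(config.model, include_thalamus=False)
    for inst in range(config.n_instances):
        seed = instance_seed(config.seed_base, inst)
        net = build_network(model_cfg, seed=seed)
        spikes, _ = simulate_network(net, t1, seed=seed + 1)
        win = spikes.in_window(t0, t1)
        seconds = (t1 - t0) / 1000.0
        counts = np.bincount(win.senders, minlength=spikes.n_neurons)
        for i, name in enumerate(spikes.pop_names):
            per_neuron_rates.setdefault(name, []).append(
                counts[spikes.pop_of == i] / seconds
            )
        for layer in ("L2/3", "L4", "L5", "L6"):
            corr_rows.append({
                "instance": inst, "layer": layer,
                "correlation": analysis.compute_pairwise_correlation(
                    spikes, layer, t0, t1, seed=seed + 2),
                "cv_isi": analysis.compute_cv_isi(
                    spikes, layer, t0, t1, seed=seed + 3),
            })

    rate_rows = []
    for name, chunks in per_neuron_rates.items():
        r = np.concatenate(chunks)
        rate_rows.append({
            "population": name, "mean": r.mean(), "sd": r.std(ddof=0),
            "median": float(np.median(r)), "q25": float(np.percentile(r, 25)),
            "q75": float(np.percentile(r, 75)), "n": r.size,
        })
    rates = pd.DataFrame(rate_rows).set_index("population")

    layer_stats = (
        pd.DataFrame(corr_rows).groupby("layer")[["correlation", "cv_isi"]].mean()
    )
    layer_stats["corr_in_awake_range"] = (
        (layer_stats["correlation"] >= crit.loc["correlation", "awake_min"])
        & (layer_stats["correlation"] <= crit.loc["correlation", "awake_max"])
    )
    layer_stats["cv_between_awake_and_anesth"] = (
        (layer_stats["cv_isi"] >= crit.loc["cv_isi", "anesth_up"])
        & (layer_stats["cv_isi"] <= crit.loc["cv_isi", "awake_max"])
    )
    return rates, layer_stats


def measure_population_rates(config: RunConfig) -> dict[str, float]:
    """Mean resting rates per population (used as presynaptic rates for the
    STP weight-scaling calibration)."""
    rates, _ = run_resting_state(config)
    return {name: float(rates.loc[name, "mean"]) for name in rates.index}


def compute_weight_scaling_factors(
    static_rates: Mapping[str, float],
    stp_table: pd.DataFrame | None = None,
) -> dict[tuple[str, str], float]:
    """Per-projection weight scaling so the STP steady state matches the
    static model's PSCs at the measured presynaptic resting rates.

    Thalamic projections are excluded: their transient input is handled by
    initial-weight scaling (w' = w/u) at build time.
    """
    from .connectivity import assemble_probability_matrix, _layer_of, _type_of
    from .model import CELL_TYPE_OF_CLASS
    from .params import load_synapse_classes, build_population_table

    stp_table = stp_table if stp_table is not None else load_stp_table()
    classes = load_synapse_classes()
    pops = {p.name: p for p in build_population_table()}
    matrix = assemble_probability_matrix()
    factors: dict[tuple[str, str], float] = {}
    for (src, tgt), spec in matrix.items():
        if src == "TH" or spec.p <= 0:
            continue
        params = stp_params_for(
            _type_of(src), _type_of(tgt), _layer_of(src), _layer_of(tgt), stp_table
        )
        if params is None:
            continue
        sc = classes[CELL_TYPE_OF_CLASS[_type_of(src)]]
        tgt_pop = pops[tgt]
        target_psc = abs(psp_to_psc(
            sc.psp_mean, tgt_pop.params.c_m, tgt_pop.params.tau_m, sc.tau_syn
        ))
        rate = float(static_rates.get(src, 0.0))
        res = stp_mod.calibrate_weight_scaling(params, rate, target_psc)
        factors[(src, tgt)] = res.factor
    return factors


def prepare_stp_model(
    base: ModelConfig, static_rates: Mapping[str, float]
) -> ModelConfig:
    """STP variant of a configuration with calibrated weight scaling."""
    cfg = replace(base, with_stp=True)
    cfg.weight_scaling = compute_weight_scaling_factors(static_rates)
    return cfg


def run_cell_type_stimulation(
    config: RunConfig,
    protocol: inputs.StimulusProtocol,
) -> dict[str, analysis.ResponseCurve]:
    """Cell-type-specific Poisson stimulation of one population.

    Levels run in ascending order within one simulation per instance; rates
    are evaluated over the last 500 ms of each on-window, averaged across the
    protocol's repeats, then normalized to the zero level and tested against
    1 across instances. Responses are reported for all populations in the
    stimulated layer.
    """
    target = protocol.target_population
    layer = target.rsplit(" ", 1)[0]
    warmup_ms = config.warmup_s * 1000.0
    sched = inputs.build_stimulus_schedule(protocol, warmup_ms)
    onsets = inputs.stimulus_onsets(protocol, warmup_ms)
    duration = protocol.total_duration(warmup_ms)

    model_cfg = replace(config.model, include_thalamus=False)
    rows = []
    for inst in range(config.n_instances):
        seed = instance_seed(config.seed_base, inst)
        net = build_network(model_cfg, seed=seed)
        if target not in net.pop_names:
            raise ConfigurationError(f"cannot stimulate non-existent {target}")
        mask = (net.pop_of == net.pop_names.index(target)).astype(np.uint8)
        stim_w = np.array([
            psp_to_psc(protocol.epsp, net.c_m[i], net.tau_m[i], 2.0)
            for i in range(net.n_neurons)
        ])
        sim_inputs = SimulationInputs(
            stim_rate_per_step=sched, stim_mask=mask, stim_w=stim_w
        )
        spikes, _ = simulate_network(net, duration, seed=seed + 1, inputs=sim_inputs)
        same_layer = [n for n in net.pop_names if n.startswith(layer + " ")]
        for level, ons in onsets.items():
            # last 500 ms of every on-window
            for name in same_layer:
                neurons = spikes.neurons_of_population(name)
                total = 0.0
                for t_on in ons:
                    w = spikes.in_window(t_on + protocol.on_duration - 500.0,
                                         t_on + protocol.on_duration)
                    total += np.isin(w.senders, neurons).sum()
                rate = total / len(ons) / neurons.size / 0.5
                rows.append({"population": name, "level": level,
                             "instance": inst, "rate": rate})
    return analysis.normalize_responses_and_test(pd.DataFrame(rows))


def run_thalamic_stimulation(
    config: RunConfig,
    thalamic: inputs.ThalamicInputSpec | None = None,
) -> tuple[dict[str, analysis.PSTHResult], np.ndarray]:
    """PSTH responses to repeated transient thalamic input (averaged over
    instances by pooling repeats)."""
    th = thalamic or inputs.ThalamicInputSpec.from_packaged_profile()
    warmup_ms = config.warmup_s * 1000.0
    duration = config.duration_s * 1000.0
    all_onsets = None
    acc: dict[str, np.ndarray] = {}
    for inst in range(config.n_instances):
        seed = instance_seed(config.seed_base, inst)
        net = build_network(config.model, seed=seed)
        spec = replace(th, n_th=net.n_external)
        steps, ids, onsets = inputs.generate_thalamic_spikes(
            spec, warmup_ms, seed=seed + 5
        )
        sim_inputs = SimulationInputs(
            ext_steps=steps, ext_ids=ids + net.n_neurons
        )
        spikes, _ = simulate_network(net, duration, seed=seed + 1, inputs=sim_inputs)
        res = analysis.compute_psth_and_peaks(spikes, onsets)
        for name, r in res.items():
            acc[name] = acc.get(name, 0.0) + r.rates
        all_onsets = onsets
    out = {}
    for name, rates in acc.items():
        rates = rates / config.n_instances
        edges = np.arange(0.0, 50.0 + 1e-9, 0.5)
        k = int(np.argmax(rates[: int(50.0 / 0.5)]))
        out[name] = analysis.PSTHResult(
            population=name, bin_ms=0.5, edges=edges, rates=rates,
            a_peak=float(rates[k]), t_peak=float(edges[k] + 0.25),
        )
    return out, all_onsets


def run_thalamic_scan(
    config: RunConfig,
    scan: ScanConfig,
    reference_peaks: pd.DataFrame,
    thalamic: inputs.ThalamicInputSpec | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Two-stage thalamic-response adjustment.

    Stage 1 scans recurrent-weight factors (exc/som/vip onto L2/3 targets)
    minimizing the RMSE of L2/3 response peak amplitudes; stage 2 starts
    from the stage-1 optimum and scans thalamic weight/time/delay factors
    minimizing the peak-time RMSE. Returns the full scan record and the
    best-fit factor set.
    """
    if not all((scan.exc_factors, scan.som_factors, scan.vip_factors,
                scan.weight_factors, scan.time_factors, scan.delay_factors)):
        raise ConfigurationError("empty scan grids")
    th = thalamic or inputs.ThalamicInputSpec.from_packaged_profile()
    rows = []

    def evaluate(model_cfg, spec):
        cfg = replace(config, model=model_cfg)
        psths, _ = run_thalamic_stimulation(cfg, spec)
        return psths

    best1 = (np.inf, None)
    for ef in scan.exc_factors:
        for sf in scan.som_factors:
            for vf in scan.vip_factors:
                mc = replace(config.model, exc_factor=ef, som_factor=sf, vip_factor=vf)
                psths = evaluate(mc, th)
                l23 = {k: v for k, v in psths.items() if k.startswith("L2/3")}
                a_rmse, _ = analysis.compute_peak_rmse(l23, reference_peaks)
                rows.append({"stage": "amplitude", "exc_factor": ef,
                             "som_factor": sf, "vip_factor": vf, "rmse": a_rmse})
                if a_rmse < best1[0]:
                    best1 = (a_rmse, (ef, sf, vf))
    ef, sf, vf = best1[1]

    best2 = (np.inf, None)
    for wf in scan.weight_factors:
        for tf in scan.time_factors:
            for df in scan.delay_factors:
                mc = replace(config.model, exc_factor=ef, som_factor=sf,
                             vip_factor=vf, th_weight_factor=wf, th_delay_factor=df)
                spec = replace(th, time_factor=tf)
                psths = evaluate(mc, spec)
                _, t_rmse = analysis.compute_peak_rmse(psths, reference_peaks)
                rows.append({"stage": "time", "weight_factor": wf,
                             "time_factor": tf, "delay_factor": df, "rmse": t_rmse})
                if t_rmse < best2[0]:
                    best2 = (t_rmse, (wf, tf, df))
    wf, tf, df = best2[1]
    best = {"exc_factor": ef, "som_factor": sf, "vip_factor": vf,
            "weight_factor": wf, "time_factor": tf, "delay_factor": df,
            "amplitude_rmse": best1[0], "time_rmse": best2[0]}
    return pd.DataFrame(rows), best
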