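"""Assembly of the full column model into a simulator-ready network.

Pulls together the population table, the assembled probability matrix, the
synapse classes and the short-term-plasticity table, samples every
projection with pairwise Bernoulli trials, and returns a `dynamics.Network`.
Supports the published model variants as pure configuration: STP on/off and
per-projection STP exclusions, connection-probability overrides and scaling,
background-rate offsets, removal of intra- or inter-laminar connections,
recurrent-weight scaling onto L2/3 targets, thalamic-input scaling, and the
double-sized column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import params as prm
from .dynamics import (
    STP_VARIANT_DECAY_TO_ZERO,
    Network,
    STPParams,
)

CELL_TYPE_OF_CLASS = {"Exc": "intracortical_exc", "PV": "intracortical_inh",
                      "SOM": "intracortical_inh", "VIP": "intracortical_inh"}

#: S1-to-VPM cell-number ratio and receptive-field doubling used to size the
#: thalamic relay population: N_th = 2 * round(N_total / 56) = 230.
S1_VPM_RATIO = 56
THALAMIC_DOUBLING = 2


def thalamic_population_size(n_total: int, ratio: int = S1_VPM_RATIO,
                             doubling: int = THALAMIC_DOUBLING) -> int:
    return doubling * round(n_total / ratio)


@dataclass
class ModelConfig:
    """Everything needed to build one model variant."""

    with_stp: bool = False
    bg_rates: Mapping[str, float] | None = None  # per cell type, spikes/s
    bg_rate_offsets: Mapping[str, float] = field(default_factory=dict)
    stp_exclusions: tuple[tuple[str, str], ...] = ()  # (source_type, target_type)
    stp_variant: int = STP_VARIANT_DECAY_TO_ZERO
    prob_overrides: Mapping[tuple[str, str], float] = field(default_factory=dict)
    prob_scale: Mapping[tuple[str, str], float] = field(default_factory=dict)
    weight_scaling: Mapping[tuple[str, str], float] = field(default_factory=dict)
    # recurrent excitatory weight scaling onto specific L2/3 targets
    exc_factor: float = 1.0
    som_factor: float = 1.0
    vip_factor: float = 1.0
    # thalamic input scaling
    th_weight_factor: float = 1.0
    th_delay_factor: float = 1.0
    remove_intralaminar: bool = False
    remove_interlaminar: bool = False
    double_sized: bool = False
    include_thalamus: bool = True
    geometry: conn.Geometry = field(default_factory=conn.Geometry)
    size_scale: float = 1.0  # miniature builds for testing

    def resolved_bg_rates(self) -> dict[str, float]:
        rates = dict(self.bg_rates) if self.bg_rates else default_background_rates(
            "base_stp" if self.with_stp else "base"
        )
        for cell, off in self.bg_rate_offsets.items():
            rates[cell] = rates[cell] + off
        return rates


def default_background_rates(variant: str = "base") -> dict[str, float]:
    df = prm.load_table("background_rates.csv")
    row = df[df["variant"] == variant].iloc[0]
    return {c: float(row[c]) for c in ("Exc", "PV", "SOM", "VIP")}


def load_stp_table() -> pd.DataFrame:
    return prm.load_table("stp_params.csv")


def stp_params_for(
    source_type: str, target_type: str, source_layer: str, target_layer: str,
    table: pd.DataFrame,
) -> STPParams | None:
    """Look up fitted STP parameters; specific layer rows beat wildcards;
    None means the projection stays static."""
    cand = table[(table["source_type"] == source_type)
                 & (table["target_type"] == target_type)]
    if cand.empty:
        return None
    exact = cand[(cand["source_layer"] == source_layer)
                 & (cand["target_layer"] == target_layer)]
    row = exact.iloc[0] if not exact.empty else None
    if row is None:
        wild = cand[(cand["source_layer"] == "*") & (cand["target_layer"] == "*")]
        row = wild.iloc[0] if not wild.empty else None
    if row is None:
        return None
    return STPParams(U=float(row["U"]), F=float(row["F_ms"]), D=float(row["D_ms"]))


def _scaled_populations(scale: float, double: bool) -> pd.DataFrame:
    df = prm.load_table("populations.csv")
    factor = scale * (2.0 if double else 1.0)
    if factor != 1.0:
        df = df.copy()
        df["n_exc"] = np.maximum(1, np.rint(df["n_exc"] * factor)).astype(int)
        df["n_inh"] = np.maximum(3, np.rint(df["n_inh"] * factor)).astype(int)
    return df


def build_network(config: ModelConfig | None = None, seed: int = 0) -> Network:
    """Sample one realization of the column (seeded, reproducible)."""
    config = config or ModelConfig()
    rng = np.random.default_rng(seed)

    pops = prm.build_population_table(
        populations=_scaled_populations(config.size_scale, config.double_sized)
    )
    classes = prm.load_synapse_classes()
    stp_table = load_stp_table() if config.with_stp else None

    if config.double_sized:
        # re-derive every probability for a footprint of twice the area
        doubled = conn.Geometry(
            surface_x=config.geometry.surface_x * 2.0,
            surface_y=config.geometry.surface_y,
            decay_length=config.geometry.decay_length,
        )
    matrix = conn.assemble_probability_matrix(geometry=config.geometry)
    if config.double_sized:
        for key, spec in matrix.items():
            spec.p = conn.derive_model_probability(
                spec.p,
                (config.geometry.surface_x, config.geometry.surface_y),
                doubled,
            )

    # neuron arrays
    n_of = {p.name: p.n for p in pops}
    offsets = {}
    off = 0
    for p in pops:
        offsets[p.name] = off
        off += p.n
    n_total = off
    pop_of = np.empty(n_total, np.int64)
    tau_m = np.empty(n_total)
    c_m = np.empty(n_total)
    v_rest = np.empty(n_total)
    v_th = np.empty(n_total)
    v_reset = np.empty(n_total)
    tau_ref = np.empty(n_total)
    pop_names = tuple(p.name for p in pops)
    params_of = {}
    for i, p in enumerate(pops):
        sl = slice(offsets[p.name], offsets[p.name] + p.n)
        pop_of[sl] = i
        tau_m[sl] = p.params.tau_m
        c_m[sl] = p.params.c_m
        v_rest[sl] = p.params.v_rest
        v_th[sl] = p.params.v_th
        v_reset[sl] = p.params.v_reset
        tau_ref[sl] = p.params.tau_ref
        params_of[p.name] = p.params

    n_th = thalamic_population_size(n_total) if config.include_thalamus else 0
    if config.double_sized:
        n_th = thalamic_population_size(n_total)  # recomputed from doubled N

    pre_all, tgt_all, w_all, d_all = [], [], [], []
    exc_all, stp_flag_all, U_all, F_all, D_all = [], [], [], [], []

    def add_projection(src_name, spec, n_src, src_offset, src_type, src_layer,
                       synapse_class, stp_params):
        p = spec.p
        key = (spec.source, spec.target)
        if key in config.prob_overrides:
            p = config.prob_overrides[key]
        p *= config.prob_scale.get(key, 1.0)
        tgt_layer, tgt_type = spec.target.rsplit(" ", 1)[0], conn._type_of(spec.target)
        if src_name != "TH":
            same_layer = conn._layer_of(spec.source) == tgt_layer
            if config.remove_intralaminar and same_layer:
                return
            if config.remove_interlaminar and not same_layer:
                return
        pre, post = conn.sample_connections(p, n_src, n_of[spec.target], rng)
        if pre.size == 0:
            return
        w, delays = conn.draw_synaptic_parameters(
            synapse_class, params_of[spec.target], pre.size, rng
        )
        scale = config.weight_scaling.get(key, 1.0)
        if src_name != "TH" and src_type == "Exc" and tgt_layer == "L2/3":
            scale *= {"Exc": config.exc_factor, "SOM": config.som_factor,
                      "VIP": config.vip_factor}.get(tgt_type, 1.0)
        if src_name == "TH":
            scale *= config.th_weight_factor
            delays = np.maximum(
                prm.SIM_RESOLUTION_MS,
                np.rint(delays * config.th_delay_factor / prm.SIM_RESOLUTION_MS)
                * prm.SIM_RESOLUTION_MS,
            )
        w = w * scale
        has_stp = 0
        U = F = D = 0.0
        if stp_params is not None:
            has_stp = 1
            U, F, D = stp_params.U, stp_params.F, stp_params.D
            if src_name == "TH":
                # transient input: scale so the first transmitted amplitude
                # equals the defined weight (w' = w / u_initial)
                w = w / U
        pre_all.append(pre + src_offset)
        tgt_all.append(post + offsets[spec.target])
        w_all.append(w)
        d_all.append(np.rint(delays / prm.SIM_RESOLUTION_MS).astype(np.int64))
        exc_all.append(np.full(pre.size, 1 if synapse_class.sign > 0 else 0, np.uint8))
        stp_flag_all.append(np.full(pre.size, has_stp, np.uint8))
        U_all.append(np.full(pre.size, U))
        F_all.append(np.full(pre.size, F))
        D_all.append(np.full(pre.size, D))

    for (src, tgt), spec in matrix.items():
        if src == conn.THALAMIC_SOURCE:
            if not config.include_thalamus:
                continue
            tgt_type = conn._type_of(tgt)
            if tgt_type == "VIP":
                raise prm.ConfigurationError("thalamic input must not target VIP")
            sc = classes["thalamic_som" if tgt_type == "SOM" else "thalamic"]
            stp_p = None
            if config.with_stp and ("TH", tgt_type) not in config.stp_exclusions:
                stp_p = stp_params_for("TH", tgt_type, "*", conn._layer_of(tgt), stp_table)
            add_projection("TH", spec, n_th, n_total, "TH", "*", sc, stp_p)
        else:
            src_layer, src_type = conn._layer_of(src), conn._type_of(src)
            sc = classes[CELL_TYPE_OF_CLASS[src_type]]
            stp_p = None
            if config.with_stp and (src_type, conn._type_of(tgt)) not in config.stp_exclusions:
                stp_p = stp_params_for(
                    src_type, conn._type_of(tgt), src_layer, conn._layer_of(tgt), stp_table
                )
            add_projection(src, spec, n_of[src], offsets[src], src_type, src_layer,
                           sc, stp_p)

    n_sources = n_total + n_th
    if pre_all:
        pre = np.concatenate(pre_all)
        order = np.argsort(pre, kind="stable")
        pre = pre[order]
        syn_tgt = np.concatenate(tgt_all)[order]
        syn_w = np.concatenate(w_all)[order]
        syn_d = np.concatenate(d_all)[order]
        syn_exc = np.concatenate(exc_all)[order]
        syn_stp = np.concatenate(stp_flag_all)[order]
        syn_U = np.concatenate(U_all)[order]
        syn_F = np.concatenate(F_all)[order]
        syn_D = np.concatenate(D_all)[order]
        indptr = np.searchsorted(pre, np.arange(n_sources + 1))
    else:
        syn_tgt = np.empty(0, np.int64)
        syn_w = syn_U = syn_F = syn_D = np.empty(0)
        syn_d = np.empty(0, np.int64)
        syn_exc = syn_stp = np.empty(0, np.uint8)
        indptr = np.zeros(n_sources + 1, np.int64)

    # background drive: one Poisson source per neuron, fixed 0.5 mV EPSP
    rates = config.resolved_bg_rates()
    bg_class = classes["background"]
    bg_rate = np.empty(n_total)
    bg_w = np.empty(n_total)
    for p in pops:
        sl = slice(offsets[p.name], offsets[p.name] + p.n)
        if p.cell_type not in rates:
            raise prm.ConfigurationError(f"missing background rate for {p.cell_type}")
        bg_rate[sl] = rates[p.cell_type]
        bg_w[sl] = prm.psp_to_psc(
            bg_class.psp_mean, p.params.c_m, p.params.tau_m, bg_class.tau_syn
        )

    return Network(
        pop_of=pop_of, pop_names=pop_names,
        tau_m=tau_m, c_m=c_m, v_rest=v_rest, v_th=v_th, v_reset=v_reset,
        tau_ref=tau_ref,
        indptr=indptr, syn_tgt=syn_tgt, syn_w=syn_w, syn_delay_steps=syn_d,
        syn_is_exc=syn_exc, syn_has_stp=syn_stp, syn_U=syn_U, syn_F=syn_F,
        syn_D=syn_D, n_external=n_th, stp_variant=config.stp_variant,
        bg_rate=bg_rate, bg_w=bg_w,
    )
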