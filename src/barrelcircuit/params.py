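"""Population, neuron, and synapse parameters of the barrel-column model.

This module houses the deterministic conversions that derive operational
model values from literature values: the in-vitro-to-awake membrane time
constant adjustment, the PSP-to-PSC amplitude conversion for exponential
synaptic currents, and the apportionment of inhibitory cell counts over the
PV/SOM/VIP interneuron classes.

The column comprises 13 populations: Exc, PV and SOM cells in each of L2/3,
L4, L5 and L6, plus a single VIP population that collects all VIP cells into
L2/3 (VIP cells are overwhelmingly supragranular and connectivity data for
deep-layer VIP cells are lacking).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

LAYERS = ("L2/3", "L4", "L5", "L6")
CELL_TYPES = ("Exc", "PV", "SOM", "VIP")

#: canonical ordering of the 13 populations
POPULATION_NAMES = (
    "L2/3 Exc", "L2/3 PV", "L2/3 SOM", "L2/3 VIP",
    "L4 Exc", "L4 PV", "L4 SOM",
    "L5 Exc", "L5 PV", "L5 SOM",
    "L6 Exc", "L6 PV", "L6 SOM",
)

#: resistance reduction from the silent (in vitro) to the awake state
TAU_M_REDUCTION = {"Exc": 0.509, "PV": 0.049, "SOM": 0.049, "VIP": 0.049}

SIM_RESOLUTION_MS = 0.1
REFRACTORY_MS = 2.0


class ParameterError(ValueError):
    """Raised for invalid parameter values."""


class ConfigurationError(ValueError):
    """Raised when required configuration entries are missing."""


def _data_path(name: str):
    return resources.files("barrelcircuit.data") / name


def load_table(name: str) -> pd.DataFrame:
    """Load a packaged delimited parameter table."""
    with resources.as_file(_data_path(name)) as p:
        return pd.read_csv(p, comment="#")


@dataclass(frozen=True)
class NeuronParams:
    """Leaky integrate-and-fire membrane parameters.

    tau_m : membrane time constant, ms (awake-adjusted)
    c_m : membrane capacitance, pF
    v_rest : resting potential, mV
    v_th : firing threshold, mV
    v_reset : post-spike reset potential, mV (defaults to v_rest; the model
        has no adaptation and no separate reset value is defined)
    tau_ref : absolute refractory period, ms (2.0 for every neuron)
    """

    tau_m: float
    c_m: float
    v_rest: float
    v_th: float
    v_reset: float | None = None
    tau_ref: float = REFRACTORY_MS

    def __post_init__(self):
        if self.v_reset is None:
            object.__setattr__(self, "v_reset", self.v_rest)
        if self.tau_m <= 0 or self.c_m <= 0:
            raise ParameterError("tau_m and c_m must be positive")
        if self.v_th <= self.v_rest:
            raise ParameterError("v_th must exceed v_rest")
        if self.v_reset > self.v_th:
            raise ParameterError("v_reset must not exceed v_th")


@dataclass(frozen=True)
class PopulationSpec:
    layer: str
    cell_type: str
    n: int
    params: NeuronParams

    @property
    def name(self) -> str:
        return f"{self.layer} {self.cell_type}"


@dataclass(frozen=True)
class SynapseClass:
    """A family of synapses sharing sign, kinetics, PSP and delay statistics.

    PSP mean/SD are linear-space magnitudes in mV (sign applied separately);
    delays in ms. An SD of zero means a fixed value.
    """

    name: str
    sign: int
    psp_mean: float
    psp_sd: float
    tau_syn: float
    delay_mean: float
    delay_sd: float

    def __post_init__(self):
        if self.sign not in (-1, 1):
            raise ParameterError("sign must be +1 or -1")
        if self.psp_sd < 0 or self.delay_mean <= 0:
            raise ParameterError("psp_sd must be >= 0 and delay_mean > 0")


@dataclass(frozen=True)
class InterneuronFractions:
    """Relative quantities of PV/SOM/VIP cells within one layer."""

    f_pv: float
    f_som: float
    f_vip: float

    def __post_init__(self):
        if min(self.f_pv, self.f_som, self.f_vip) < 0:
            raise ParameterError("fractions must be non-negative")
        if self.f_pv + self.f_som + self.f_vip <= 0:
            raise ParameterError("at least one fraction must be positive")


def adjust_membrane_time_constant(tau_m_invitro: float, reduction_fraction: float) -> float:
    """Apply the silent-to-awake membrane resistance reduction to tau_m.

    With capacitance unchanged, a fractional decrease of the membrane
    resistance decreases tau_m by the same fraction. Returns the full-
    precision value; reporting rounds to one decimal.
    """
    if not 0 <= reduction_fraction < 1:
        raise ParameterError("reduction_fraction must be in [0, 1)")
    if tau_m_invitro <= 0:
        raise ParameterError("tau_m_invitro must be positive")
    return tau_m_invitro * (1.0 - reduction_fraction)


def psp_to_psc(psp: float, c_m: float, tau_m: float, tau_syn: float) -> float:
    """Amplitude (pA) of an exponentially decaying PSC whose membrane
    response peaks at ``psp`` (mV).

    For a LIF membrane (tau_m, c_m) receiving I(t) = PSC * exp(-t/tau_syn),
    the voltage peak is PSP; inverting gives

        PSC = C_m (a-1) PSP / (tau_syn (a^{1/(1-a)} - a^{a/(1-a)})),

    with a = tau_syn/tau_m. The formula is 0/0 at a = 1; the analytic limit
    C_m e PSP / tau_syn is used in a small neighbourhood of a = 1.
    """
    if c_m <= 0 or tau_m <= 0 or tau_syn <= 0:
        raise ParameterError("c_m, tau_m, tau_syn must be positive")
    a = tau_syn / tau_m
    if abs(a - 1.0) < 1e-9:
        return c_m * math.e * psp / tau_syn
    denom = tau_syn * (a ** (1.0 / (1.0 - a)) - a ** (a / (1.0 - a)))
    return c_m * (a - 1.0) * psp / denom


def allocate_interneuron_counts(
    n_inh: int, fractions: InterneuronFractions
) -> tuple[int, int, int]:
    """Distribute ``n_inh`` over PV/SOM/VIP by largest-remainder apportionment.

    The integer counts match the exact quotas n_inh * f_x / sum(f) within one
    and always sum to ``n_inh``.
    """
    if n_inh < 0:
        raise ParameterError("n_inh must be non-negative")
    f = np.array([fractions.f_pv, fractions.f_som, fractions.f_vip], float)
    quotas = n_inh * f / f.sum()
    counts = np.floor(quotas).astype(int)
    remainder = int(n_inh - counts.sum())
    # hand out leftover seats by largest fractional part; ties by index order
    order = np.argsort(-(quotas - counts), kind="stable")
    for i in range(remainder):
        counts[order[i]] += 1
    return tuple(int(c) for c in counts)


def merge_vip_population(per_layer_vip_counts: Sequence[int]) -> int:
    """Total VIP count, assigned to the single L2/3 VIP population."""
    if any(c < 0 for c in per_layer_vip_counts):
        raise ParameterError("counts must be non-negative")
    return int(sum(per_layer_vip_counts))


def _neuron_param_groups(
    reduction: Mapping[str, float] = TAU_M_REDUCTION,
    use_overrides: bool = True,
) -> dict[str, NeuronParams]:
    df = load_table("neuron_params.csv")
    groups: dict[str, NeuronParams] = {}
    for _, row in df.iterrows():
        cell = row["group"].split("_")[-1] if "_" in row["group"] else row["group"]
        tau = adjust_membrane_time_constant(row["tau_m_invitro_ms"], reduction[cell])
        if use_overrides and not pd.isna(row["tau_m_override_ms"]):
            tau = float(row["tau_m_override_ms"])
        groups[row["group"]] = NeuronParams(
            tau_m=tau,
            c_m=float(row["c_m_pf"]),
            v_rest=float(row["v_rest_mv"]),
            v_th=float(row["v_th_mv"]),
        )
    return groups


# supra-granular parameters serve L2/3 and L4; infra-granular serve L5 and L6
_GROUP_OF = {
    ("L2/3", "Exc"): "L23_Exc", ("L4", "Exc"): "L23_Exc",
    ("L2/3", "PV"): "L23_PV", ("L4", "PV"): "L23_PV",
    ("L2/3", "SOM"): "L23_SOM", ("L4", "SOM"): "L23_SOM",
    ("L2/3", "VIP"): "VIP",
    ("L5", "Exc"): "L5_Exc", ("L6", "Exc"): "L5_Exc",
    ("L5", "PV"): "L5_PV", ("L6", "PV"): "L5_PV",
    ("L5", "SOM"): "L5_SOM", ("L6", "SOM"): "L5_SOM",
}


def build_population_table(
    populations: pd.DataFrame | None = None,
    fractions: Mapping[str, InterneuronFractions] | None = None,
    reduction: Mapping[str, float] = TAU_M_REDUCTION,
) -> list[PopulationSpec]:
    """Assemble the 13 populations with awake-adjusted neuron parameters.

    Deterministic: identical inputs yield identical tables.
    """
    if populations is None:
        populations = load_table("populations.csv")
    if fractions is None:
        fdf = load_table("interneuron_fractions.csv")
        fractions = {
            row["layer"]: InterneuronFractions(row["f_pv"], row["f_som"], row["f_vip"])
            for _, row in fdf.iterrows()
        }
    groups = _neuron_param_groups(reduction)
    counts: dict[tuple[str, str], int] = {}
    vip_counts = []
    for _, row in populations.iterrows():
        layer = row["layer"]
        if layer not in fractions:
            raise ConfigurationError(f"missing interneuron fractions for {layer}")
        n_pv, n_som, n_vip = allocate_interneuron_counts(int(row["n_inh"]), fractions[layer])
        counts[(layer, "Exc")] = int(row["n_exc"])
        counts[(layer, "PV")] = n_pv
        counts[(layer, "SOM")] = n_som
        vip_counts.append(n_vip)
    counts[("L2/3", "VIP")] = merge_vip_population(vip_counts)

    specs = []
    for name in POPULATION_NAMES:
        layer, cell = name.rsplit(" ", 1)
        key = (layer, cell)
        if key not in counts:
            raise ConfigurationError(f"missing population count for {name}")
        specs.append(PopulationSpec(layer, cell, counts[key], groups[_GROUP_OF[key]]))
    return specs


def load_synapse_classes() -> dict[str, SynapseClass]:
    df = load_table("synapse_classes.csv")
    return {
        row["name"]: SynapseClass(
            name=row["name"],
            sign=int(row["sign"]),
            psp_mean=float(row["psp_mean_mv"]),
            psp_sd=float(row["psp_sd_mv"]),
            tau_syn=float(row["tau_syn_ms"]),
            delay_mean=float(row["delay_mean_ms"]),
            delay_sd=float(row["delay_sd_ms"]),
        )
        for _, row in df.iterrows()
    }


def total_neurons(specs: Sequence[PopulationSpec]) -> int:
    return sum(s.n for s in specs)
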