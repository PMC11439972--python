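"""Connection-probability derivation and synapse instantiation.

Connection probabilities measured in paired recordings apply to the lateral
sampling range of the experiment. The model rescales such a probability to
its own column footprint by assuming an exponential decay of connection
probability with lateral distance: the decay kernel is calibrated so that its
average over the experimental sampling footprint equals the measured value,
and the model probability is the kernel's average over the model footprint.
After this derivation the network is non-spatial: connections are pairwise
Bernoulli with projection-specific probabilities, autapses allowed, multapses
disallowed (one synapse per ordered pair), log-normal weights and delays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .params import (
    LAYERS,
    POPULATION_NAMES,
    SIM_RESOLUTION_MS,
    ConfigurationError,
    NeuronParams,
    ParameterError,
    SynapseClass,
    load_table,
    psp_to_psc,
)

THALAMIC_SOURCE = "TH"

#: default lateral decay constant of connection probability, um.
#: Placeholder magnitude typical of cortical lateral connectivity; the
#: calibrated value lives outside the main parameter set and is configurable.
DEFAULT_DECAY_LENGTH_UM = 150.0


@dataclass(frozen=True)
class Geometry:
    """Column footprint and lateral decay constant (um)."""

    surface_x: float = 200.0
    surface_y: float = 300.0
    decay_length: float = DEFAULT_DECAY_LENGTH_UM

    def __post_init__(self):
        if min(self.surface_x, self.surface_y, self.decay_length) <= 0:
            raise ParameterError("geometry dimensions must be positive")


@dataclass
class ProjectionSpec:
    """One population-to-population projection."""

    source: str
    target: str
    p: float
    provenance: str
    p_exp: float | None = None
    synapse_class: SynapseClass | None = None
    stp: "object | None" = None  # STPParams or None for static
    weight_scale: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ParameterError(f"{self.source}->{self.target}: P outside [0, 1]")


def _mean_kernel_over_rectangle(ax: float, ay: float, lam: float, order: int = 96) -> float:
    """< exp(-r / lam) > over displacements of uniform point pairs in an
    ax x ay rectangle (deterministic Gauss-Legendre quadrature).

    The displacement components are independent with triangular densities
    2(a - u)/a^2 on [0, a].
    """
    nodes, weights = np.polynomial.legendre.leggauss(order)
    x = 0.5 * ax * (nodes + 1.0)
    wx = 0.5 * ax * weights * 2.0 * (ax - x) / ax**2
    y = 0.5 * ay * (nodes + 1.0)
    wy = 0.5 * ay * weights * 2.0 * (ay - y) / ay**2
    r = np.sqrt(x[:, None] ** 2 + y[None, :] ** 2)
    return float(wx @ np.exp(-r / lam) @ wy)


def derive_model_probability(
    p_exp: float,
    experimental_range: tuple[float, float],
    geometry: Geometry,
) -> float:
    """Rescale an experimentally sampled probability to the model footprint.

    The exponential kernel c*exp(-r/lam) is calibrated so that its average
    over the experimental footprint equals ``p_exp``; the returned value is
    its average over the model footprint, clipped to [0, 1].
    """
    if not 0.0 <= p_exp <= 1.0:
        raise ParameterError("p_exp must be in [0, 1]")
    rx, ry = experimental_range
    if rx <= 0 or ry <= 0:
        raise ParameterError("experimental range must be positive")
    if p_exp == 0.0:
        return 0.0
    if (rx, ry) == (geometry.surface_x, geometry.surface_y):
        return p_exp
    k_exp = _mean_kernel_over_rectangle(rx, ry, geometry.decay_length)
    k_model = _mean_kernel_over_rectangle(
        geometry.surface_x, geometry.surface_y, geometry.decay_length
    )
    return float(min(1.0, p_exp * k_model / k_exp))


def combine_morphological_subtypes(
    probabilities: Sequence[float], cell_counts: Sequence[float]
) -> float:
    """Cell-number-weighted average of morphological-subtype probabilities."""
    p = np.asarray(probabilities, float)
    n = np.asarray(cell_counts, float)
    if p.shape != n.shape or p.size == 0:
        raise ParameterError("probabilities and counts must match and be non-empty")
    if n.sum() <= 0:
        raise ParameterError("total cell count must be positive")
    return float(np.average(p, weights=n))


def _layer_of(pop: str) -> str:
    return pop.rsplit(" ", 1)[0]


def _type_of(pop: str) -> str:
    return pop.rsplit(" ", 1)[1]


def assemble_probability_matrix(
    entries: pd.DataFrame | None = None,
    geometry: Geometry | None = None,
) -> dict[tuple[str, str], ProjectionSpec]:
    """Build the full 13x13 cortical probability matrix plus thalamic rows.

    Missing intra-layer entries are filled by the documented rules:
    Exc->PV copies PV->Exc where absent (Exc/PV pairs reciprocate with very
    high probability); the L5 SOM-related entries (Exc->SOM, SOM->Exc,
    SOM->SOM) are the averages of L2/3 and L4; all L6 entries other than
    Exc->Exc copy their L5 counterparts. Raises if any of the 169 cortical
    entries is still undefined afterwards.
    """
    if entries is None:
        entries = load_table("connectivity.csv")
    geometry = geometry or Geometry()

    table: dict[tuple[str, str], ProjectionSpec] = {}
    for _, row in entries.iterrows():
        p_exp = float(row["p_percent"]) / 100.0
        rng = (float(row["range_x_um"]), float(row["range_y_um"]))
        p = derive_model_probability(p_exp, rng, geometry)
        table[(row["source"], row["target"])] = ProjectionSpec(
            row["source"], row["target"], p, row["provenance"], p_exp=p_exp
        )

    def fill(src: str, tgt: str, p: float, prov: str):
        if (src, tgt) not in table:
            table[(src, tgt)] = ProjectionSpec(src, tgt, p, prov)

    # rule 1: Exc->PV reciprocity where Exc->PV is missing
    for layer in LAYERS:
        e, p_ = f"{layer} Exc", f"{layer} PV"
        if (e, p_) not in table and (p_, e) in table:
            fill(e, p_, table[(p_, e)].p, "assumption")
    # rule 2: L5 SOM-related entries average L2/3 and L4
    for pair in (("Exc", "SOM"), ("SOM", "Exc"), ("SOM", "SOM")):
        key5 = (f"L5 {pair[0]}", f"L5 {pair[1]}")
        sources = [(f"{l} {pair[0]}", f"{l} {pair[1]}") for l in ("L2/3", "L4")]
        if key5 not in table and all(k in table for k in sources):
            fill(*key5, float(np.mean([table[k].p for k in sources])), "assumption")
    # rule 3: remaining L6 intra-layer entries copy L5
    for s_t in ("Exc", "PV", "SOM"):
        for t_t in ("Exc", "PV", "SOM"):
            key6 = (f"L6 {s_t}", f"L6 {t_t}")
            key5 = (f"L5 {s_t}", f"L5 {t_t}")
            if key6 not in table and key5 in table:
                fill(*key6, table[key5].p, "assumption")

    missing = [
        (s, t)
        for s in POPULATION_NAMES
        for t in POPULATION_NAMES
        if (s, t) not in table
    ]
    if missing:
        raise ConfigurationError(f"{len(missing)} cortical entries undefined: {missing[:5]}")
    return table


def count_projections(
    table: Mapping[tuple[str, str], ProjectionSpec]
) -> tuple[int, int]:
    """(intra-layer, inter-layer) cortical entry counts."""
    intra = inter = 0
    for (s, t) in table:
        if s == THALAMIC_SOURCE:
            continue
        if _layer_of(s) == _layer_of(t):
            intra += 1
        else:
            inter += 1
    return intra, inter


def matrix_to_frame(table: Mapping[tuple[str, str], ProjectionSpec]) -> pd.DataFrame:
    """Export the assembled matrix as a tidy table (percent, provenance)."""
    rows = [
        {
            "source": s,
            "target": t,
            "p_percent": spec.p * 100.0,
            "provenance": spec.provenance,
        }
        for (s, t), spec in sorted(table.items())
    ]
    return pd.DataFrame(rows)


def sample_connections(
    p: float, n_src: int, n_tgt: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Bernoulli draw: returns (pre, post) index arrays.

    Each ordered pair connects independently with probability ``p``; at most
    one synapse per ordered pair; autapses arise naturally when source and
    target index the same population.
    """
    if p <= 0.0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    if p >= 1.0:
        pre, post = np.meshgrid(np.arange(n_src), np.arange(n_tgt), indexing="ij")
        return pre.ravel().astype(np.int64), post.ravel().astype(np.int64)
    mask = rng.random((n_src, n_tgt)) < p
    pre, post = np.nonzero(mask)
    return pre.astype(np.int64), post.astype(np.int64)


def _lognormal_moments(mean: float, sd: float) -> tuple[float, float]:
    """Log-space (mu, sigma) matching linear-space mean and SD."""
    if mean <= 0:
        raise ParameterError("log-normal mean must be positive")
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - 0.5 * sigma2
    return mu, math.sqrt(sigma2)


def draw_synaptic_parameters(
    synapse_class: SynapseClass,
    target_params: NeuronParams,
    size: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (weights pA, delays ms) for ``size`` synapses of one class.

    PSP magnitudes are log-normal with the class's linear-space moments, the
    class sign is applied, and each PSP is converted to a PSC amplitude via
    the target population's membrane parameters. Delays are log-normal,
    rounded to the 0.1 ms grid with a one-step floor. Classes with zero SD
    (background) return fixed values.
    """
    factor = psp_to_psc(1.0, target_params.c_m, target_params.tau_m, synapse_class.tau_syn)
    if synapse_class.psp_sd == 0.0:
        psp = np.full(size, synapse_class.psp_mean)
    else:
        mu, sigma = _lognormal_moments(synapse_class.psp_mean, synapse_class.psp_sd)
        psp = rng.lognormal(mu, sigma, size)
    weights = synapse_class.sign * psp * factor

    if synapse_class.delay_sd == 0.0:
        delays = np.full(size, synapse_class.delay_mean)
    else:
        mu_d, sigma_d = _lognormal_moments(synapse_class.delay_mean, synapse_class.delay_sd)
        delays = rng.lognormal(mu_d, sigma_d, size)
    steps = np.maximum(1, np.rint(delays / SIM_RESOLUTION_MS)).astype(np.int64)
    return weights, steps * SIM_RESOLUTION_MS
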