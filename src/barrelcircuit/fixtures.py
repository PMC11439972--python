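"""Synthetic inputs with known ground truth.

Everything downstream modules need for testing is generated here from seeded
generators: PSP-amplitude trains from a known Tsodyks synapse (optionally
with multiplicative Gaussian noise), and miniature columns that preserve the
13-population topology at a fraction of the size for fast end-to-end runs.
Fixture objects carry their ground truth and seed alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import Network, STPParams, stp_amplitude_sequence
from .model import ModelConfig, build_network
from .params import ParameterError
from .stp import PSPTrainObservation


@dataclass(frozen=True)
class PSPTrainFixture:
    observation: PSPTrainObservation
    truth: STPParams
    noise_sigma: float
    seed: int


def make_psp_train_fixture(
    stp: STPParams,
    rate: float,
    n_spikes: int,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> PSPTrainFixture:
    """Normalized PSP amplitudes from the exact STP recursion, optionally
    degraded by multiplicative Gaussian noise (the first amplitude stays 1
    by normalization convention)."""
    if n_spikes < 2:
        raise ParameterError("a single PSP cannot constrain STP parameters")
    times = np.arange(n_spikes) * 1000.0 / rate
    amps = stp_amplitude_sequence(stp, times)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        amps = amps * (1.0 + noise_sigma * rng.standard_normal(n_spikes))
        amps = np.maximum(amps, 1e-6)
    amps = amps / amps[0]
    obs = PSPTrainObservation(
        presyn_rate=rate,
        normalized_amplitudes=tuple(float(a) for a in amps),
        subtraction_applied=True,
    )
    return PSPTrainFixture(obs, stp, noise_sigma, seed)


def make_toy_network_fixture(
    size_scale: float = 0.05,
    seed: int = 0,
    bg_rates: dict | None = None,
    **config_kwargs,
) -> Network:
    """A miniature column: same 13-population topology and parameter tables,
    population sizes scaled down for fast tests."""
    cfg = ModelConfig(
        size_scale=size_scale,
        bg_rates=bg_rates,
        include_thalamus=config_kwargs.pop("include_thalamus", False),
        **config_kwargs,
    )
    return build_network(cfg, seed=seed)
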