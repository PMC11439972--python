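"""Background-rate calibration against in vivo reference firing rates.

The four cell-type-specific (layer-independent) background rates are scanned
on a coarse grid (500 spikes/s) and then a fine grid (100 spikes/s) centred
on the coarse optimum. The objective is the root-mean-square percentage
error (RMSPE) of the mean population firing rates of the seven L2/3 and L4
populations against their in vivo reference means; deeper layers are not
fitted. The scan is performed separately for the static-synapse and STP
model versions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .params import ParameterError, load_table

CELL_TYPES = ("Exc", "PV", "SOM", "VIP")


@dataclass(frozen=True)
class RMSPEResult:
    value: float
    per_population_errors: tuple[float, ...]


def compute_rmspe(simulated: Sequence[float], targets: Sequence[float]) -> RMSPEResult:
    """RMSPE = sqrt(mean(((sim - target)/target)^2))."""
    sim = np.asarray(simulated, float)
    tgt = np.asarray(targets, float)
    if sim.shape != tgt.shape or sim.size == 0:
        raise ParameterError("simulated and target vectors must match")
    if np.any(tgt == 0):
        raise ParameterError("percentage error undefined for zero targets")
    err = (sim - tgt) / tgt
    return RMSPEResult(float(np.sqrt(np.mean(err**2))), tuple(err))


def calibration_targets() -> dict[str, float]:
    """The seven reference means (L2/3 Exc/PV/SOM/VIP, L4 Exc/PV/SOM)."""
    df = load_table("reference_rates.csv")
    sel = df[df["calibration_target"] == 1]
    return {f"{r.layer} {r.cell_type}": float(r.mean) for r in sel.itertuples()}


@dataclass
class OptimizationConfig:
    coarse_step: float = 500.0
    fine_step: float = 100.0
    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {c: (0.0, 8000.0) for c in CELL_TYPES}
    )
    fine_halfwidth: float = 400.0
    instances_per_setting: int = 10
    target_rates: Mapping[str, float] | None = None


def _grid(bounds: tuple[float, float], step: float) -> np.ndarray:
    lo, hi = bounds
    return np.arange(lo, hi + 1e-9, step)


def optimize_background_rates(
    evaluate: Callable[[Mapping[str, float]], Mapping[str, float]],
    config: OptimizationConfig | None = None,
) -> tuple[dict[str, float], pd.DataFrame]:
    """Two-stage exhaustive grid scan of the four background rates.

    ``evaluate`` maps a rate combination to mean population firing rates
    (averaging over instances is the evaluator's responsibility). Returns the
    argmin combination and the full scan record (one row per evaluated grid
    point, coarse stage first), enabling second/third-best variants.
    """
    config = config or OptimizationConfig()
    targets = dict(config.target_rates or calibration_targets())
    target_pops = sorted(targets)
    rows = []

    def scan(grids: Mapping[str, np.ndarray], stage: str):
        best = (np.inf, None)
        for combo in itertools.product(*(grids[c] for c in CELL_TYPES)):
            rates = dict(zip(CELL_TYPES, (float(v) for v in combo)))
            sim = evaluate(rates)
            rmspe = compute_rmspe(
                [sim[p] for p in target_pops], [targets[p] for p in target_pops]
            ).value
            rows.append({**{f"r_bg_{c}": rates[c] for c in CELL_TYPES},
                         "stage": stage, "rmspe": rmspe,
                         **{p: sim[p] for p in target_pops}})
            if rmspe < best[0]:
                best = (rmspe, rates)
        return best

    coarse_grids = {c: _grid(config.bounds[c], config.coarse_step) for c in CELL_TYPES}
    if any(g.size == 0 for g in coarse_grids.values()):
        raise ParameterError("empty scan bounds")
    _, coarse_best = scan(coarse_grids, "coarse")

    fine_grids = {
        c: _grid(
            (max(config.bounds[c][0], coarse_best[c] - config.fine_halfwidth),
             min(config.bounds[c][1], coarse_best[c] + config.fine_halfwidth)),
            config.fine_step,
        )
        for c in CELL_TYPES
    }
    _, fine_best = scan(fine_grids, "fine")
    return fine_best, pd.DataFrame(rows)
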