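# barrelcircuit

A layered spiking microcircuit model of a mouse barrel-cortex column with
three inhibitory interneuron types — parvalbumin- (PV), somatostatin- (SOM)
and vasoactive-intestinal-peptide-expressing (VIP) cells — and cell-type-
specific short-term synaptic plasticity (STP).

The package is aimed at computational neuroscientists studying how distinct
interneuron classes shape cortical network dynamics: it builds the column
(13 populations, 6448 leaky integrate-and-fire neurons across L2/3–L6),
derives synaptic weights from postsynaptic-potential definitions, fits
Tsodyks STP parameters (U, F, D) to PSP-amplitude trains, calibrates
background drive against in vivo firing rates, and runs the three standard
protocols — resting state, cell-type-specific Poisson stimulation, and
transient thalamic (VPM) stimulation — with the corresponding analysis
(rates, pairwise spike-count correlations, CV ISI, PSTH peaks, normalized
response curves with t-tests).

At its core are three pieces of standard machinery, implemented exactly:

- LIF neurons with exponential PSCs, `dV/dt = -(V-V_rest)/tau_m + I/C_m`,
  integrated with exact propagators at 0.1 ms resolution, and the PSP-to-PSC
  conversion `PSC = C_m (a-1) PSP / (tau_syn (a^{1/(1-a)} - a^{a/(1-a)}))`
  with `a = tau_syn/tau_m`;
- pairwise-Bernoulli connectivity with log-normal weights and delays, with
  measured connection probabilities rescaled from the experimental sampling
  range to the 200 x 300 um column footprint via an exponential lateral
  decay kernel;
- the Tsodyks synapse (release parameter U, facilitation constant F,
  depression constant D), fitted by exhaustive grid search and weight-scaled
  so the plastic model's steady state matches the static model.

The packaged connection-probability and STP tables are approximate
transcriptions anchored to the values printed in the source text (see
`docs/methods.md` for exactly what is exact and what is approximate).

## Worked example

Simulate one instance of the calibrated resting state and print population
firing rates and asynchronous-irregular statistics:

```python
from barrelcircuit.model import ModelConfig, build_network
from barrelcircuit.dynamics import simulate_network
from barrelcircuit.analysis import (
    compute_population_rates, compute_pairwise_correlation, compute_cv_isi)

net = build_network(ModelConfig(include_thalamus=False), seed=42)
spikes, _ = simulate_network(net, 15_000.0, seed=43)   # 15 s biological time
print(compute_population_rates(spikes, 10_000.0, 15_000.0)[["mean"]].round(2))
print(round(compute_pairwise_correlation(spikes, "L2/3", 10_000.0, 15_000.0), 4),
      round(compute_cv_isi(spikes, "L2/3", 10_000.0, 15_000.0), 3))
```

Output (seed 42/43):

```
            mean
population
L2/3 Exc    0.33
L2/3 PV    14.36
L2/3 SOM    4.65
L2/3 VIP   14.30
L4 Exc      0.59
L4 PV      13.72
L4 SOM      2.92
L5 Exc      8.23
L5 PV      16.71
L5 SOM     24.04
L6 Exc      4.60
L6 PV      24.06
L6 SOM     33.05
0.0014 0.783
```

The calibrated layers track the in vivo reference means (L4 Exc 0.5, L4 PV
10.2, L2/3 VIP 14.6 spikes/s, ...): excitatory cells fire well below one to
a few spikes per second, PV and VIP cells in the tens, and the near-zero
pairwise correlation with CV ISI near one marks the asynchronous-irregular
regime. Stimulating L4 PV cells at 1000 spikes/s suppresses L4 excitatory
firing by roughly 85%, while stimulating L4 SOM cells disinhibits excitatory
cells — an effect that flips sign when the L4 SOM->PV connection probability
is halved (18.2% instead of 36.3%).

A thin CLI wraps the same pipeline:

```
barrelcircuit build                 # export population + probability tables
barrelcircuit rest --instances 1    # resting-state rates and AI statistics
barrelcircuit stimulate "L4 PV"     # cell-type-specific stimulation curves
barrelcircuit thalamic              # PSTH peaks under VPM stimulation
barrelcircuit fit-stp train.csv --rate 10
```

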