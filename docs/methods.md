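# Methods

## Model

`barrelcircuit` simulates one cortical column of mouse barrel (somatosensory)
cortex as a network of current-based leaky integrate-and-fire (LIF) point
neurons. The column spans layers 2/3, 4, 5 and 6 with excitatory (Exc) cells
and three inhibitory interneuron classes — parvalbumin- (PV), somatostatin-
(SOM) and vasoactive-intestinal-peptide-expressing (VIP) cells — for 13
populations and 6448 neurons in total. All VIP cells are collected into a
single L2/3 population, since VIP cells are overwhelmingly supragranular and
connectivity data for deep-layer VIP cells are lacking.

Membrane dynamics follow

    dV/dt = -(V - V_rest)/tau_m + (I_exc + I_inh)/C_m,

with exponentially decaying postsynaptic currents (decay constants 2 ms for
excitatory, 4 ms for inhibitory synapses), a firing threshold V_th, reset to
V_reset and a 2.0 ms absolute refractory period for every neuron. V_reset is
not separately constrained; it is set equal to V_rest per population
(configurable) because the model has no adaptation. Membrane parameters are
layer- and cell-type-specific in vitro measurements; supragranular values
serve L2/3 and L4, infragranular values L5 and L6. To approximate the awake
state, the in vitro membrane time constants are shortened by the
experimentally reported membrane-resistance reductions from Down to Up
states: 50.9% for excitatory and 4.9% for inhibitory cells. Internally the
full-precision adjusted values are used; reporting rounds to one decimal.
One transcribed exception: the supragranular PV time constant is pinned to
the published one-decimal value 3.0 ms although 3.1 x 0.951 recomputes to
2.9 ms; the override is in the parameter table, not in code.

Interneuron counts per layer distribute the layer's inhibitory total over
PV/SOM/VIP proportionally to relative-quantity parameters (largest-remainder
apportionment, which conserves the total exactly; the rounding scheme of the
source is not documented). The packaged relative quantities are the
pre-merge interneuron counts themselves, which reproduce the published
population table exactly; they are overridable.

## Synapses

Synaptic interactions are defined by postsynaptic potential (PSP)
amplitudes: 0.5 ± 0.5 mV for intracortical excitatory, −2.0 ± 2.0 mV for
inhibitory, 0.49 ± 0.13 mV for thalamocortical (halved to 0.245 ± 0.065 mV
onto SOM cells), and a fixed 0.5 mV for background input. A PSP is converted
to the exponential-PSC amplitude that produces it,

    PSC = C_m (a-1) PSP / (tau_syn (a^{1/(1-a)} - a^{a/(1-a)})),  a = tau_syn/tau_m,

with the analytic limit C_m e PSP / tau_syn used near a = 1 (the formula is
0/0 there). PSP magnitudes and delays are log-normal; log-space parameters
are obtained by moment matching so the printed linear-space mean ± SD are
reproduced. Inhibitory weights are drawn as magnitudes and negated
(log-normal support is positive). Delays (1.36 ± 0.51 ms excitatory,
1.43 ± 1.09 ms inhibitory, 1.72 ± 0.73 ms thalamic) are rounded to the
0.1 ms simulation grid with a one-step floor; the background delay is fixed
at 0.1 ms.

## Connectivity

Connections are pairwise Bernoulli per ordered neuron pair (autapses
allowed, multapses collapsed into single stronger synapses). Probabilities
measured in paired recordings apply to a finite lateral sampling range; the
model rescales them to its 200 x 300 um footprint by calibrating an
exponential lateral decay kernel (default length 150 um, a placeholder
magnitude — the calibrated constant is configurable) so its average over the
experimental footprint equals the measured value, then averaging it over the
model footprint (deterministic Gauss-Legendre quadrature; a Monte-Carlo
oracle cross-checks it in the tests). Missing intra-layer entries follow
fill-in rules: Exc->PV copies PV->Exc where unmeasured (Exc/PV pairs
reciprocate with very high probability), L5 SOM-related entries average
L2/3 and L4, and L6 copies L5 except for the measured Exc->Exc entry.
Inter-layer entries are morphology-based estimates; the cell-number-weighted
averaging of morphological subtypes is implemented generically, while the
packaged inter-layer values are pre-combined estimates.

The packaged probability matrix is an approximate transcription: the three
values printed in the source text (L2/3 SOM->PV 11.81%, L4 SOM->PV 36.30%,
L4 SOM->Exc 19.8%) are exact; the remaining entries are best-effort
estimates chosen from the same experimental literature style and constrained
to produce the qualitative operating regime of the original model (a stable,
inhibition-stabilized, asynchronous-irregular resting state). Quantities
that depend on the exact matrix should be read as approximate.

## Short-term plasticity

STP synapses follow the Tsodyks model with release parameter U,
facilitation time constant F and depression time constant D. Per-synapse
state (u, x) is updated event-wise at presynaptic spikes using exact
exponential relaxation over the elapsed interval. Published formulations
differ in whether u relaxes toward 0 or toward U between spikes; the default
here is the reference-implementation convention (u decays toward 0, the
facilitation bump u <- u + U(1-u) is applied at every spike including the
first, u starts at 0), which uniquely makes the first transmitted amplitude
exactly w*U and makes F = 0 equivalent to instantaneous relaxation. The
alternative decay-toward-U variant is selectable by configuration for
cross-checks. F = 0 and D = 0 are exact instantaneous relaxations, not
divisions by zero.

Parameters are fitted to normalized PSP-amplitude trains by exhaustive grid
search (U: 0.05–1.0 step 0.05; F, D: 0–1000 ms step 20 ms) minimizing the
RMSE between simulated and observed trains at the experimental presynaptic
rate. When the experimental analysis subtracted the overlap of preceding
PSPs, the same subtraction is applied to the simulation; below threshold the
membrane is linear, so subtracted amplitudes equal w*u_n*x_n exactly and the
fit runs on the event recursion. Onset-referenced (unsubtracted) amplitudes
are measured on the superposed voltage trace. Ties break toward the smallest
RMSE, then smallest U, F, D in deterministic scan order (degenerate flat
trains make this necessary). The packaged per-projection (U, F, D) matrix is
an approximate, on-grid transcription reproducing the qualitative pattern of
the source fits (depressing Exc->Exc, Exc->PV, PV->* and thalamic->PV;
facilitating Exc->SOM and thalamic->SOM; VIP-related projections static
because the corresponding dataset destabilized the source model and was
excluded).

With STP the effective weights drift; to keep the STP model's resting state
comparable to the static model, each plastic projection's initial weight is
scaled so that the amplitude transmitted at the last spike of a 5 s
fixed-interspike-interval pair simulation (at the presynaptic population's
measured static-model resting rate) matches the static PSC within 0.1 pA
(proportional updates, at most 100 iterations; the relation is linear in the
weight so convergence is immediate). "Last synaptic weight recorded" is
interpreted as the transmitted amplitude w*u*x, the only weight-like
quantity that evolves. Because the procedure consumes measured rates, the
factors are seed-dependent and recorded per run. The transient thalamic
input cannot equilibrate, so its weights are instead scaled as w' = w/u so
the first transmitted amplitude equals the defined weight.

## Inputs

Background: one independent homogeneous Poisson source per neuron with a
fixed 0.5 mV EPSP, 0.1 ms delay, and a cell-type-specific (layer-independent)
rate; present in every simulation. Stimulation: a second gated Poisson
source (0.5 mV EPSP) onto one cell type in one layer, 1 s on / 1 s off,
repeated per level; nine levels per protocol including zero. The exact
nonzero levels are not published; the default is eight equally spaced levels
up to 1000 spikes/s for Exc and PV or 200 spikes/s for SOM and VIP, which
places every quoted level (125, 200, 250, 375, 1000) on the grid and is
fully overridable. Levels run in ascending order within one simulation (the
source is not explicit on this; both modes are supported).

Thalamic input: 230 relay cells — the column total 6448 divided by the
S1-to-VPM cell ratio 56 gives a 115-cell barreloid estimate, doubled to
account for multi-whisker receptive fields. Each relay cell fires an
independent inhomogeneous Poisson train (thinning against the profile
maximum at 0.1 ms resolution) following a log-normal rate time course
r(t) = A exp(-(ln(t-t0)-mu)^2/(2 sigma^2))/(t-t0), repeated every second.
The packaged profile parameters are approximate figure-derived stand-ins
(peak ~55 spikes/s a few ms after onset, decayed within ~50 ms); the fitting
operation recovers exact parameters from clean samples and is what users
should run on their own digitized data. Relay cells contact Exc and PV cells
in every layer, SOM cells only in L4 at half probability and weight, and
never VIP cells.

## Calibration

The four background rates are calibrated against seven in vivo reference
means (L2/3 Exc/PV/SOM/VIP and L4 Exc/PV/SOM; deeper layers are excluded
because their connectivity is least constrained). The objective is the
root-mean-square percentage error of mean population rates over t = 10–15 s,
scanned exhaustively on a coarse 500 spikes/s grid and then a fine
100 spikes/s grid around the coarse optimum, separately for the static and
STP model versions. The packaged optimum (Exc 4400, PV 7000, SOM 2500,
VIP 3300 spikes/s) was produced by this procedure at reduced budget
(shortened instances during the coarse stage, the fine stage on the
100 spikes/s grid) — a package-level choice of problem size; it reproduces
the published ordering PV > Exc > VIP > SOM. The SOM/VIP pair sits near a
regime boundary of their mutual-inhibition loop, so SOM background above
~2600 spikes/s switches the column into a SOM-dominant state; the packaged
value keeps it in the VIP-active, SOM-quiet state matching the reference
rates.

## Analysis

Population rates are per-neuron spike counts over the analysis window;
the first 10 s of every full-length run are discarded (shorter warmups are
used in reduced test profiles). Pairwise spike-count correlations use 10 ms
bins over 200 neurons sampled per layer regardless of cell type after
excluding silent neurons; CV ISI uses an independent 200-neuron draw after
excluding neurons below 1 spike/s. Both samplings are seeded. PSTHs use
0.5 ms bins normalized by bin width, neuron count and repeat count; peaks
are searched 0–50 ms post-onset with ties broken toward the earliest bin.
Peak-RMSE comparisons use zero as the VIP amplitude criterion and omit VIP
from the timing comparison (no VIP response is observable in the reference
data). Stimulus responses are rates over the last 500 ms of each on-window,
averaged over repeats, normalized per instance to the zero level, and tested
against 1 with a two-tailed one-sample t-test across instances;
zero-variance levels return p = 1 with a flag, and instances with a zero
baseline are excluded and flagged. The asynchronous-irregular criteria
packaged with the model are approximate compilation stand-ins used only for
flagged pass/fail reporting.

## What the synthetic data do and do not show

The fixture generators emulate (i) normalized PSP-amplitude trains from a
known Tsodyks synapse at fixed presynaptic rate, optionally with
multiplicative Gaussian noise, and (ii) miniature columns with the full
13-population topology at a fraction of the size. Passing tests on these
fixtures demonstrate correctness of the algorithms (fitting, calibration,
statistics, simulation) under known ground truth; they do not validate the
approximate transcriptions of the probability, STP and thalamic-profile
tables against the original figures, and miniature columns do not preserve
the full column's operating point (recurrent inhibition scales with absolute
cell counts, so small columns run hot).

## Numerical choices and problem sizes

Simulation step 0.1 ms; subthreshold integration by exact exponential
propagators (halving the step changes trajectories only through spike-time
discretization); threshold detection at step boundaries without
interpolation; the refractory clamp holds V at V_reset while synaptic
currents continue to evolve. Initial membrane potentials are uniform between
rest and threshold per neuron (seeded, configurable to all-at-rest) to avoid
synchronous onset transients. Event delivery uses a ring buffer over the
0.1 ms grid; every run is bitwise reproducible given (configuration, seed),
and per-instance seeds derive deterministically from a base seed.

The default test and acceptance profiles use scaled-down problem sizes
chosen as package defaults: single instances with 2.5–3 s warmups, two-level
stimulation protocols with 3 repeats, and 5 s analysis windows; full-scale
protocols (20 instances, 9 levels, 20 repeats, 10 s warmup) are what the
configuration objects default to for research use.

## Known limitations

The probability matrix, STP matrix, interneuron relative quantities,
thalamic rate profile and AI-state criteria are approximate transcriptions
(figure-derived in the original; reconstructed here), so quantitative
network-level results track the original qualitatively, not digit-for-digit.
L5/L6 rates are uncalibrated by design and run high for SOM cells. No
conductance synapses, no NMDA component, no neuron-model heterogeneity
within populations, no explicit Martinotti/non-Martinotti SOM subtypes, no
higher-order thalamus, and no spatial structure beyond the probability
derivation.
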