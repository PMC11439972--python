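"""Helper for the acceptance script: a one-neuron network with a single
external synapse, used for the PSP/PSC round-trip measurement."""

import numpy as np

from barrelcircuit.dynamics import Network


def single_neuron_network(params, psc, delay_steps=10):
    z1 = np.zeros(1)
    return Network(
        pop_of=np.zeros(1, np.int64), pop_names=("X",),
        tau_m=np.full(1, params.tau_m), c_m=np.full(1, params.c_m),
        v_rest=np.full(1, params.v_rest), v_th=np.full(1, params.v_th),
        v_reset=np.full(1, params.v_reset), tau_ref=np.full(1, params.tau_ref),
        indptr=np.array([0, 0, 1], np.int64),
        syn_tgt=np.array([0], np.int64),
        syn_w=np.array([psc]),
        syn_delay_steps=np.array([delay_steps], np.int64),
        syn_is_exc=np.array([1], np.uint8),
        syn_has_stp=np.array([0], np.uint8),
        syn_U=z1, syn_F=z1, syn_D=z1,
        n_external=1,
    )
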