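"""Numba simulation kernel: fixed-step (0.1 ms) LIF network with
exponentially decaying PSCs, Tsodyks short-term plasticity, per-neuron
Poisson background/stimulus sources and scheduled external spike sources.

Subthreshold integration uses exact exponential propagators, so halving the
step would change trajectories only through spike-time discretization.
Single-threaded and fully deterministic for a given seed.
"""

import numpy as np
from numba import njit

#: u decays toward zero between spikes; facilitation bump at every spike
VARIANT_DECAY_TO_ZERO = 0
#: u decays toward U between spikes (alternative published convention)
VARIANT_DECAY_TO_U = 1


@njit(cache=True, inline="always")
def _stp_amplitude(t_ms, w, U, F, D, u, x, t_last, variant):
    """Effective amplitude and updated (u, x, t_last) at a presynaptic spike."""
    if t_last >= 0.0:
        dt_sp = t_ms - t_last
        if variant == VARIANT_DECAY_TO_ZERO:
            u = u * np.exp(-dt_sp / F) if F > 0.0 else 0.0
        else:
            u = U + (u - U) * np.exp(-dt_sp / F) if F > 0.0 else U
        x = 1.0 + (x - 1.0) * np.exp(-dt_sp / D) if D > 0.0 else 1.0
    u = u + U * (1.0 - u)
    amp = w * u * x
    x = x * (1.0 - u)
    return amp, u, x, t_ms


@njit(cache=True)
def run_network(
    n_steps,
    dt,
    seed,
    # per-neuron membrane propagators and parameters
    p_v, k_e, k_i, d_e, d_i, v_rest, v_th, v_reset, ref_steps,
    v_init,
    # synapses, CSR by source (cortical neurons then external sources)
    indptr, syn_tgt, syn_w, syn_delay_steps, syn_is_exc,
    syn_has_stp, syn_U, syn_F, syn_D, syn_u, syn_x, syn_tlast,
    stp_variant,
    # background and stimulus Poisson drive
    bg_lam, bg_w, stim_lam_t, stim_mask, stim_w,
    # scheduled external source spikes (sorted by step; ids >= n_neurons)
    ext_steps, ext_ids,
    # voltage recording
    rec_ids,
):
    np.random.seed(seed)
    n = p_v.shape[0]
    max_delay = 1
    for s in range(syn_delay_steps.shape[0]):
        if syn_delay_steps[s] > max_delay:
            max_delay = syn_delay_steps[s]
    ring_len = max_delay + 2
    buf_e = np.zeros((ring_len, n))
    buf_i = np.zeros((ring_len, n))

    v = v_init.copy()
    i_e = np.zeros(n)
    i_i = np.zeros(n)
    refr = np.zeros(n, np.int64)

    cap = 1024
    spk_t = np.empty(cap)
    spk_id = np.empty(cap, np.int64)
    n_spk = 0

    n_rec = rec_ids.shape[0]
    v_rec = np.zeros((n_steps, n_rec)) if n_rec > 0 else np.zeros((1, 1))

    ext_ptr = 0
    n_ext = ext_steps.shape[0]

    for step in range(n_steps):
        slot = step % ring_len
        # scheduled external sources spiking at this step
        while ext_ptr < n_ext and ext_steps[ext_ptr] == step:
            src = ext_ids[ext_ptr]
            t_ms = step * dt
            for s in range(indptr[src], indptr[src + 1]):
                if syn_has_stp[s] == 1:
                    amp, syn_u[s], syn_x[s], syn_tlast[s] = _stp_amplitude(
                        t_ms, syn_w[s], syn_U[s], syn_F[s], syn_D[s],
                        syn_u[s], syn_x[s], syn_tlast[s], stp_variant,
                    )
                else:
                    amp = syn_w[s]
                a_slot = (step + syn_delay_steps[s]) % ring_len
                if syn_is_exc[s] == 1:
                    buf_e[a_slot, syn_tgt[s]] += amp
                else:
                    buf_i[a_slot, syn_tgt[s]] += amp
            ext_ptr += 1

        stim_lam = stim_lam_t[step]
        for i in range(n):
            # deliver ring-buffer arrivals for this step
            i_e[i] += buf_e[slot, i]
            i_i[i] += buf_i[slot, i]
            buf_e[slot, i] = 0.0
            buf_i[slot, i] = 0.0
            # independent Poisson background (one source per neuron), 1-step delay
            if bg_lam[i] > 0.0:
                k = np.random.poisson(bg_lam[i])
                if k > 0:
                    buf_e[(step + 1) % ring_len, i] += k * bg_w[i]
            if stim_lam > 0.0 and stim_mask[i] == 1:
                k = np.random.poisson(stim_lam)
                if k > 0:
                    buf_e[(step + 1) % ring_len, i] += k * stim_w[i]
            # membrane update: exact propagators; clamp during refractoriness
            if refr[i] > 0:
                refr[i] -= 1
                v[i] = v_reset[i]
            else:
                v[i] = (
                    v_rest[i]
                    + (v[i] - v_rest[i]) * p_v[i]
                    + i_e[i] * k_e[i]
                    + i_i[i] * k_i[i]
                )
            i_e[i] *= d_e[i]
            i_i[i] *= d_i[i]
            # threshold crossing at the step boundary
            if refr[i] == 0 and v[i] >= v_th[i]:
                t_spike = (step + 1) * dt
                v[i] = v_reset[i]
                refr[i] = ref_steps[i]
                if n_spk >= cap:
                    cap *= 2
                    new_t = np.empty(cap)
                    new_id = np.empty(cap, np.int64)
                    new_t[:n_spk] = spk_t[:n_spk]
                    new_id[:n_spk] = spk_id[:n_spk]
                    spk_t = new_t
                    spk_id = new_id
                spk_t[n_spk] = t_spike
                spk_id[n_spk] = i
                n_spk += 1
                for s in range(indptr[i], indptr[i + 1]):
                    if syn_has_stp[s] == 1:
                        amp, syn_u[s], syn_x[s], syn_tlast[s] = _stp_amplitude(
                            t_spike, syn_w[s], syn_U[s], syn_F[s], syn_D[s],
                            syn_u[s], syn_x[s], syn_tlast[s], stp_variant,
                        )
                    else:
                        amp = syn_w[s]
                    a_slot = (step + 1 + syn_delay_steps[s]) % ring_len
                    if syn_is_exc[s] == 1:
                        buf_e[a_slot, syn_tgt[s]] += amp
                    else:
                        buf_i[a_slot, syn_tgt[s]] += amp

        for r in range(n_rec):
            v_rec[step, r] = v[rec_ids[r]]

    return spk_t[:n_spk], spk_id[:n_spk], v_rec
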