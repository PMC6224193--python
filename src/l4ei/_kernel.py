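"""Numba integration kernels for the leaky integrate-and-fire network.

Unit system: mV, ms, nS, pA, pF (consistent: nS*mV = pA, pF*mV/ms = pA).

Integration is exponential-Euler: synaptic conductances decay exactly between
events; over one step the membrane relaxes toward the instantaneous
steady-state voltage with the instantaneous total conductance held fixed.
The scheme is unconditionally stable and keeps V within the reversal
potentials for non-negative conductances.

External drive is drawn as per-population aggregate Poisson counts per step,
with each event assigned to a uniformly chosen neuron of the population.  By
the superposition/thinning property of Poisson processes this is
distributionally identical to independent per-neuron compound trains (all
channels of one pathway share a single weight), at a fraction of the RNG
cost.
"""

import numpy as np
from numba import njit

__all__ = ["run_network", "run_single"]


@njit(cache=True, fastmath=True)
def run_network(
    n_steps,
    dt,
    N,
    NE,
    C,
    gL,
    VL,
    Vexc,
    Vinh,
    Vtheta,
    Vreset,
    ref_steps,
    syn_decay,
    out_ptr,
    out_idx,
    w_ee,
    w_ei,
    w_ie,
    w_ii,
    delay_steps,
    lam_th_e,
    lam_th_i,
    lam_bkg,
    w_th_e,
    w_th_i,
    w_bkg,
    use_ext_matrix,
    ext_exc,
    V0,
    seed,
    record_v_from,
):
    """Integrate the full recurrent network; return spikes and diagnostics.

    Returns (spike_ids, spike_steps, n_spikes, v_sum, v_nsteps, err_step,
    overflow) where err_step >= 0 names the first step at which the state
    became non-finite (-1 if none) and overflow flags spike-buffer exhaustion.
    """
    np.random.seed(seed)
    V = V0.copy()
    ge = np.zeros(N)
    gi = np.zeros(N)
    ref = np.zeros(N, np.int64)
    D = delay_steps + 1
    buf_e = np.zeros((D, N))
    buf_i = np.zeros((D, N))
    v_sum = np.zeros(N)
    v_nsteps = 0

    denom = ref_steps if ref_steps > 0 else 1
    cap = N * (n_steps // denom + 1)
    if cap > 60_000_000:
        cap = 60_000_000
    spike_ids = np.empty(cap, np.int32)
    spike_steps = np.empty(cap, np.int32)
    ns = 0
    overflow = False
    err_step = -1
    NI = N - NE

    for step in range(n_steps):
        slot = step % D
        for i in range(N):
            ge[i] += buf_e[slot, i]
            gi[i] += buf_i[slot, i]
            buf_e[slot, i] = 0.0
            buf_i[slot, i] = 0.0

        if use_ext_matrix:
            for i in range(N):
                ge[i] += ext_exc[step, i]
        else:
            k = np.random.poisson(lam_th_e)
            for _ in range(k):
                ge[np.random.randint(0, NE)] += w_th_e
            if NI > 0:
                k = np.random.poisson(lam_th_i)
                for _ in range(k):
                    ge[NE + np.random.randint(0, NI)] += w_th_i
            k = np.random.poisson(lam_bkg)
            for _ in range(k):
                ge[np.random.randint(0, N)] += w_bkg

        dslot = (step + delay_steps) % D
        record = record_v_from >= 0 and step >= record_v_from
        for i in range(N):
            if ref[i] > 0:
                ref[i] -= 1
                V[i] = Vreset
            else:
                gtot = gL + ge[i] + gi[i]
                vinf = (gL * VL + ge[i] * Vexc + gi[i] * Vinh) / gtot
                V[i] = vinf + (V[i] - vinf) * np.exp(-gtot * dt / C)
                if not np.isfinite(V[i]):
                    if err_step < 0:
                        err_step = step
                elif V[i] > Vtheta:
                    if ns < cap:
                        spike_ids[ns] = i
                        spike_steps[ns] = step + 1
                        ns += 1
                    else:
                        overflow = True
                    V[i] = Vreset
                    ref[i] = ref_steps
                    if i < NE:
                        for p in range(out_ptr[i], out_ptr[i + 1]):
                            t = out_idx[p]
                            if t < NE:
                                buf_e[dslot, t] += w_ee
                            else:
                                buf_e[dslot, t] += w_ei
                    else:
                        for p in range(out_ptr[i], out_ptr[i + 1]):
                            t = out_idx[p]
                            if t < NE:
                                buf_i[dslot, t] += w_ie
                            else:
                                buf_i[dslot, t] += w_ii
            if record:
                v_sum[i] += V[i]
        if record:
            v_nsteps += 1
        if err_step >= 0:
            break

        for i in range(N):
            ge[i] *= syn_decay
            gi[i] *= syn_decay

    return (
        spike_ids[:ns].copy(),
        spike_steps[:ns].copy(),
        ns,
        v_sum,
        v_nsteps,
        err_step,
        overflow,
    )


@njit(cache=True)
def run_single(
    n_steps,
    dt,
    C,
    gL,
    VL,
    Vexc,
    Vinh,
    Vtheta,
    Vreset,
    ref_steps,
    I_inj,
    ge_clamp,
    gi_clamp,
    V0,
):
    """Single LIF neuron under constant injected current and/or clamped
    conductances.  Returns (V trace incl. t=0, spike step indices)."""
    gtot = gL + ge_clamp + gi_clamp
    vinf = (gL * VL + ge_clamp * Vexc + gi_clamp * Vinh + I_inj) / gtot
    f = np.exp(-gtot * dt / C)
    V = V0
    out = np.empty(n_steps + 1)
    out[0] = V
    spikes = np.empty(n_steps, np.int32)
    ns = 0
    ref = 0
    for step in range(n_steps):
        if ref > 0:
            ref -= 1
            V = Vreset
        else:
            V = vinf + (V - vinf) * f
            if V > Vtheta:
                spikes[ns] = step + 1
                ns += 1
                V = Vreset
                ref = ref_steps
        out[step + 1] = V
    return out, spikes[:ns].copy()
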