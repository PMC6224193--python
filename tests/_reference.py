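"""Independent reference integrator: vectorized forward Euler.

Deliberately a different numerical scheme from the package's
exponential-Euler kernel (explicit Euler for both the membrane and the
conductance decay), driven by a pre-drawn external input realization so
that a comparison against the native integrator is paired: any rate
difference reflects the integration scheme, not the stochastic drive.
"""

import numpy as np

from l4ei import Connectivity, NetworkSpec, NeuronParams


def forward_euler_rates(
    neuron: NeuronParams,
    spec: NetworkSpec,
    conn: Connectivity,
    ext_exc: np.ndarray,  # (n_steps, N) conductance increments
    dt: float,
    V0: np.ndarray,
    transient_discard: float,
) -> tuple[float, float]:
    n_steps, n = ext_exc.shape
    assert n == spec.N
    delay_steps = max(1, int(round(spec.delay / dt)))
    ref_steps = int(round(neuron.t_ref / dt))
    d = delay_steps + 1
    w_e = spec.weight_scale * spec.j
    w_i = spec.weight_scale * spec.g_rc * spec.j

    # out-adjacency masks per source neuron
    out_ptr, out_idx = conn.out_csr()

    v = V0.copy()
    ge = np.zeros(n)
    gi = np.zeros(n)
    ref = np.zeros(n, dtype=int)
    buf_e = np.zeros((d, n))
    buf_i = np.zeros((d, n))
    ne_spikes = ni_spikes = 0
    discard_step = int(round(transient_discard / dt))

    for step in range(n_steps):
        slot = step % d
        ge += buf_e[slot] + ext_exc[step]
        gi += buf_i[slot]
        buf_e[slot] = 0.0
        buf_i[slot] = 0.0

        active = ref == 0
        i_syn = (
            -neuron.gL * (v - neuron.VL)
            - ge * (v - neuron.Vexc)
            - gi * (v - neuron.Vinh)
        )
        v = np.where(active, v + dt * i_syn / neuron.C, neuron.Vreset)
        ref = np.maximum(ref - 1, 0)

        spiking = np.flatnonzero(active & (v > neuron.Vtheta))
        if spiking.size:
            v[spiking] = neuron.Vreset
            ref[spiking] = ref_steps
            dslot = (step + delay_steps) % d
            for i in spiking:
                targets = out_idx[out_ptr[i] : out_ptr[i + 1]]
                if i < spec.NE:
                    np.add.at(buf_e[dslot], targets, w_e)
                else:
                    np.add.at(buf_i[dslot], targets, w_i)
            if step >= discard_step:
                ne_spikes += int(np.count_nonzero(spiking < spec.NE))
                ni_spikes += int(np.count_nonzero(spiking >= spec.NE))

        ge -= dt * ge / neuron.tau_syn
        gi -= dt * gi / neuron.tau_syn

    window_s = (n_steps - discard_step) * dt / 1000.0
    return ne_spikes / (spec.NE * window_s), ni_spikes / (spec.NI * window_s)
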