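"""Conductance-based LIF network model of a local layer 4 circuit.

The model is a sparse random network of N = 5000 leaky integrate-and-fire
neurons (80% excitatory, 20% inhibitory).  Each membrane obeys

    C dV/dt = -gL (V - VL) - g_exc(t) (V - Vexc) - g_inh(t) (V - Vinh)

where the synaptic conductances jump by a fixed peak conductance on each
presynaptic spike and decay exponentially with tau_syn = 5 ms.  Recurrent
excitatory synapses have peak conductance j, inhibitory ones g_rc * j.
Every neuron receives n_lgn independent thalamic Poisson trains at R_lgn and
n_bkg background trains at R_bkg, all with weight j_s, except that thalamic
drive onto inhibitory neurons is scaled by g_fw > 1 (the measured stronger
feedforward drive to PV+ cells).

Reset potential, refractory period, synaptic delay, initial conditions and
the integrator are not constrained by the measurements the model encodes;
the defaults chosen here (Vreset = VL, t_ref = 2 ms, 1 ms recurrent delay,
exponential-Euler at dt = 0.1 ms, V(0) uniform on [VL, Vtheta)) follow
common practice for sparse random E-I networks and are recorded in every
result.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from ._kernel import run_network, run_single

__all__ = [
    "NeuronParams",
    "NetworkSpec",
    "InputSpec",
    "Connectivity",
    "SimResult",
    "PathwayMultipliers",
    "TABLE1_NEURON",
    "TABLE1_NETWORK",
    "TABLE1_INPUT",
    "build_connectivity",
    "simulate",
    "population_rates",
    "free_membrane_stats",
    "simulate_single_neuron",
]


class IntegrationError(RuntimeError):
    """Raised when the network state becomes non-finite during integration."""


@dataclass(frozen=True)
class NeuronParams:
    """Single-neuron parameters (units: pF, nS, mV, ms)."""

    C: float = 200.0
    gL: float = 10.0
    VL: float = -70.0
    Vexc: float = 0.0
    Vinh: float = -85.0
    Vtheta: float = -50.0
    Vreset: float = -70.0
    t_ref: float = 2.0
    tau_syn: float = 5.0

    def __post_init__(self) -> None:
        if not (self.Vinh < self.VL < self.Vtheta < self.Vexc):
            raise ValueError(
                "require Vinh < VL < Vtheta < Vexc, got "
                f"{self.Vinh}, {self.VL}, {self.Vtheta}, {self.Vexc}"
            )
        if self.C <= 0 or self.gL <= 0 or self.tau_syn <= 0:
            raise ValueError("C, gL and tau_syn must be positive")
        if self.t_ref < 0:
            raise ValueError("t_ref must be >= 0")

    @property
    def rheobase(self) -> float:
        """Minimal constant current (pA) that can reach threshold: gL (Vtheta - VL)."""
        return self.gL * (self.Vtheta - self.VL)


@dataclass(frozen=True)
class NetworkSpec:
    """Population sizes, in-degrees and recurrent weights.

    The fixed in-degree rule (every neuron receives exactly ``in_degree_e``
    excitatory and ``in_degree_i`` inhibitory connections) is the binding
    wiring rule; the 10% connection probability is the density this implies
    at full size.
    """

    N: int = 5000
    NE: int = 4000
    NI: int = 1000
    in_degree_e: int = 400
    in_degree_i: int = 100
    j: float = 0.3
    g_rc: float = 8.0
    delay: float = 1.0
    #: multiplier on all recurrent weights; > 1 in size-reduced networks to
    #: preserve each neuron's total recurrent conductance (in-degree x weight)
    weight_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.NE + self.NI != self.N:
            raise ValueError(f"NE + NI must equal N ({self.NE}+{self.NI}!={self.N})")
        if self.in_degree_e > self.NE or self.in_degree_i > self.NI:
            raise ValueError("in-degrees cannot exceed population sizes")
        if self.j <= 0 or self.g_rc <= 0 or self.weight_scale <= 0:
            raise ValueError("j, g_rc and weight_scale must be positive")

    @classmethod
    def scaled(cls, N: int, **overrides) -> "NetworkSpec":
        """Reduced-size network with proportional in-degrees (80/20 split).

        Recurrent weights are compensated by the in-degree ratio so every
        neuron keeps the full-size total recurrent conductance; ``j`` keeps
        its published full-size meaning.
        """
        ne = int(round(0.8 * N))
        ni = N - ne
        k_e = max(1, int(round(0.1 * ne)))
        kw = dict(
            N=N,
            NE=ne,
            NI=ni,
            in_degree_e=k_e,
            in_degree_i=max(1, int(round(0.1 * ni))),
            weight_scale=cls().in_degree_e / k_e,
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass(frozen=True)
class InputSpec:
    """External Poisson drive (thalamic + background).

    ``g_fw`` scales thalamic drive onto inhibitory neurons only; background
    drive has the same weight ``j_s`` for both cell types and is never
    scaled by any scenario.
    """

    j_s: float = 0.5
    g_fw: float = 1.25
    n_lgn: int = 100
    R_lgn: float = 8.0
    n_bkg: int = 100
    R_bkg: float = 14.2

    def __post_init__(self) -> None:
        if min(self.j_s, self.g_fw) <= 0 or min(self.n_lgn, self.n_bkg) < 1:
            raise ValueError("input weights must be positive and channel counts >= 1")
        if self.R_lgn < 0 or self.R_bkg < 0:
            raise ValueError("input rates must be >= 0")


TABLE1_NEURON = NeuronParams()
TABLE1_NETWORK = NetworkSpec()
TABLE1_INPUT = InputSpec()


@dataclass(frozen=True)
class PathwayMultipliers:
    """Per-pathway weight multipliers applied on top of the baseline weights."""

    tc_e: float = 1.0  # thalamic -> excitatory
    tc_i: float = 1.0  # thalamic -> inhibitory
    bkg: float = 1.0  # background -> all (scenarios never touch this)
    ee: float = 1.0  # recurrent E -> E
    ei: float = 1.0  # recurrent E -> I
    ie: float = 1.0  # recurrent I -> E
    ii: float = 1.0  # recurrent I -> I


@dataclass
class Connectivity:
    """Fixed in-degree random wiring: per-target presynaptic source lists."""

    sources_e: np.ndarray  # (N, in_degree_e) int32, values in [0, NE)
    sources_i: np.ndarray  # (N, in_degree_i) int32, values in [NE, N)
    NE: int
    seed: int

    @property
    def N(self) -> int:
        return self.sources_e.shape[0]

    def out_csr(self) -> tuple[np.ndarray, np.ndarray]:
        """Out-adjacency (source -> targets) in CSR form for the integrator."""
        n = self.N
        src = np.concatenate([self.sources_e.ravel(), self.sources_i.ravel()])
        tgt = np.concatenate(
            [
                np.repeat(np.arange(n, dtype=np.int32), self.sources_e.shape[1]),
                np.repeat(np.arange(n, dtype=np.int32), self.sources_i.shape[1]),
            ]
        )
        order = np.argsort(src, kind="stable")
        out_idx = tgt[order].astype(np.int32)
        counts = np.bincount(src, minlength=n)
        out_ptr = np.zeros(n + 1, dtype=np.int64)
        np.cumsum(counts, out=out_ptr[1:])
        return out_ptr, out_idx


def build_connectivity(spec: NetworkSpec, seed: int) -> Connectivity:
    """Sample exact-in-degree wiring without autapses or duplicate edges.

    Every neuron receives exactly ``in_degree_e`` distinct excitatory and
    ``in_degree_i`` distinct inhibitory sources, uniformly without
    replacement, excluding itself.
    """
    rng = np.random.default_rng(seed)
    n, ne, ni = spec.N, spec.NE, spec.NI
    # a target inside its own pool excludes itself
    if ne > 0 and spec.in_degree_e > ne - 1:
        raise ValueError("in_degree_e infeasible once autapses are excluded")
    if ni > 0 and spec.in_degree_i > ni - 1:
        raise ValueError("in_degree_i infeasible once autapses are excluded")
    src_e = np.empty((n, spec.in_degree_e), dtype=np.int32)
    src_i = np.empty((n, spec.in_degree_i), dtype=np.int32)
    for i in range(n):
        if i < ne:
            pick = rng.choice(ne - 1, size=spec.in_degree_e, replace=False)
            pick[pick >= i] += 1  # skip self
            src_e[i] = pick
            src_i[i] = ne + rng.choice(ni, size=spec.in_degree_i, replace=False)
        else:
            src_e[i] = rng.choice(ne, size=spec.in_degree_e, replace=False)
            pick = rng.choice(ni - 1, size=spec.in_degree_i, replace=False)
            pick[pick >= i - ne] += 1
            src_i[i] = ne + pick
    return Connectivity(sources_e=src_e, sources_i=src_i, NE=ne, seed=seed)


@dataclass
class SimResult:
    """Spike raster plus steady-state population rates."""

    spike_ids: np.ndarray  # int32 neuron indices
    spike_times: np.ndarray  # float64 ms
    duration: float
    NE: int
    NI: int
    rate_e: float
    rate_i: float
    transient_discard: float
    v_mean: Optional[np.ndarray] = None  # per-neuron time-averaged V (if recorded)
    meta: dict = field(default_factory=dict)


def population_rates(
    result: SimResult, transient_discard: Optional[float] = None
) -> tuple[float, float]:
    """Mean steady-state rate (Hz) per neuron for the E and I populations.

    Counts spikes in [transient_discard, duration] and divides by population
    size times the analysis window.
    """
    disc = result.transient_discard if transient_discard is None else transient_discard
    window_ms = result.duration - disc
    if window_ms <= 0:
        raise ValueError("invalid window: transient_discard >= duration")
    keep = result.spike_times >= disc
    ids = result.spike_ids[keep]
    ne_spikes = int(np.count_nonzero(ids < result.NE))
    ni_spikes = ids.size - ne_spikes
    window_s = window_ms / 1000.0
    rate_e = ne_spikes / (result.NE * window_s) if result.NE else 0.0
    rate_i = ni_spikes / (result.NI * window_s) if result.NI else 0.0
    return rate_e, rate_i


def simulate(
    neuron: NeuronParams,
    spec: NetworkSpec,
    input_spec: InputSpec,
    conn: Connectivity,
    duration: float,
    seed: int,
    weight_overrides: Optional[PathwayMultipliers] = None,
    dt: float = 0.1,
    transient_discard: float = 500.0,
    record_v_mean: bool = False,
    ext_exc: Optional[np.ndarray] = None,
    V0: Optional[np.ndarray] = None,
) -> SimResult:
    """Integrate the network for ``duration`` ms and report steady-state rates.

    ``weight_overrides`` rescales individual pathways (scenario application).
    ``ext_exc`` optionally replaces the internally drawn external Poisson
    drive with a precomputed (n_steps, N) matrix of excitatory-conductance
    increments, for paired-input comparisons and oracle tests.
    ``seed`` controls both the initial voltages and the Poisson realization;
    the connectivity carries its own seed.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if conn.N != spec.N:
        raise ValueError("connectivity does not match network spec")
    mult = weight_overrides or PathwayMultipliers()
    n_steps = int(round(duration / dt))
    delay_steps = max(1, int(round(spec.delay / dt)))
    ref_steps = int(round(neuron.t_ref / dt))

    ss = np.random.SeedSequence(seed)
    state = ss.generate_state(2)
    kernel_seed = int(state[0] % (2**31 - 1))
    if V0 is None:
        init_rng = np.random.default_rng(state[1])
        V0 = init_rng.uniform(neuron.VL, neuron.Vtheta, size=spec.N)
    else:
        V0 = np.asarray(V0, dtype=float)
        if V0.shape != (spec.N,):
            raise ValueError("V0 must have one entry per neuron")

    # per-step aggregate external rates (events per step per population)
    dt_s = dt / 1000.0
    lam_th_e = spec.NE * input_spec.n_lgn * input_spec.R_lgn * dt_s
    lam_th_i = spec.NI * input_spec.n_lgn * input_spec.R_lgn * dt_s
    lam_bkg = spec.N * input_spec.n_bkg * input_spec.R_bkg * dt_s

    use_ext = ext_exc is not None
    if use_ext:
        if ext_exc.shape != (n_steps, spec.N):
            raise ValueError("ext_exc must have shape (n_steps, N)")
        ext = np.ascontiguousarray(ext_exc, dtype=np.float64)
    else:
        ext = np.zeros((1, 1))

    out_ptr, out_idx = conn.out_csr()
    spk_ids, spk_steps, ns, v_sum, v_nsteps, err_step, overflow = run_network(
        n_steps,
        dt,
        spec.N,
        spec.NE,
        neuron.C,
        neuron.gL,
        neuron.VL,
        neuron.Vexc,
        neuron.Vinh,
        neuron.Vtheta,
        neuron.Vreset,
        ref_steps,
        float(np.exp(-dt / neuron.tau_syn)),
        out_ptr,
        out_idx,
        spec.weight_scale * spec.j * mult.ee,
        spec.weight_scale * spec.j * mult.ei,
        spec.weight_scale * spec.g_rc * spec.j * mult.ie,
        spec.weight_scale * spec.g_rc * spec.j * mult.ii,
        delay_steps,
        lam_th_e,
        lam_th_i,
        lam_bkg,
        input_spec.j_s * mult.tc_e,
        input_spec.g_fw * input_spec.j_s * mult.tc_i,
        input_spec.j_s * mult.bkg,
        use_ext,
        ext,
        V0,
        kernel_seed,
        int(round(transient_discard / dt)) if record_v_mean else -1,
    )
    if err_step >= 0:
        raise IntegrationError(
            f"integration failure: non-finite membrane state at step {err_step} "
            f"(t = {err_step * dt:.3f} ms)"
        )
    if overflow:
        raise IntegrationError("spike buffer overflow (pathological firing)")

    result = SimResult(
        spike_ids=spk_ids,
        spike_times=spk_steps.astype(np.float64) * dt,
        duration=duration,
        NE=spec.NE,
        NI=spec.NI,
        rate_e=0.0,
        rate_i=0.0,
        transient_discard=transient_discard,
        v_mean=(v_sum / max(v_nsteps, 1)) if record_v_mean else None,
        meta={
            "seed": seed,
            "dt_ms": dt,
            "Vreset_mV": neuron.Vreset,
            "t_ref_ms": neuron.t_ref,
            "delay_ms": spec.delay,
            "multipliers": mult,
        },
    )
    result.rate_e, result.rate_i = population_rates(result)
    return result


def free_membrane_stats(
    neuron: NeuronParams, input_spec: InputSpec, is_inhibitory: bool
) -> dict:
    """Analytic mean conductance and free membrane potential (no recurrence).

    By Campbell's theorem, a compound Poisson conductance with increment w,
    rate R and exponential decay tau has mean w * tau * R.  The free mean
    voltage ignores threshold: V = (gL VL + <g> Vexc) / (gL + <g>).
    """
    w_th = input_spec.g_fw * input_spec.j_s if is_inhibitory else input_spec.j_s
    tau_s = neuron.tau_syn / 1000.0
    mean_g = (
        w_th * tau_s * input_spec.n_lgn * input_spec.R_lgn
        + input_spec.j_s * tau_s * input_spec.n_bkg * input_spec.R_bkg
    )
    mean_v = (neuron.gL * neuron.VL + mean_g * neuron.Vexc) / (neuron.gL + mean_g)
    return {"mean_g_exc": mean_g, "mean_V": mean_v}


def simulate_single_neuron(
    neuron: NeuronParams,
    duration: float,
    dt: float = 0.01,
    I_inj: float = 0.0,
    g_exc_clamp: float = 0.0,
    g_inh_clamp: float = 0.0,
    V0: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Single LIF neuron under constant drive.

    Returns (voltage trace including t = 0, spike times in ms).  Used by the
    FI-protocol generator and as the substrate for closed-form oracles
    (rheobase, Ohmic deflection, clamped-conductance ISI).
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    n_steps = int(round(duration / dt))
    v0 = neuron.VL if V0 is None else V0
    v, spk = run_single(
        n_steps,
        dt,
        neuron.C,
        neuron.gL,
        neuron.VL,
        neuron.Vexc,
        neuron.Vinh,
        neuron.Vtheta,
        neuron.Vreset,
        int(round(neuron.t_ref / dt)),
        I_inj,
        g_exc_clamp,
        g_inh_clamp,
        v0,
    )
    return v, spk.astype(np.float64) * dt


def draw_external_increments(
    spec: NetworkSpec,
    input_spec: InputSpec,
    n_steps: int,
    dt: float,
    rng: np.random.Generator,
    mult: Optional[PathwayMultipliers] = None,
) -> np.ndarray:
    """Pre-drawn per-step external excitatory conductance increments.

    Equivalent in distribution to the drive the integrator draws internally;
    used to feed the same input realization to two integration schemes or
    two step sizes (paired comparisons).
    """
    m = mult or PathwayMultipliers()
    dt_s = dt / 1000.0
    lam_th = input_spec.n_lgn * input_spec.R_lgn * dt_s
    lam_bkg = input_spec.n_bkg * input_spec.R_bkg * dt_s
    out = np.zeros((n_steps, spec.N))
    w_th = np.empty(spec.N)
    w_th[: spec.NE] = input_spec.j_s * m.tc_e
    w_th[spec.NE :] = input_spec.g_fw * input_spec.j_s * m.tc_i
    out += rng.poisson(lam_th, size=(n_steps, spec.N)) * w_th
    out += rng.poisson(lam_bkg, size=(n_steps, spec.N)) * (input_spec.j_s * m.bkg)
    return out


def with_disabled_threshold(neuron: NeuronParams) -> NeuronParams:
    """Copy of ``neuron`` whose threshold can never be reached (free membrane)."""
    return replace(neuron, Vtheta=neuron.Vexc - 1e-9)
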