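"""Synthetic slice-electrophysiology data with known ground truth.

Raw recordings behind the measurements this package quantifies are not
publicly available, so every analysis input is generated here with the
statistical structure the downstream quantification assumes:

* mEPSC traces: baseline + i.i.d. Gaussian noise + difference-of-exponential
  quantal events at Poisson times with lognormal amplitudes;
* optogenetic quantal traces: the same, with the event rate elevated by a
  known factor inside a laser window;
* paired EPSC/IPSC sweep families whose charges scale linearly with
  stimulus intensity;
* LTD amplitude series (per-minute evoked EPSCs around an induction);
* minimal-stimulation success/failure trials;
* FI protocols simulated on the single LIF neuron of the network model.

Every generator returns a ``GroundTruth`` sufficient to compute the
downstream metric exactly in the noiseless case.  Identical (spec, seed)
pairs give bit-identical output; the noise realization is drawn from a
sub-stream independent of the event stream, so a trace minus its seeded
kernels and baseline equals the pure-noise realization of the same seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .network import NeuronParams, simulate_single_neuron
from .traces import FIRecording, LTDExperiment, Trace, TrialSet, SweepSet

__all__ = [
    "SynthTraceSpec",
    "EventKinetics",
    "GroundTruth",
    "event_kernel",
    "kernel_peak",
    "kernel_charge_per_amp",
    "gen_mepsc_trace",
    "gen_optogenetic_quantal_trace",
    "gen_paired_ei_sweeps",
    "gen_ltd_series",
    "gen_minimal_stim_trials",
    "gen_fi_protocol",
]


@dataclass(frozen=True)
class SynthTraceSpec:
    """Shape of a synthetic voltage-clamp current sweep."""

    duration: float  # ms
    sample_interval: float = 0.1  # ms (10 kHz acquisition)
    noise_sd: float = 0.0  # pA
    baseline_current: float = 0.0  # pA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.sample_interval <= 0:
            raise ValueError("invalid spec: duration and sample_interval must be > 0")
        if self.noise_sd < 0:
            raise ValueError("invalid spec: noise_sd must be >= 0")


@dataclass(frozen=True)
class EventKinetics:
    """Difference-of-exponentials event shape and amplitude statistics."""

    rise_tau: float = 0.5  # ms
    decay_tau: float = 3.0  # ms
    amp_mean: float = 10.0  # pA (peak amplitude)
    amp_cv: float = 0.2  # dimensionless

    def __post_init__(self) -> None:
        if not self.rise_tau < self.decay_tau:
            raise ValueError("rise_tau must be smaller than decay_tau")
        if self.amp_mean <= 0 or self.amp_cv < 0:
            raise ValueError("amp_mean must be > 0 and amp_cv >= 0")


@dataclass
class GroundTruth:
    """Seeded events and construction parameters for parameter-recovery tests."""

    event_times: np.ndarray
    event_amps: np.ndarray  # positive peak magnitudes, pA
    labels: Optional[list] = None  # e.g. spontaneous/evoked or success/failure
    true_ratio: Optional[float] = None
    true_factor: Optional[float] = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.event_amps = np.asarray(self.event_amps, dtype=float)
        if self.event_times.size != self.event_amps.size:
            raise ValueError("event_times and event_amps must align")
        if np.any(self.event_amps <= 0):
            raise ValueError("all ground-truth amplitudes must be positive")


# -- event kernel -----------------------------------------------------------

def kernel_peak(rise_tau: float, decay_tau: float) -> tuple[float, float]:
    """(peak time, peak value) of the raw kernel (1-e^(-t/r)) e^(-t/d)."""
    r, d = rise_tau, decay_tau
    t_peak = r * math.log((r + d) / r)
    peak = (1.0 - math.exp(-t_peak / r)) * math.exp(-t_peak / d)
    return t_peak, peak


def kernel_charge_per_amp(rise_tau: float, decay_tau: float) -> float:
    """Integral (pA*ms per pA of peak amplitude) of the peak-normalized kernel."""
    r, d = rise_tau, decay_tau
    _, peak = kernel_peak(r, d)
    return (d * d / (r + d)) / peak


def event_kernel(t: np.ndarray, kinetics: EventKinetics) -> np.ndarray:
    """Peak-normalized difference-of-exponentials kernel evaluated at t (ms)."""
    r, d = kinetics.rise_tau, kinetics.decay_tau
    _, peak = kernel_peak(r, d)
    out = np.where(t >= 0, (1.0 - np.exp(-np.maximum(t, 0) / r)) * np.exp(-np.maximum(t, 0) / d), 0.0)
    return out / peak


def _add_events(
    samples: np.ndarray,
    dt: float,
    times: np.ndarray,
    amps: np.ndarray,
    kinetics: EventKinetics,
    sign: float,
) -> None:
    """Superimpose peak-normalized kernels (in place, linear superposition)."""
    if times.size == 0:
        return
    span = int(math.ceil((kinetics.decay_tau * 12 + kinetics.rise_tau * 5) / dt))
    n = samples.size
    rel_t = np.arange(span) * dt
    for t0, a in zip(times, amps):
        i0 = int(math.ceil(t0 / dt))
        if i0 >= n:
            continue
        offset = i0 * dt - t0
        seg = event_kernel(rel_t + offset, kinetics)
        i1 = min(n, i0 + span)
        samples[i0:i1] += sign * a * seg[: i1 - i0]


def _lognormal_amps(rng: np.random.Generator, n: int, mean: float, cv: float) -> np.ndarray:
    """Lognormal amplitudes with the requested mean and coefficient of variation."""
    if cv == 0:
        return np.full(n, mean)
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size=n)


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


# -- generators -------------------------------------------------------------

def gen_mepsc_trace(
    spec: SynthTraceSpec,
    kinetics: EventKinetics,
    event_rate: float,
) -> tuple[Trace, GroundTruth]:
    """Spontaneous quantal-event trace (inward events on a -70 mV hold).

    Event times are homogeneous Poisson at ``event_rate`` (Hz); amplitudes
    are lognormal with mean ``amp_mean`` and CV ``amp_cv``.
    """
    if event_rate < 0:
        raise ValueError("event_rate must be >= 0")
    noise_rng, event_rng = _streams(spec.seed, 2)
    n = int(round(spec.duration / spec.sample_interval))
    samples = np.full(n, spec.baseline_current, dtype=float)
    if spec.noise_sd > 0:
        samples += noise_rng.normal(0.0, spec.noise_sd, size=n)
    n_events = event_rng.poisson(event_rate * spec.duration / 1000.0)
    times = np.sort(event_rng.uniform(0.0, spec.duration, size=n_events))
    amps = _lognormal_amps(event_rng, n_events, kinetics.amp_mean, kinetics.amp_cv)
    _add_events(samples, spec.sample_interval, times, amps, kinetics, sign=-1.0)
    trace = Trace(samples, spec.sample_interval, holding_potential=-70.0)
    return trace, GroundTruth(times, amps, labels=["spontaneous"] * n_events)


def gen_optogenetic_quantal_trace(
    spec: SynthTraceSpec,
    kinetics: EventKinetics,
    base_rate: float,
    evoked_factor: float,
    laser_window: tuple[float, float],
    evoked_kinetics: Optional[EventKinetics] = None,
) -> tuple[Trace, GroundTruth]:
    """Quantal trace whose event rate is elevated inside a laser window.

    The spontaneous process runs at ``base_rate`` over the whole trace; an
    additional evoked process at ``base_rate * (evoked_factor - 1)`` runs
    inside ``laser_window`` only, so the in-window rate is
    ``base_rate * evoked_factor``.  Ground-truth labels record provenance.
    """
    if evoked_factor < 1:
        raise ValueError("evoked_factor must be >= 1")
    w0, w1 = laser_window
    if not (0 <= w0 < w1 <= spec.duration):
        raise ValueError("invalid window: laser_window must lie inside the trace")
    ek = evoked_kinetics or kinetics
    noise_rng, event_rng = _streams(spec.seed, 2)
    n = int(round(spec.duration / spec.sample_interval))
    samples = np.full(n, spec.baseline_current, dtype=float)
    if spec.noise_sd > 0:
        samples += noise_rng.normal(0.0, spec.noise_sd, size=n)

    n_spont = event_rng.poisson(base_rate * spec.duration / 1000.0)
    t_spont = np.sort(event_rng.uniform(0.0, spec.duration, size=n_spont))
    a_spont = _lognormal_amps(event_rng, n_spont, kinetics.amp_mean, kinetics.amp_cv)
    extra_rate = base_rate * (evoked_factor - 1.0)
    n_ev = event_rng.poisson(extra_rate * (w1 - w0) / 1000.0)
    t_ev = np.sort(event_rng.uniform(w0, w1, size=n_ev))
    a_ev = _lognormal_amps(event_rng, n_ev, ek.amp_mean, ek.amp_cv)

    _add_events(samples, spec.sample_interval, t_spont, a_spont, kinetics, sign=-1.0)
    _add_events(samples, spec.sample_interval, t_ev, a_ev, ek, sign=-1.0)

    times = np.concatenate([t_spont, t_ev])
    amps = np.concatenate([a_spont, a_ev])
    labels = ["spontaneous"] * n_spont + ["evoked"] * n_ev
    order = np.argsort(times, kind="stable")
    trace = Trace(
        samples,
        spec.sample_interval,
        holding_potential=-70.0,
        stimulus_markers=[(w0, "laser_on"), (w1, "laser_off")],
    )
    gt = GroundTruth(
        times[order],
        amps[order],
        labels=[labels[i] for i in order],
        true_factor=evoked_factor,
    )
    return trace, gt


def gen_paired_ei_sweeps(
    intensities: list,
    e_gain: float,
    i_gain: float,
    kinetics_e: EventKinetics,
    kinetics_i: EventKinetics,
    noise_sd: float,
    seed: int,
    sample_interval: float = 0.1,
    sweep_duration: float = 300.0,
    stim_time: float = 50.0,
) -> tuple[SweepSet, GroundTruth]:
    """Paired EPSC (-70 mV) / IPSC (0 mV) sweeps scaling linearly with intensity.

    True charges are ``e_gain * level`` and ``i_gain * level`` (pC); event
    peak amplitudes are set so the analytic kernel integral delivers exactly
    those charges.  The ground-truth ratio is ``e_gain / i_gain``.
    """
    levels = np.asarray(list(intensities), dtype=float)
    if levels.size == 0 or np.any(np.diff(levels) <= 0):
        raise ValueError("intensities must be non-empty and strictly increasing")
    if e_gain < 0 or i_gain < 0:
        raise ValueError("invalid spec: gains must be >= 0")
    rngs = _streams(seed, 2 * levels.size)
    q_e = kernel_charge_per_amp(kinetics_e.rise_tau, kinetics_e.decay_tau)  # pA*ms/pA
    q_i = kernel_charge_per_amp(kinetics_i.rise_tau, kinetics_i.decay_tau)
    n = int(round(sweep_duration / sample_interval))
    pairs = []
    e_charges, i_charges = [], []
    for k, level in enumerate(levels):
        qe_pc, qi_pc = e_gain * level, i_gain * level
        amp_e = qe_pc * 1000.0 / q_e  # pC -> pA*ms, then per-unit-amp integral
        amp_i = qi_pc * 1000.0 / q_i
        se = np.zeros(n)
        si = np.zeros(n)
        if noise_sd > 0:
            se += rngs[2 * k].normal(0.0, noise_sd, size=n)
            si += rngs[2 * k + 1].normal(0.0, noise_sd, size=n)
        _add_events(se, sample_interval, np.array([stim_time]), np.array([max(amp_e, 1e-12)]), kinetics_e, sign=-1.0)
        _add_events(si, sample_interval, np.array([stim_time]), np.array([max(amp_i, 1e-12)]), kinetics_i, sign=+1.0)
        marker = [(stim_time, "stim")]
        pairs.append(
            (
                level,
                Trace(se, sample_interval, holding_potential=-70.0, stimulus_markers=list(marker)),
                Trace(si, sample_interval, holding_potential=0.0, stimulus_markers=list(marker)),
            )
        )
        e_charges.append(qe_pc)
        i_charges.append(qi_pc)
    ratio = float(np.divide(e_gain, i_gain)) if i_gain > 0 else math.inf
    gt = GroundTruth(
        event_times=np.full(levels.size, stim_time),
        event_amps=np.maximum(levels, 1e-12),
        true_ratio=ratio,
        extras={
            "true_e_charges_pC": np.array(e_charges),
            "true_i_charges_pC": np.array(i_charges),
            "fit_defined": levels.size >= 2,
        },
    )
    return SweepSet(pairs), gt


def gen_ltd_series(
    n_pre: int,
    n_post: int,
    baseline_amp: float,
    post_factor: float,
    noise_cv: float,
    seed: int,
    induction_minutes: int = 10,
) -> tuple[LTDExperiment, GroundTruth]:
    """Per-minute evoked EPSC amplitudes around an LTD induction.

    Pre-induction minutes fluctuate around ``baseline_amp``; post-induction
    minutes around ``baseline_amp * post_factor``.  Multiplicative lognormal
    noise of the given CV is mean-one, so the recovered post/pre factor is
    unbiased.
    """
    if n_pre < 1:
        raise ValueError("need at least one baseline minute")
    if n_post < 31:
        raise ValueError(
            "window-infeasible: need >= 31 post minutes to cover the 5-30 min window"
        )
    if baseline_amp <= 0:
        raise ValueError("baseline_amp must be positive")
    if not 100.0 <= baseline_amp <= 700.0:
        import warnings

        warnings.warn(
            "baseline_amp outside the 100-700 pA range accepted for evoked EPSCs",
            stacklevel=2,
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    pre_minutes = np.arange(n_pre)
    induction_end = int(n_pre - 1 + induction_minutes)
    post_minutes = induction_end + 1 + np.arange(n_post)
    minutes = np.concatenate([pre_minutes, post_minutes])
    means = np.concatenate(
        [np.full(n_pre, baseline_amp), np.full(n_post, baseline_amp * post_factor)]
    )
    if noise_cv > 0:
        sigma2 = math.log(1.0 + noise_cv * noise_cv)
        noise = rng.lognormal(-sigma2 / 2.0, math.sqrt(sigma2), size=minutes.size)
    else:
        noise = np.ones(minutes.size)
    amps = means * noise
    exp = LTDExperiment(minutes=minutes, amplitudes=amps, induction_end=induction_end)
    gt = GroundTruth(
        event_times=minutes,
        event_amps=amps,
        true_factor=post_factor,
        extras={"baseline_amp_pA": baseline_amp},
    )
    return exp, gt


def gen_minimal_stim_trials(
    n_trials: int,
    p_success: float,
    unitary_amp: float,
    noise_sd: float,
    kinetics: EventKinetics,
    seed: int,
    sample_interval: float = 0.1,
    trial_duration: float = 60.0,
    stim_time: float = 10.0,
) -> tuple[TrialSet, GroundTruth]:
    """Minimal-stimulation trials: stereotyped IPSC successes vs noise-only failures.

    Each trial is an independent Bernoulli(``p_success``); successes contain
    an outward IPSC of peak ``unitary_amp`` at a fixed latency after the
    stimulus, recorded at 0 mV.
    """
    if n_trials <= 0:
        raise ValueError("empty-trial error: n_trials must be >= 1")
    if not 0.0 <= p_success <= 1.0:
        raise ValueError("p_success must lie in [0, 1]")
    rngs = _streams(seed, n_trials + 1)
    outcome = rngs[0].random(n_trials) < p_success
    n = int(round(trial_duration / sample_interval))
    onset = stim_time + 3.0  # fixed synaptic latency, ms
    trials = []
    for k in range(n_trials):
        s = np.zeros(n)
        if noise_sd > 0:
            s += rngs[k + 1].normal(0.0, noise_sd, size=n)
        if outcome[k]:
            _add_events(
                s, sample_interval, np.array([onset]), np.array([unitary_amp]), kinetics, sign=+1.0
            )
        trials.append(
            Trace(s, sample_interval, holding_potential=0.0, stimulus_markers=[(stim_time, "laser")])
        )
    succ = np.flatnonzero(outcome)
    gt = GroundTruth(
        event_times=np.full(succ.size, onset),
        event_amps=np.full(succ.size, unitary_amp),
        labels=["success" if o else "failure" for o in outcome],
        true_ratio=p_success,
        extras={"unitary_amp_pA": unitary_amp},
    )
    return TrialSet(trials=trials, stim_time=stim_time), gt


def gen_fi_protocol(
    neuron: NeuronParams,
    current_steps: list,
    step_duration: float,
    seed: int = 0,
    dt: float = 0.01,
) -> FIRecording:
    """Simulate the model LIF neuron under a family of square current steps.

    The protocol mirrors slice intrinsic-excitability measurements: 1 s
    steps of increasing amplitude from rest, no synaptic input.  ``seed`` is
    accepted for interface uniformity; the single-neuron dynamics are
    deterministic.
    """
    steps = np.asarray(list(current_steps), dtype=float)
    if steps.size == 0 or np.any(np.diff(steps) <= 0):
        raise ValueError("invalid protocol: current steps must be strictly increasing")
    if step_duration <= 0:
        raise ValueError("invalid protocol: step_duration must be positive")
    voltages, spikes = [], []
    for i_inj in steps:
        v, spk = simulate_single_neuron(
            neuron, duration=step_duration, dt=dt, I_inj=float(i_inj)
        )
        voltages.append(v)
        spikes.append(spk)
    return FIRecording(
        currents=steps, step_duration=step_duration, dt=dt, voltages=voltages, spike_times=spikes
    )
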