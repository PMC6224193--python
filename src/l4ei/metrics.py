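"""Quantification of synaptic and intrinsic measurements from traces.

This module turns raw current traces into the derived quantities the rest
of the pipeline consumes: detected quantal events with inclusion criteria
(amplitude > 5 pA, rise time < 3 ms), per-event decay constants, synaptic
charges and E-I charge ratios with amplitude minima, LTD outcomes, FI
curves with rheobase and input resistance, minimal-stimulation unitary
IPSC estimates, and two-group statistical comparisons.

Event tables are plain :class:`pandas.DataFrame` objects with columns
``onset_ms, peak_time_ms, amplitude_pA, rise_ms, decay_ms, baseline_pA,
included, epoch`` — one row per detected event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats

from .traces import FIRecording, LTDExperiment, Trace, TrialSet, SweepSet

__all__ = [
    "EVENT_COLUMNS",
    "EIRatioResult",
    "RheobaseUndefinedError",
    "detect_events",
    "fit_event_kinetics",
    "quantal_amplitude_stats",
    "charge",
    "ei_charge_ratio",
    "pyr_pv_charge_ratio",
    "ltd_outcome",
    "fi_analysis",
    "unitary_ipsc",
    "compare_groups",
]

EVENT_COLUMNS = [
    "onset_ms",
    "peak_time_ms",
    "amplitude_pA",
    "rise_ms",
    "decay_ms",
    "baseline_pA",
    "included",
    "epoch",
]

#: default inclusion criteria for quantal events
MIN_AMP_PA = 5.0
MAX_RISE_MS = 3.0


class RheobaseUndefinedError(ValueError):
    """No current step produced a spike; carries the FI curve that was computed."""

    def __init__(self, msg: str, fi_curve: list):
        super().__init__(msg)
        self.fi_curve = fi_curve


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=float) for c in EVENT_COLUMNS}).astype(
        {"included": bool, "epoch": object}
    )


def _noise_sd_estimate(x: np.ndarray) -> float:
    """Robust per-sample noise SD from the MAD of the first difference.

    First-differencing suppresses the slow synaptic components so sparse
    events barely inflate the estimate; for white noise the difference has
    sqrt(2) times the sample SD.
    """
    d = np.diff(x)
    if d.size == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / math.sqrt(2.0)


def detect_events(
    trace: Trace,
    min_amp: float = MIN_AMP_PA,
    max_rise: float = MAX_RISE_MS,
    detection_floor: float = 2.0,
    smooth_ms: float = 0.3,
    merge_ms: float = 1.0,
    baseline_ms: float = 2.0,
) -> pd.DataFrame:
    """Detect quantal events and apply the amplitude/rise inclusion criteria.

    Detection runs on a Gaussian-smoothed copy of the rectified trace:
    peaks exceeding ``max(3 x noise SD, detection_floor)`` in height and
    prominence are events; peaks closer than ``merge_ms`` merge into one
    (automated stand-in for manual overlap resolution).  Amplitude and
    20-80% rise time are then measured on the raw trace against a local
    pre-onset baseline.  ``included`` applies ``amplitude > min_amp`` and
    ``rise < max_rise``; detection itself uses the lower floor so
    sub-criterion events are still reported with ``included=False``.
    Deterministic for a fixed trace.
    """
    if trace.n_samples == 0:
        raise ValueError("invalid input: empty trace")
    dt = trace.sample_interval
    x = trace.polarity * (trace.samples - np.median(trace.samples))
    sd = _noise_sd_estimate(x)
    threshold = max(3.0 * sd, detection_floor)
    smoothed = ndimage.gaussian_filter1d(x, sigma=max(smooth_ms / dt, 1e-6))
    distance = max(1, int(round(merge_ms / dt)))
    peaks, _props = signal.find_peaks(
        smoothed, height=threshold, prominence=threshold / 2.0, distance=distance
    )

    rows = []
    half_search = max(1, int(round(0.5 / dt)))
    nb = max(1, int(round(baseline_ms / dt)))
    for p in peaks:
        # raw peak near the smoothed peak
        lo = max(0, p - half_search)
        hi = min(x.size, p + half_search + 1)
        praw = lo + int(np.argmax(x[lo:hi]))
        # onset: walk back to where the smoothed trace falls under 10% of peak
        level = 0.1 * smoothed[p]
        i = p
        while i > 0 and smoothed[i - 1] > level:
            i -= 1
        onset = i
        b0 = max(0, onset - nb)
        baseline = float(np.mean(x[b0:onset])) if onset > b0 else 0.0
        amp = float(x[praw] - baseline)
        if amp <= 0:
            continue
        rise = _rise_time_20_80(x, onset, praw, baseline, amp, dt)
        rows.append(
            {
                "onset_ms": onset * dt,
                "peak_time_ms": praw * dt,
                "amplitude_pA": amp,
                "rise_ms": rise,
                "decay_ms": np.nan,
                "baseline_pA": baseline,
                "included": bool(amp > min_amp and rise < max_rise),
                "epoch": "spontaneous",
            }
        )
    if not rows:
        return _empty_events()
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def _rise_time_20_80(
    x: np.ndarray, onset: int, peak: int, baseline: float, amp: float, dt: float
) -> float:
    """20-80% rise time with two-sample linear interpolation of the crossings."""
    seg = x[onset : peak + 1] - baseline
    if seg.size < 2:
        return 0.0

    def crossing(frac: float) -> float:
        target = frac * amp
        idx = np.flatnonzero(seg >= target)
        if idx.size == 0:
            return float(seg.size - 1)
        i = idx[0]
        if i == 0:
            return 0.0
        y0, y1 = seg[i - 1], seg[i]
        return (i - 1) + (target - y0) / (y1 - y0)

    return (crossing(0.8) - crossing(0.2)) * dt


def fit_event_kinetics(
    trace: Trace, events: pd.DataFrame, fit_window_ms: float = 10.0
) -> pd.DataFrame:
    """Fill per-event decay constants by single-exponential fits after the peak.

    Log-linear least squares on the baseline-subtracted trace from the peak
    to ``peak + fit_window_ms``.  Events whose post-peak segment is shorter
    than 5 ms, has no positive samples, or does not decay are flagged with
    ``decay_ms = NaN``.
    """
    out = events.copy()
    if out.empty:
        return out
    dt = trace.sample_interval
    x = trace.polarity * (trace.samples - np.median(trace.samples))
    taus = np.full(len(out), np.nan)
    for k, (_, ev) in enumerate(out.iterrows()):
        p = int(round(ev["peak_time_ms"] / dt))
        end = min(x.size, p + int(round(fit_window_ms / dt)) + 1)
        if (end - p) * dt < 5.0:
            continue  # truncated at trace end: flagged
        y = x[p:end] - ev["baseline_pA"]
        pos = y > 0
        if np.count_nonzero(pos) < 5:
            continue
        t = np.arange(y.size)[pos] * dt
        ly = np.log(y[pos])
        slope, _intercept = np.polyfit(t, ly, 1)
        if slope >= 0:
            continue  # non-decaying segment: flagged
        taus[k] = -1.0 / slope
    out["decay_ms"] = taus
    return out


def quantal_amplitude_stats(
    events: pd.DataFrame, laser_window: tuple[float, float]
) -> dict:
    """Partition included events around a laser window; frequency elevation.

    ``freq_elevation`` is the in-window event rate as a percent of the
    pre-window (baseline) rate.  Amplitude means are reported separately
    for the spontaneous (pre-window) and evoked (in-window) epochs.
    """
    w0, w1 = laser_window
    if not w0 < w1:
        raise ValueError("invalid window: laser window must have positive length")
    inc = events[events["included"]]
    t = inc["onset_ms"].to_numpy()
    pre = inc[t < w0]
    during = inc[(t >= w0) & (t <= w1)]
    if len(pre) == 0:
        raise ValueError("baseline-undefined: no included events before the laser window")
    if len(during) == 0:
        raise ValueError("no included events inside the laser window")
    pre_rate = len(pre) / (w0 / 1000.0)
    in_rate = len(during) / ((w1 - w0) / 1000.0)
    return {
        "spont_mean_amp": float(pre["amplitude_pA"].mean()),
        "evoked_mean_amp": float(during["amplitude_pA"].mean()),
        "spont_rate_hz": pre_rate,
        "evoked_rate_hz": in_rate,
        "freq_elevation": 100.0 * in_rate / pre_rate,
    }


def charge(
    trace: Trace, window: tuple[float, float], baseline_window: tuple[float, float]
) -> float:
    """|trapezoidal integral of (current - baseline)| over ``window``, in pC."""
    dur = trace.duration
    for w in (window, baseline_window):
        if not (0 <= w[0] < w[1] <= dur + trace.sample_interval / 2):
            raise ValueError(f"invalid window: {w} outside trace of {dur} ms")
    if not (window[1] <= baseline_window[0] or baseline_window[1] <= window[0]):
        raise ValueError("invalid window: analysis and baseline windows overlap")
    t = trace.times
    bmask = (t >= baseline_window[0]) & (t <= baseline_window[1])
    wmask = (t >= window[0]) & (t <= window[1])
    baseline = float(np.mean(trace.samples[bmask]))
    integral = np.trapezoid(trace.samples[wmask] - baseline, t[wmask])  # pA*ms
    return abs(float(integral)) / 1000.0


@dataclass
class EIRatioResult:
    """Mean E-I charge ratio with per-intensity detail and linear-fit diagnostics."""

    mean_ratio: float
    per_intensity_ratios: list
    fit_slope: float
    fit_r2: float
    n_pairs_used: int
    fit_defined: bool


def _stim_windows(
    trace: Trace, response_ms: float, baseline_ms: float
) -> tuple[tuple[float, float], tuple[float, float]]:
    if not trace.stimulus_markers:
        raise ValueError("trace has no stimulus marker")
    t0 = trace.stimulus_markers[0][0]
    return (t0, min(t0 + response_ms, trace.duration)), (max(0.0, t0 - baseline_ms), t0)


def _peak_amplitude(trace: Trace, window: tuple[float, float], baseline_window) -> float:
    t = trace.times
    bmask = (t >= baseline_window[0]) & (t <= baseline_window[1])
    wmask = (t >= window[0]) & (t <= window[1])
    baseline = float(np.mean(trace.samples[bmask]))
    dev = trace.polarity * (trace.samples[wmask] - baseline)
    return float(np.max(dev))


def ei_charge_ratio(
    sweeps: SweepSet,
    min_epsc: float = 150.0,
    min_ipsc: float = 600.0,
    response_ms: float = 100.0,
    baseline_ms: float = 10.0,
) -> EIRatioResult:
    """E-I charge ratio across a sweep family with amplitude minima.

    Pairs whose EPSC or IPSC peak falls below the pathway-appropriate
    minimum (thalamocortical 150/600 pA, intracortical 50/600 pA) are
    excluded.  The mean ratio averages per-pair EPSC/IPSC charge ratios;
    the fit regresses EPSC charge on IPSC charge over surviving pairs.
    """
    ratios, e_charges, i_charges = [], [], []
    n_small_e = n_small_i = 0
    for _level, epsc, ipsc in sweeps.pairs:
        we, be = _stim_windows(epsc, response_ms, baseline_ms)
        wi, bi = _stim_windows(ipsc, response_ms, baseline_ms)
        pe = _peak_amplitude(epsc, we, be)
        pi_amp = _peak_amplitude(ipsc, wi, bi)
        if pe < min_epsc:
            n_small_e += 1
            continue
        if pi_amp < min_ipsc:
            n_small_i += 1
            continue
        qe = charge(epsc, we, be)
        qi = charge(ipsc, wi, bi)
        ratios.append(qe / qi)
        e_charges.append(qe)
        i_charges.append(qi)
    if not ratios:
        raise ValueError(
            "all-excluded: no sweep pair met the amplitude minima "
            f"(EPSC >= {min_epsc} pA violated {n_small_e}x, "
            f"IPSC >= {min_ipsc} pA violated {n_small_i}x)"
        )
    fit_defined = len(ratios) >= 2
    if fit_defined:
        res = stats.linregress(i_charges, e_charges)
        slope, r2 = float(res.slope), float(res.rvalue**2)
    else:
        slope, r2 = math.nan, math.nan
    return EIRatioResult(
        mean_ratio=float(np.mean(ratios)),
        per_intensity_ratios=ratios,
        fit_slope=slope,
        fit_r2=r2,
        n_pairs_used=len(ratios),
        fit_defined=fit_defined,
    )


def pyr_pv_charge_ratio(
    pairs: list,
    response_ms: float = 100.0,
    baseline_ms: float = 10.0,
) -> dict:
    """Pyramidal/PV thalamocortical EPSC charge ratio across intensities.

    ``pairs`` is a list of (pyramidal EPSC trace, PV EPSC trace) recorded
    with shared stimuli; the ratio is pyramidal charge / PV charge per
    intensity, averaged, with linear-fit diagnostics (PV on x, PYR on y).
    """
    if not pairs:
        raise ValueError("need at least one intensity pair")
    ratios, q_pyr, q_pv = [], [], []
    for pyr, pv in pairs:
        wp, bp = _stim_windows(pyr, response_ms, baseline_ms)
        wv, bv = _stim_windows(pv, response_ms, baseline_ms)
        qp = charge(pyr, wp, bp)
        qv = charge(pv, wv, bv)
        if qv == 0:
            raise ValueError("division-undefined: PV charge is zero")
        ratios.append(qp / qv)
        q_pyr.append(qp)
        q_pv.append(qv)
    if len(pairs) >= 2:
        res = stats.linregress(q_pv, q_pyr)
        r2 = float(res.rvalue**2)
    else:
        r2 = math.nan
    return {"mean_ratio": float(np.mean(ratios)), "fit_r2": r2, "n_pairs": len(pairs)}


def ltd_outcome(exp: LTDExperiment) -> dict:
    """Post/pre EPSC amplitude ratio for an LTD experiment.

    The post average runs over minutes 5-30 after the end of induction; the
    pre average over all pre-induction minutes.  Invariant to amplitude
    units.
    """
    m = exp.minutes
    pre = exp.amplitudes[m < exp.induction_end - 1e-9]
    lo, hi = exp.induction_end + 5, exp.induction_end + 30
    post = exp.amplitudes[(m >= lo) & (m <= hi)]
    if pre.size == 0:
        raise ValueError("no pre-induction minutes")
    if m.max() < hi or post.size == 0:
        raise ValueError(
            "window-infeasible: series must cover 30 min past the end of induction"
        )
    return {
        "post_pre_ratio": float(np.mean(post) / np.mean(pre)),
        "n_pre": int(pre.size),
        "n_post": int(post.size),
    }


def fi_analysis(rec: FIRecording) -> dict:
    """FI curve, rheobase and input resistance from a current-step protocol.

    Firing rate is spike count / step duration per step; rheobase is the
    smallest current with at least one spike; input resistance is the
    steady-state voltage deflection (mean over the last 20% of the step) on
    the most hyperpolarizing (else largest subthreshold) step divided by
    its current.
    """
    if rec.currents.size < 2:
        raise ValueError("need at least two current steps")
    dur_s = rec.step_duration / 1000.0
    counts = np.array([len(s) for s in rec.spike_times])
    fi_curve = [(float(i), float(c / dur_s)) for i, c in zip(rec.currents, counts)]

    sub = np.flatnonzero((counts == 0) & (rec.currents != 0))
    if sub.size == 0:
        raise ValueError(
            "input resistance undefined: no hyperpolarizing or subthreshold step"
        )
    neg = sub[rec.currents[sub] < 0]
    k = neg[np.argmin(rec.currents[neg])] if neg.size else sub[np.argmax(rec.currents[sub])]
    v = rec.voltages[k]
    tail = v[int(0.8 * (v.size - 1)) :]
    dv = float(np.mean(tail) - v[0])
    r_mohm = dv / float(rec.currents[k]) * 1000.0  # mV/pA -> MOhm

    spiking = np.flatnonzero(counts > 0)
    if spiking.size == 0:
        raise RheobaseUndefinedError(
            "rheobase-undefined: no step elicited a spike", fi_curve
        )
    return {
        "fi_curve": fi_curve,
        "rheobase": float(rec.currents[spiking[0]]),
        "input_resistance": r_mohm,
    }


def unitary_ipsc(
    trials: TrialSet,
    noise_sd_window: tuple[float, float],
    response_window: tuple[float, float] = (2.0, 20.0),
    threshold_sd: float = 3.0,
    threshold_floor: float = 1.0,
) -> dict:
    """Success rate and mean amplitude of putative unitary IPSCs.

    A trial is a success when its peak deviation in the post-stimulus
    response window (``response_window`` ms after the stimulus) exceeds
    ``threshold_sd`` times the baseline-noise SD measured in
    ``noise_sd_window`` (floored at ``threshold_floor`` pA for noiseless
    traces).  Classification runs on a 1 ms boxcar-smoothed copy so that
    isolated noise samples cannot cross the threshold; the reported
    amplitude is the raw peak near the smoothed maximum.
    """
    if len(trials) < 10:
        raise ValueError("need at least 10 trials")
    amps, successes = [], []
    for tr in trials.trials:
        t = tr.times
        dt = tr.sample_interval
        nmask = (t >= noise_sd_window[0]) & (t <= noise_sd_window[1])
        if not np.any(nmask):
            raise ValueError("invalid window: noise window contains no samples")
        baseline = float(np.mean(tr.samples[nmask]))
        sd = float(np.std(tr.samples[nmask]))
        w0 = trials.stim_time + response_window[0]
        w1 = trials.stim_time + response_window[1]
        wmask = (t >= w0) & (t <= w1)
        dev = tr.polarity * (tr.samples - baseline)
        width = max(1, int(round(1.0 / dt)))
        smooth = ndimage.uniform_filter1d(dev, size=width)
        widx = np.flatnonzero(wmask)
        p = widx[int(np.argmax(smooth[widx]))]
        ok = smooth[p] > max(threshold_sd * sd, threshold_floor)
        lo = max(widx[0], p - width)
        hi = min(widx[-1] + 1, p + width + 1)
        successes.append(bool(ok))
        amps.append(float(np.max(dev[lo:hi])))
    successes = np.asarray(successes)
    if not successes.any():
        raise ValueError("estimate-undefined: zero successes")
    amps = np.asarray(amps)
    return {
        "success_rate": float(np.mean(successes)),
        "mean_success_amp": float(np.mean(amps[successes])),
        "n_trials": int(successes.size),
    }


def compare_groups(x, y, method: str = "t_test") -> dict:
    """Two-sided two-group comparison: Student t, Wilcoxon rank sum, or KS.

    Mirrors the study's convention: a 2-sample t-test for normally
    distributed data, Wilcoxon rank sum otherwise, and a two-sample
    Kolmogorov-Smirnov test for whole-distribution comparisons.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must be finite")
    if method == "t_test":
        if np.var(x) == 0 and np.var(y) == 0:
            raise ValueError("degenerate-sample: zero pooled variance")
        res = stats.ttest_ind(x, y)
    elif method == "rank_sum":
        res = stats.ranksums(x, y)
    elif method == "ks":
        res = stats.ks_2samp(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue)}
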