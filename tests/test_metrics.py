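"""Trace quantification: event detection, charges, E-I ratios, LTD, FI,
unitary IPSCs and group comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from l4ei.metrics import (
    RheobaseUndefinedError,
    charge,
    compare_groups,
    detect_events,
    ei_charge_ratio,
    fi_analysis,
    fit_event_kinetics,
    ltd_outcome,
    pyr_pv_charge_ratio,
    quantal_amplitude_stats,
    unitary_ipsc,
)
from l4ei.synth import (
    EventKinetics,
    SynthTraceSpec,
    _add_events,
    gen_fi_protocol,
    gen_ltd_series,
    gen_mepsc_trace,
    gen_minimal_stim_trials,
    gen_optogenetic_quantal_trace,
    gen_paired_ei_sweeps,
)
from l4ei.traces import LTDExperiment, Trace

KIN = EventKinetics(rise_tau=0.5, decay_tau=3.0, amp_mean=20.0, amp_cv=0.2)
KIN_E = EventKinetics(rise_tau=0.8, decay_tau=6.0, amp_mean=100.0, amp_cv=0.0)
KIN_I = EventKinetics(rise_tau=1.0, decay_tau=12.0, amp_mean=100.0, amp_cv=0.0)


def make_event_trace(times, amps, kinetics=KIN, duration=2000.0, dt=0.1, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt))
    s = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    _add_events(s, dt, np.asarray(times, float), np.asarray(amps, float), kinetics, sign=-1.0)
    return Trace(s, dt, holding_potential=-70.0)


class TestDetectEvents:
    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_events(Trace(np.array([]), 0.1))

    def test_flat_trace_no_events(self):
        ev = detect_events(Trace(np.zeros(10_000), 0.1))
        assert len(ev) == 0

    def test_noiseless_recall_one_no_false_positives(self):
        spec = SynthTraceSpec(duration=20_000.0, noise_sd=0.0, seed=11)
        trace, gt = gen_mepsc_trace(spec, KIN, 1.0)
        ev = detect_events(trace)
        assert len(ev) == gt.event_times.size
        det = np.sort(ev["onset_ms"].to_numpy())
        assert np.all(np.abs(det - np.sort(gt.event_times)) < 2.0)

    def test_noisy_amplitude_accuracy(self):
        """20 seeded 20 pA events in 1 pA noise: all detected and included,
        amplitudes within 3 pA of truth."""
        times = 50.0 + 100.0 * np.arange(20)
        trace = make_event_trace(
            times, np.full(20, 20.0), duration=2100.0, noise_sd=1.0, seed=5
        )
        ev = detect_events(trace)
        inc = ev[ev["included"]]
        assert len(inc) == 20
        for t0 in times:
            row = inc.iloc[(inc["onset_ms"] - t0).abs().argmin()]
            assert abs(row["amplitude_pA"] - 20.0) < 3.0

    def test_noisy_recall_above_095(self):
        spec = SynthTraceSpec(duration=20_000.0, noise_sd=2.0, seed=21)
        trace, gt = gen_mepsc_trace(spec, KIN, 2.0)
        ev = detect_events(trace)
        det = ev["onset_ms"].to_numpy()
        hits = sum(np.any(np.abs(det - t) < 2.5) for t in gt.event_times)
        assert hits / gt.event_times.size >= 0.95

    def test_inclusion_criteria_flag_but_keep(self):
        """A 4 pA event and a slow-rise 20 pA event are detected but not
        included (criteria: amplitude > 5 pA, rise < 3 ms)."""
        small = make_event_trace([100.0], [4.0])
        ev = detect_events(small)
        assert len(ev) == 1 and not bool(ev["included"].iloc[0])

        slow = EventKinetics(rise_tau=5.0, decay_tau=20.0, amp_mean=20.0, amp_cv=0.0)
        ev = detect_events(make_event_trace([100.0], [20.0], kinetics=slow))
        assert len(ev) == 1
        assert ev["rise_ms"].iloc[0] > 3.0
        assert not bool(ev["included"].iloc[0])

    def test_good_event_included(self):
        ev = detect_events(make_event_trace([100.0], [20.0]))
        assert len(ev) == 1 and bool(ev["included"].iloc[0])


class TestEventKinetics:
    def test_pure_exponential_decay_recovered_exactly(self):
        dt = 0.1
        n = 3000
        t = np.arange(n) * dt
        s = np.zeros(n)
        onset = 1000
        s[onset:] = -20.0 * np.exp(-(t[onset:] - t[onset]) / 0.910)
        trace = Trace(s, dt)
        ev = fit_event_kinetics(trace, detect_events(trace))
        assert len(ev) == 1
        assert ev["decay_ms"].iloc[0] == pytest.approx(0.910, abs=1e-3)

    def test_tau_scaling(self):
        taus = []
        for tau in (2.0, 4.0):
            kin = EventKinetics(rise_tau=0.1, decay_tau=tau, amp_mean=50.0, amp_cv=0.0)
            trace = make_event_trace([100.0], [50.0], kinetics=kin)
            ev = fit_event_kinetics(trace, detect_events(trace))
            taus.append(ev["decay_ms"].iloc[0])
        assert taus[1] / taus[0] == pytest.approx(2.0, rel=0.05)

    def test_truncated_event_flagged(self):
        trace = make_event_trace([1998.0], [50.0], duration=2000.0)
        ev = fit_event_kinetics(trace, detect_events(trace))
        assert len(ev) == 1
        assert np.isnan(ev["decay_ms"].iloc[0])


class TestCharge:
    def test_zero_trace(self):
        tr = Trace(np.zeros(5000), 0.1)
        assert charge(tr, (100.0, 200.0), (0.0, 50.0)) == 0.0

    def test_rectangle_analytic(self):
        s = np.zeros(3000)
        s[1000:1101] = 100.0  # 100 pA for exactly 10 ms of trapezoid support
        tr = Trace(s, 0.1)
        assert charge(tr, (100.0, 110.0), (0.0, 50.0)) == pytest.approx(1.0, rel=1e-12)

    def test_exponential_closed_form(self):
        dt = 0.1
        t = np.arange(10_000) * dt
        s = np.where(t >= 100.0, 100.0 * np.exp(-(t - 100.0) / 5.0), 0.0)
        tr = Trace(s, dt)
        q = charge(tr, (100.0, 900.0), (0.0, 50.0))
        assert q == pytest.approx(0.5, rel=1e-3)

    @given(
        scale=st.floats(min_value=0.1, max_value=50, allow_nan=False),
        offset=st.floats(min_value=-100, max_value=100, allow_nan=False),
    )
    @settings(max_examples=25, deadline=None)
    def test_linearity_and_offset_invariance(self, scale, offset):
        base = make_event_trace([100.0], [40.0], duration=400.0)
        w, b = (100.0, 200.0), (50.0, 90.0)
        q0 = charge(base, w, b)
        scaled = Trace(base.samples * scale, base.sample_interval)
        assert charge(scaled, w, b) == pytest.approx(scale * q0, rel=1e-9)
        shifted = Trace(base.samples + offset, base.sample_interval)
        assert charge(shifted, w, b) == pytest.approx(q0, rel=1e-6, abs=1e-9)

    def test_bad_windows_rejected(self):
        tr = Trace(np.zeros(1000), 0.1)
        with pytest.raises(ValueError):
            charge(tr, (50.0, 500.0), (0.0, 40.0))  # window beyond trace
        with pytest.raises(ValueError):
            charge(tr, (10.0, 50.0), (40.0, 80.0))  # overlap


class TestEIChargeRatio:
    def test_construction_ratio_recovered(self):
        sweeps, _ = gen_paired_ei_sweeps(
            [1, 2, 3, 4, 5], 0.106 * 3, 3.0, KIN_E, KIN_I, 0.0, seed=1
        )
        res = ei_charge_ratio(sweeps, min_epsc=1.0, min_ipsc=1.0)
        # finite 100 ms window truncates the slow IPSC tail by O(e^(-w/tau))
        assert res.mean_ratio == pytest.approx(0.106, rel=1e-3)
        assert res.fit_r2 == pytest.approx(1.0, abs=1e-9)

    def test_equal_charges_unit_ratio(self):
        sweeps, _ = gen_paired_ei_sweeps([1, 2, 3], 1.0, 1.0, KIN_E, KIN_I, 0.0, seed=2)
        res = ei_charge_ratio(sweeps, min_epsc=1.0, min_ipsc=1.0)
        assert res.mean_ratio == pytest.approx(1.0, rel=1e-3)
        assert res.fit_r2 == pytest.approx(1.0, abs=1e-9)

    def test_amplitude_minima_exclude_small_pairs(self):
        """A pair whose EPSC peaks near 100 pA fails the 150 pA
        thalamocortical minimum and is excluded from the ratio."""
        sweeps, _ = gen_paired_ei_sweeps(
            [1, 2, 3], 0.8, 4.0, KIN_E, KIN_I, 0.0, seed=3
        )
        # peak EPSC amplitudes ~100/200/300 pA: level 1 fails the 150 pA minimum
        res_all = ei_charge_ratio(sweeps, min_epsc=1.0, min_ipsc=1.0)
        res_min = ei_charge_ratio(sweeps, min_epsc=150.0, min_ipsc=1.0)
        assert res_min.n_pairs_used < res_all.n_pairs_used

    def test_all_excluded_names_minimum(self):
        sweeps, _ = gen_paired_ei_sweeps([1, 2], 0.001, 0.01, KIN_E, KIN_I, 0.0, seed=4)
        with pytest.raises(ValueError, match="150"):
            ei_charge_ratio(sweeps, min_epsc=150.0, min_ipsc=600.0)

    def test_single_pair_fit_flagged(self):
        sweeps, _ = gen_paired_ei_sweeps([5.0], 0.2, 1.0, KIN_E, KIN_I, 0.0, seed=5)
        res = ei_charge_ratio(sweeps, min_epsc=1.0, min_ipsc=1.0)
        assert not res.fit_defined
        assert np.isnan(res.fit_r2)


class TestPyrPvRatio:
    def test_constructed_ratios(self):
        for target in (0.260, 0.369):
            pairs = []
            for level in (1.0, 2.0, 3.0):
                sw, _ = gen_paired_ei_sweeps(
                    [level], target, 1.0, KIN_E, KIN_E, 0.0, seed=int(level)
                )
                _lv, epsc, ipsc = sw.pairs[0]
                pv = Trace(
                    -np.abs(ipsc.samples),
                    ipsc.sample_interval,
                    holding_potential=-70.0,
                    stimulus_markers=list(ipsc.stimulus_markers),
                )
                pairs.append((epsc, pv))
            res = pyr_pv_charge_ratio(pairs)
            assert res["mean_ratio"] == pytest.approx(target, rel=1e-4)

    def test_identical_traces_unit_ratio(self):
        tr = make_event_trace([100.0], [200.0], duration=400.0)
        tr.stimulus_markers = [(100.0, "stim")]
        res = pyr_pv_charge_ratio([(tr, tr)])
        assert res["mean_ratio"] == pytest.approx(1.0)

    def test_zero_pv_charge_rejected(self):
        tr = make_event_trace([100.0], [200.0], duration=400.0)
        tr.stimulus_markers = [(100.0, "stim")]
        flat = Trace(np.zeros_like(tr.samples), 0.1, stimulus_markers=[(100.0, "stim")], holding_potential=-70.0)
        with pytest.raises(ValueError, match="division-undefined"):
            pyr_pv_charge_ratio([(tr, flat)])


class TestLTDOutcome:
    def test_constant_series(self):
        exp, _ = gen_ltd_series(10, 40, 300.0, 1.0, 0.0, seed=0)
        assert ltd_outcome(exp)["post_pre_ratio"] == 1.0

    def test_occluded_depression_value(self):
        exp, _ = gen_ltd_series(10, 45, 400.0, 0.893, 0.0, seed=0)
        assert ltd_outcome(exp)["post_pre_ratio"] == pytest.approx(0.893, abs=1e-12)

    def test_units_invariance(self):
        exp, _ = gen_ltd_series(10, 45, 400.0, 0.644, 0.05, seed=1)
        r1 = ltd_outcome(exp)["post_pre_ratio"]
        scaled = LTDExperiment(exp.minutes, exp.amplitudes * 1000.0, exp.induction_end)
        assert ltd_outcome(scaled)["post_pre_ratio"] == pytest.approx(r1, rel=1e-12)

    def test_insufficient_post_coverage(self):
        exp, _ = gen_ltd_series(10, 45, 400.0, 0.644, 0.0, seed=0)
        short = LTDExperiment(exp.minutes[:30], exp.amplitudes[:30], exp.induction_end)
        with pytest.raises(ValueError, match="window-infeasible"):
            ltd_outcome(short)


class TestFIAnalysis:
    def test_table_neuron_rheobase_and_resistance(self, table1_neuron):
        rec = gen_fi_protocol(
            table1_neuron, [-50.0, 0.0, 100.0, 200.0, 220.0, 240.0], 1000.0
        )
        res = fi_analysis(rec)
        # closed-form rheobase is 200 pA; first spiking step within one increment
        assert res["rheobase"] == pytest.approx(220.0)
        assert res["input_resistance"] == pytest.approx(100.0, rel=1e-6)
        rates = dict(res["fi_curve"])
        assert rates[240.0] > rates[220.0] > 0.0

    def test_no_spikes_raises_with_curve(self, table1_neuron):
        rec = gen_fi_protocol(table1_neuron, [-50.0, 0.0, 50.0], 500.0)
        with pytest.raises(RheobaseUndefinedError) as exc:
            fi_analysis(rec)
        assert len(exc.value.fi_curve) == 3


class TestQuantalStats:
    def test_equal_rates_elevation_100(self):
        spec = SynthTraceSpec(duration=60_000.0, noise_sd=0.0, seed=13)
        trace, _ = gen_optogenetic_quantal_trace(spec, KIN, 3.0, 1.0, (20_000.0, 50_000.0))
        ev = detect_events(trace)
        q = quantal_amplitude_stats(ev, (20_000.0, 50_000.0))
        assert q["freq_elevation"] == pytest.approx(100.0, rel=0.35)

    def test_evoked_factor_recovered(self):
        """Frequency elevation tracks the seeded 4.85x factor within
        sampling error."""
        spec = SynthTraceSpec(duration=100_000.0, noise_sd=0.5, seed=17)
        window = (40_000.0, 90_000.0)
        trace, _ = gen_optogenetic_quantal_trace(
            spec, EventKinetics(0.5, 3.0, 10.7, 0.2), 2.0, 4.85, window
        )
        ev = detect_events(trace)
        q = quantal_amplitude_stats(ev, window)
        n_pre = (ev["included"] & (ev["onset_ms"] < window[0])).sum()
        n_in = (ev["included"] & (ev["onset_ms"] >= window[0]) & (ev["onset_ms"] <= window[1])).sum()
        se = 485.0 * np.sqrt(1.0 / n_pre + 1.0 / n_in)
        assert abs(q["freq_elevation"] - 485.0) < 3 * se

    def test_evoked_amplitude_recovered(self):
        """With evoked events dominating the laser window, the evoked mean
        amplitude recovers its construction value."""
        spec = SynthTraceSpec(duration=80_000.0, noise_sd=0.0, seed=18)
        window = (30_000.0, 78_000.0)
        trace, _ = gen_optogenetic_quantal_trace(
            spec,
            EventKinetics(0.5, 3.0, 10.7, 0.1),
            0.5,
            16.0,
            window,
            evoked_kinetics=EventKinetics(0.5, 3.0, 9.7, 0.1),
        )
        ev = detect_events(trace)
        q = quantal_amplitude_stats(ev, window)
        # in-window mixture: 0.5 Hz spontaneous at 10.7 pA + 7.5 Hz evoked at 9.7 pA
        assert q["evoked_mean_amp"] == pytest.approx(9.76, abs=0.4)
        assert q["spont_mean_amp"] == pytest.approx(10.7, abs=0.5)

    def test_no_baseline_events_rejected(self):
        spec = SynthTraceSpec(duration=10_000.0, noise_sd=0.0, seed=19)
        trace, _ = gen_optogenetic_quantal_trace(spec, KIN, 0.0, 100.0, (100.0, 9_000.0))
        ev = detect_events(trace)
        with pytest.raises(ValueError, match="baseline-undefined"):
            quantal_amplitude_stats(ev, (100.0, 9_000.0))


class TestUnitaryIPSC:
    KIN_U = EventKinetics(rise_tau=1.0, decay_tau=12.0, amp_mean=215.0, amp_cv=0.0)

    def test_success_rate_and_amplitude(self):
        trials, _ = gen_minimal_stim_trials(400, 0.5, 215.0, 5.0, self.KIN_U, seed=23)
        res = unitary_ipsc(trials, (0.0, 10.0))
        assert res["success_rate"] == pytest.approx(0.5, abs=3 * np.sqrt(0.25 / 400))
        assert res["mean_success_amp"] == pytest.approx(215.0, abs=12.0)

    def test_all_noise_undefined(self):
        trials, _ = gen_minimal_stim_trials(50, 0.0, 215.0, 5.0, self.KIN_U, seed=24)
        with pytest.raises(ValueError, match="estimate-undefined"):
            unitary_ipsc(trials, (0.0, 10.0))

    def test_subthreshold_amplitudes_are_failures(self):
        kin = EventKinetics(rise_tau=1.0, decay_tau=12.0, amp_mean=5.0, amp_cv=0.0)
        trials, _ = gen_minimal_stim_trials(60, 1.0, 5.0, 5.0, kin, seed=25)
        with pytest.raises(ValueError, match="estimate-undefined"):
            unitary_ipsc(trials, (0.0, 10.0))

    def test_too_few_trials(self):
        trials, _ = gen_minimal_stim_trials(5, 1.0, 215.0, 1.0, self.KIN_U, seed=26)
        with pytest.raises(ValueError):
            unitary_ipsc(trials, (0.0, 10.0))


class TestCompareGroups:
    def test_identical_samples(self):
        res = compare_groups([1, 2, 3], [1, 2, 3], "t_test")
        assert res["statistic"] == 0.0 and res["p_value"] == 1.0
        res = compare_groups(range(1, 11), range(1, 11), "rank_sum")
        assert res["p_value"] == pytest.approx(1.0)

    def test_separated_samples(self, rng):
        x = rng.normal(0.0, 1.0, 50)
        y = rng.normal(5.0, 1.0, 50)
        for method in ("t_test", "rank_sum", "ks"):
            assert compare_groups(x, y, method)["p_value"] < 1e-10

    def test_degenerate_and_invalid(self):
        with pytest.raises(ValueError, match="degenerate"):
            compare_groups([2, 2, 2], [2, 2, 2], "t_test")
        with pytest.raises(ValueError):
            compare_groups([1], [1, 2], "t_test")
        with pytest.raises(ValueError):
            compare_groups([1, np.nan], [1, 2], "t_test")
        with pytest.raises(ValueError):
            compare_groups([1, 2], [1, 2], "anova")
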