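# Methods

## The scientific question

Brief monocular deprivation (MD) during the visual critical period depresses
thalamocortical synapses in layer 4 of visual cortex, yet the measured
*feedforward* (thalamocortical-evoked) excitation-inhibition ratio shifts
toward excitation, because thalamic drive onto PV+ interneurons depresses
even more than drive onto pyramidal cells.  At the same time the *feedback*
(intracortical) E-I ratio shifts toward inhibition, driven by potentiation
of recurrent excitatory synapses onto PV+ interneurons.  This package
implements (a) the slice-electrophysiology quantification rules that produce
those ratios from raw current traces, (b) the arithmetic that converts them
into three synaptic-change factors, and (c) a spiking network model of a
local layer 4 circuit that asks which of the two opposing shifts wins.

## Plasticity factors

* `delta_e` = 0.9 — thalamic drive onto excitatory cells after MD, as a
  fraction of control (measured directly from evoked quantal amplitudes).
* `delta_i = delta_e / (shift of the PYR/PV EPSC charge ratio)`.  The shift
  of the pyramidal/PV charge ratio (deprived/control) equals
  `delta_e/delta_i`; with the published rounded shift of 1.5 this gives
  `delta_i = 0.6`.  The unrounded printed ratios (0.260 -> 0.369) give a
  shift of 1.42 and `delta_i = 0.634`; both are computable, and simulations
  default to the published 0.6.
* `pi = (control intracortical E-I ratio) / (deprived intracortical E-I
  ratio)`, attributing the whole shift to potentiation of recurrent
  excitation onto inhibitory cells (PV->pyramidal strength was measured to
  be unchanged; this assumption is recorded in the result metadata).  The
  printed means (0.091 -> 0.066) give 1.38; simulations default to the
  published 1.5.
* `rho_ei = delta_e / delta_i` summarizes the feedforward shift.

## Network model

5000 conductance-based leaky integrate-and-fire neurons, 80% excitatory,
20% inhibitory.  Membrane:

    C dV/dt = -gL (V - VL) - g_exc(t) (V - Vexc) - g_inh(t) (V - Vinh)

with C = 200 pF, gL = 10 nS, VL = -70 mV, Vexc = 0 mV, Vinh = -85 mV,
threshold -50 mV.  A presynaptic spike increments the target's conductance
by the pathway's peak conductance; conductances decay exponentially with
tau = 5 ms.  Recurrent weights: j = 0.3 nS for excitatory synapses,
g_rc * j = 2.4 nS for inhibitory ones.  Every neuron receives exactly 400
excitatory and 100 inhibitory recurrent connections drawn uniformly without
replacement (no autapses, no duplicate edges); the fixed in-degree is the
binding wiring rule and the 10% connection density is its consequence at
full size.  External drive: 100 thalamic Poisson trains at 8 Hz and 100
background trains at 14.2 Hz per neuron, weight j_s = 0.5 nS, with thalamic
drive onto inhibitory cells scaled by g_fw = 1.25 (0.625 nS).  Background
weights are identical for both cell types and are never changed by any
scenario.

### Decision parameters (not constrained by the measurements)

| parameter | default | rationale |
|---|---|---|
| reset potential | -70 mV (= VL) | sparse random E-I network convention |
| refractory period | 2 ms | same |
| recurrent synaptic delay | 1 ms (0 on external drive) | avoids same-step self-excitation |
| integration step dt | 0.1 ms | halving changes rates < 2% (tested) |
| initial voltages | uniform on [VL, Vtheta) per neuron | seeded |

All are configurable and recorded in every result file.

### Integration

Exponential Euler: conductances decay exactly between events
(`g *= exp(-dt/tau)`), and over one step the membrane relaxes toward the
instantaneous steady state with the total conductance held fixed.  The
scheme is unconditionally stable, and voltages stay within the reversal
potentials.  Threshold crossing uses a strict `V > Vtheta`, so a neuron
driven exactly to threshold (e.g. the 200 pA rheobase current of the model
cell) does not fire — the closed-form rheobase gL(Vtheta - VL) is
reproduced at one step-current resolution.

External compound Poisson drive is drawn as per-population aggregate event
counts per time step, each event assigned to a uniformly chosen neuron.
By superposition/thinning this is distributionally identical to independent
per-neuron trains (all channels of a pathway share one weight) and an order
of magnitude cheaper.  An integrator hook accepts a pre-drawn increment
matrix instead, which the tests use to feed the *same* input realization to
two integration schemes (native vs an independent forward-Euler reference)
and to two step sizes, making those comparisons paired.

### Scenarios

`BL` leaves all weights unscaled; `TC` multiplies thalamic weights onto
excitatory cells by `delta_e` and onto inhibitory cells by `delta_i`;
`TC_IC` additionally multiplies recurrent excitatory-to-inhibitory weights
by `pi`.  Background and recurrent inhibitory weights are never scaled.
Within one comparison the scenarios share connectivity, initial conditions
and the external input realization, so rate differences are attributable to
the weight changes alone.  Steady-state population rates discard a 500 ms
transient.

### Size-reduced networks

The Monte-Carlo sweep and the (rho, pi) grid run at N = 1000 with
proportional in-degrees (80 excitatory / 20 inhibitory) to keep runtimes
reasonable; `NetworkSpec.scaled` compensates the recurrent weights by the
in-degree ratio (x5) so each neuron keeps the full-size total recurrent
conductance.  Without this compensation the feedback loop is 5x weaker and
the TC+IC suppression disappears — an artifact of naive scaling, not of the
biology.  A residual finite-size effect remains: per-synapse increments are
larger, input fluctuations grow, and the baseline rate scale inflates
(roughly 30 Hz at the published parameters versus ~5 Hz at full size).
For this reason the sweep's rate-matching targets should be interpreted on
the scaled model's own rate scale; the shipped acceptance checks compute
them as the scaled model's baseline rates at the published parameters,
which selects the analogous operating point exactly as matching in-vivo
rates does for the full-size model.  The full-size three-scenario
comparison is run unscaled.

### Monte-Carlo sweep and grid

The sweep draws (j, g_rc, R_lgn, R_bkg) independently and uniformly from
the published ranges (j: 0.1-0.4 nS, g_rc: 7-10, rates: 5-15 Hz), keeps
networks whose baseline rates fall within +/-10% of the targets (both
populations by default; configurable), and applies TC and TC+IC to each
kept network with per-network baseline normalization.  Scaled-down
defaults: 500 draws x 3 s (versus the reference design of 100,000 x 9 s);
each draw's parameters and seeds derive deterministically from the master
seed.  In-vivo rate targets have *no defaults*: the reference values exist
only as a figure, so they are mandatory user input.

The grid fixes `delta_e = 0.9`, sets `delta_i = delta_e / rho` for each
grid row and applies `pi` per column, all cells sharing seeds.  Percent-of-
baseline uses the grid's own (rho = 1, pi = 1) cell as denominator — that
cell applies uniform 0.9 thalamic depression, matching the convention that
the grid isolates the *ratio* changes; its raw rates are also reported, and
the (1.5, 1.5) cell is bit-identical to the TC+IC pipeline under shared
seeds.

## Trace quantification

* **Event detection** — deterministic threshold crossing on a Gaussian-
  smoothed (sigma 0.3 ms) rectified trace; threshold `max(3 x noise SD,
  2 pA)` with the noise SD estimated robustly from the MAD of the first
  difference.  Peaks closer than 1 ms merge into one event (automated
  stand-in for the manual resolution of overlapping events, which has no
  published rule).  Amplitude and 20-80% linearly-interpolated rise time
  are measured on the raw trace against a 2 ms pre-onset baseline.
  Inclusion applies amplitude > 5 pA and rise < 3 ms; sub-criterion events
  are kept with `included = False`.
* **Decay constants** — log-linear least squares from the peak to
  peak + 10 ms; events truncated at the trace end or non-decaying are
  flagged instead of fitted.
* **Charge** — |trapezoidal integral of (current - baseline)| over a 100 ms
  post-stimulus window, baseline from 10 ms pre-stimulus; both windows
  configurable.  The finite window truncates a decay of time constant tau
  by O(e^(-100/tau)) — about 2 x 10^-4 relative for a 12 ms IPSC — which
  bounds the accuracy of "exact" noiseless recovery.
* **E-I charge ratio** — per-intensity EPSC/IPSC charge ratios averaged
  over pairs surviving the amplitude minima (thalamocortical 150/600 pA,
  intracortical 50/600 pA), with least-squares diagnostics (EPSC charge on
  IPSC charge) mirroring the published linear fits.
* **LTD outcome** — mean amplitude over minutes 5-30 after induction end,
  divided by the pre-induction mean; units-invariant.
* **FI analysis** — rate = spikes / step duration; rheobase = smallest
  spiking step; input resistance from the steady-state deflection (last
  20% of the step) on the most hyperpolarizing subthreshold step.
* **Unitary IPSC (minimal stimulation)** — a trial is a success when its
  1 ms boxcar-smoothed peak in a 2-20 ms post-stimulus window exceeds 3x
  the baseline-noise SD (floored at 1 pA); amplitudes are read from the raw
  peak near the smoothed maximum.
* **Group comparisons** — two-sided Student t, Wilcoxon rank sum, or
  two-sample Kolmogorov-Smirnov, mirroring the study's convention.

## Synthetic data

Raw recordings are not publicly available, so all inputs are generated with
the statistical structure the analyses assume: difference-of-exponentials
events `(1 - e^(-t/tau_r)) e^(-t/tau_d)`, peak-normalized so amplitude
parameters are literal peak amplitudes; lognormal amplitude spread
(strictly positive, right-skewed, like empirical quantal distributions);
i.i.d. Gaussian baseline noise at 10 kHz sampling.  Noise levels are free
parameters, not calibrated claims — the source recordings publish no noise
statistics.  The noise realization comes from a sub-stream independent of
the event stream, so trace = baseline + noise + sum of kernels holds
exactly (tested), and every generator's ground truth suffices to compute
the downstream metric exactly in the noiseless case.

What the generators do *not* emulate: electrode/access-resistance
artifacts, series-resistance errors, filtered (colored) noise,
multi-compartment waveform shaping, and genuinely overlapping multiquantal
events.  Passing tests therefore validate the quantification rules and the
pipeline's internal consistency, not detection performance on real
recordings.

## Verification summary

The suite checks, among others: Poisson/lognormal/binomial law recovery in
the generators; exact noiseless round-trips for every metric (E-I ratio
0.106, PYR/PV 0.260 and 0.369, LTD 0.644 and 0.893, decay 0.910 ms);
closed-form LIF oracles (rheobase 200 pA, input resistance 100 MOhm,
clamped-conductance ISI within 1%); a Campbell-theorem mean-conductance /
mean-voltage oracle (5.55 nS, within 1 mV); agreement with an independent
forward-Euler integrator within 5% under a shared input realization; dt
convergence (< 2% on halving); and the headline simulation results —
TC raises and TC+IC lowers both population rates on the full-size network
(>= 9/10 paired replicates), consistently across matched random networks,
with the grid monotone in rho and pi.  Simulation-based checks use 3 s
runs with a 0.5 s transient; these problem sizes are the package's test
defaults, chosen to keep the suite fast while leaving the conclusions
unchanged at longer durations.

## Known limitations

* The reduced-size sweep/grid inherit the finite-size rate-scale shift
  discussed above; quantitative percentages differ from full-size runs even
  though the qualitative pattern is robust.
* Reset potential, refractory period, delays and initial conditions are
  conventions, not measurements; results are reported with those values
  embedded.
* The overlap-merge rule in event detection is a deterministic stand-in for
  the original manual analysis.
* Factors carry no uncertainty: SEM propagation from the measured ratios is
  out of scope (the model uses point values).
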