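# l4ei — feedforward/feedback E-I ratio analysis and a layer 4 network model

Brief monocular deprivation during the visual critical period silences
layer 4 of rodent visual cortex, an effect long attributed to LTD at
thalamocortical synapses.  Slice measurements tell a more interesting
story: the *feedforward* (thalamocortical-evoked) excitation-inhibition
ratio actually shifts toward excitation — thalamic drive onto PV+
interneurons depresses more than drive onto pyramidal cells — while the
*feedback* (intracortical) E-I ratio shifts toward inhibition, via
potentiation of recurrent excitation onto PV+ interneurons.  `l4ei` is a
reusable pipeline for the computational side of that analysis, for
computational and systems neuroscientists who want to quantify E-I ratios
from voltage-clamp data or probe the circuit-level consequences of opposing
E-I shifts:

* **`l4ei.synth`** — synthetic voltage-clamp/current-clamp recordings with
  known ground truth (quantal-event traces, paired EPSC/IPSC sweep
  families, LTD series, minimal-stimulation trials, FI protocols);
* **`l4ei.metrics`** — the quantification rules: event detection with the
  amplitude (> 5 pA) and rise-time (< 3 ms) inclusion criteria, charges and
  E-I charge ratios with amplitude minima, LTD outcomes, FI/rheobase/input
  resistance, unitary IPSC estimates, group statistics;
* **`l4ei.factors`** — the deprivation factors: thalamic depression onto
  excitatory (delta_E) and inhibitory (delta_I) cells and recurrent E-to-I
  potentiation (pi), with rho_EI = delta_E/delta_I;
* **`l4ei.network`** — a conductance-based leaky integrate-and-fire network
  of layer 4 (5000 neurons, 80/20 E/I, exponential synapses, fixed
  in-degree random wiring, Poisson thalamic + background drive), with a
  fast numba integrator;
* **`l4ei.scenarios`** — the in-silico experiments: paired baseline (BL) /
  thalamocortical depression (TC) / TC + intracortical potentiation
  (TC+IC) comparisons, a Monte-Carlo robustness sweep with baseline rate
  matching, and a (rho_EI, pi) grid scan.

The headline model result: depressing thalamic drive (TC, with
delta_E = 0.9 and delta_I = 0.6) *raises* network firing — feedforward
disinhibition wins — but adding the measured feedback potentiation
(pi = 1.5) reverses the sign and suppresses both populations below
baseline.  Enhanced feedback inhibition, not thalamocortical LTD, is what
silences the circuit.

## Worked example

```python
import l4ei

# factors from the measured ratios: delta_E = 0.9, E-I shift = 1.5
delta_i = l4ei.derive_delta_i(0.9, ratio_control=1.0, ratio_deprived=1.5)
factors = l4ei.make_factors(0.9, delta_i, 1.5)
print(delta_i, factors.rho_ei)

# paired three-scenario comparison on a reduced network (N = 1000, 3 s)
res = l4ei.run_condition_comparison(
    l4ei.NeuronParams(), l4ei.NetworkSpec.scaled(1000), l4ei.InputSpec(),
    factors, duration=3000.0, seed=7, keep_results=False,
)
for scen, (e, i) in res.rates.items():
    pe, pi_ = res.percent_of_bl[scen]
    print(f"{scen}: E {e:.2f} Hz ({pe:.0f}%)  I {i:.2f} Hz ({pi_:.0f}%)")
```

prints

```
0.6 1.5
BL: E 27.37 Hz (100%)  I 31.12 Hz (100%)
TC: E 41.09 Hz (150%)  I 40.60 Hz (130%)
TC_IC: E 6.47 Hz (24%)  I 15.15 Hz (49%)
```

`delta_I = 0.6` is the depression of thalamic drive onto inhibitory cells
implied by dividing the excitatory depression (0.9) by the 1.5x shift of
the feedforward E-I ratio.  Under TC both populations fire *more* than
baseline (the stronger depression onto interneurons disinhibits the
circuit); under TC+IC the potentiated recurrent drive onto interneurons
overcomes this and pushes both populations *below* baseline — the opposing
E-I shifts net out as suppression.  (Reduced-size networks compensate
recurrent weights to preserve per-neuron input; their rate scale is higher
than the full-size model's — see `docs/methods.md`.)

The same pipeline is scriptable from the shell:

```bash
l4ei derive --delta-e 0.9 --tc-shift 1.5 --pi 1.5 --out factors.json
l4ei compare --duration 3000 --seed 7 --out out/          # Table-level config built in
l4ei synth mepsc --rate 2 --seed 3 --out synth/ && l4ei ephys detect --in synth/trace.csv --out events/
l4ei sweep --n 500 --target-e 30 --target-i 33 --tol 0.10 --seed 1 --out sweep/
l4ei grid --rho 1:1.5:4 --pi 1:1.5:4 --seed 1 --out grid/
```

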