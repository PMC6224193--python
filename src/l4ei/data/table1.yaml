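# Published parameters of the layer 4 network model.
# Keys carry explicit unit suffixes; g_rc and g_fw are the dimensionless
# pre-factors (the published inhibitory peak conductance is g_rc * j = 2.4 nS
# and the inhibitory thalamic weight is g_fw * js = 0.625 nS).
neuron:
  C_pF: 200.0
  gL_nS: 10.0
  VL_mV: -70.0
  Vexc_mV: 0.0
  Vinh_mV: -85.0
  Vtheta_mV: -50.0
  tau_syn_ms: 5.0
  # decision parameters (not experimentally constrained):
  Vreset_mV: -70.0
  t_ref_ms: 2.0
network:
  N: 5000
  NE: 4000
  NI: 1000
  in_degree_e: 400
  in_degree_i: 100
  j_nS: 0.3
  g_rc: 8.0
  delay_ms: 1.0
input:
  js_nS: 0.5
  g_fw: 1.25
  n_lgn: 100
  R_lgn_Hz: 8.0
  n_bkg: 100
  R_bkg_Hz: 14.2
factors:
  delta_e: 0.9
  delta_i: 0.6
  pi: 1.5
sweep_ranges:
  j_nS: [0.1, 0.4]
  g_rc: [7.0, 10.0]
  R_lgn_Hz: [5.0, 15.0]
  R_bkg_Hz: [5.0, 15.0]
sim:
  dt_ms: 0.1
  duration_ms: 9000.0
  transient_ms: 500.0
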