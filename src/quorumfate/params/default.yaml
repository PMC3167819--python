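schema: quorumfate-params-v1
curves:
  wnt_signal_curve:
    kind: up
    vmax: 10.0
    half_sat: 2.0
    hill: 2.0
  dkk_inhibition_curve:
    kind: down
    vmax: 1.0
    half_sat: 21.25
    hill: 6.0
  dkk_synth_curve:
    kind: up
    vmax: 0.023483
    half_sat: 1.0
    hill: 2.0
  lef_ecad_curve:
    kind: down
    vmax: 1.0
    half_sat: 14.9
    hill: 2.0
  ecad_synth_curve:
    kind: down
    vmax: 1.0
    half_sat: 1.0
    hill: 2.0
  pf_synth_curve:
    kind: up
    vmax: 1.0
    half_sat: 1.6
    hill: 4.0
  notch_deg_curve:
    kind: down
    vmax: 0.05
    half_sat: 0.9
    hill: 2.0
  hes_synth_curve:
    kind: up
    vmax: 0.33
    half_sat: 2.4
    hill: 2.0
  df_synth_curve:
    kind: down
    vmax: 0.8
    half_sat: 2.0
    hill: 2.0
degradation:
  dkk_deg: 0.2
  lef_deg: 1.0
  ecad_deg: 0.1
  pf_deg: 0.1
  hes_deg: 0.0667
  df_deg: 0.025
scalars:
  notch_synth: 0.05
  ecad_binding_coeff: 0.5
  pf_threshold: 5.2
  df_threshold: 8.55
  tau: 24.0
  phi: 168.0
  dsl_level: 1.2
  wnt_ext: 1.0
  ng_per_model_unit: 2.01
  pericellular_factor: 12.4726
initial_state:
  dkk_produced: 0.0
  lef_tcf: 2.0
  ecad_total: 5.0
  pf: 0.0
  notch: 15.0
  hes: 8.0
  df: 0.0
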