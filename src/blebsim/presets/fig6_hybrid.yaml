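cell:
  n_nodes: 96
  newtonian: true
  radius: 10.0
cortex:
  N_myo: 12800.0
  death_fraction: 0.05
  f_myo: 5.0
  gamma0: 0.001
  kappa_c: 0.1
  n_act_bar: 20000.0
  v_myo: 0.5
fluid:
  domain_size: 80.0
  dt: 0.00025
  eta_f: 0.4
  grid_shape:
  - 128
  - 128
linkers:
  rest_length: 0.2
  site_capacity: 20.0
  stiffness: 20.0
membrane:
  bending_stiffness: 8.0
  tension_stiffness: 150.0
osmotic:
  Pi_out: 20.0
protocol:
  detachment_arc:
  - -18.0
  - 18.0
  duration: 8.0
  equilibration: 1.0
  kind: single_bleb
rates:
  F_b: 8.0
  K_tau: 4.0
  k_act_decay: 8.0
  k_act_off: 1.0
  k_act_on: 1.0
  k_adh_on: 10.0
  k_myo_off: 1.0
  k_myo_on: 1.0
  k_off0: 1.0
  recruit_delay: 0.1
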