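cell:
  n_nodes: 64
  newtonian: true
  radius: 10.0
cortex:
  N_myo: 6400.0
  death_fraction: 0.05
  f_myo: 4.0
  gamma0: 0.001
  kappa_c: 0.1
  n_act_bar: 20000.0
  v_myo: 0.5
fluid:
  domain_size: 80.0
  dt: 0.001
  eta_f: 0.5
  grid_shape:
  - 96
  - 96
linkers:
  rest_length: 0.2
  site_capacity: 5.0
  stiffness: 40.0
membrane:
  bending_stiffness: 4.0
  tension_stiffness: 100.0
osmotic:
  Pi_out: 20.0
  balance_offset: 20.0
  permeability: 0.05
  vant_hoff: true
protocol:
  duration: 5.0
  equilibration: 0.5
  kind: stochastic_swim
rates:
  F_b: 0.7
  K_tau: 1.0
  k_act_decay: 8.0
  k_act_off: 1.0
  k_act_on: 1.0
  k_adh_on: 5.0
  k_myo_off: 1.0
  k_myo_on: 1.0
  k_off0: 0.03
  recruit_delay: 0.1
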