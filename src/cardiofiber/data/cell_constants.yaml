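version: 1
units: mV ms nA uS nF mM uL
parameters:
  G_K1: 0.5
  G_Na: 0.5
  R: 8314.472
  T: 310.0
  F: 96485.3415
  C_m: 0.095
  V_cell: 3.347681131665283e-05
  V_i_ratio: 0.49
  V_ds_ratio: 0.1
  V_up_ratio: 0.01
  V_rel_ratio: 0.1
  K_o: 5.4
  Na_o: 140.0
  Ca_o: 2.0
  k_mK1: 10.0
  K1_steepness: 1.25
  g_pNa: 0.004
  g_bNa: 0.0006
  delta_m: 1.0e-05
  P_mh: 0.12
  g_Kr1: 0.0021
  g_Kr2: 0.0013
  g_Ks: 0.0026
  P_kna: 0.03
  g_to: 0.005
  g_tos: 0.0
  P_Ca_L: 0.1
  P_CaK: 0.002
  P_CaNa: 0.01
  FrICa: 1.0
  speed_d: 3.0
  speed_f: 0.3
  Km_f2: 100000.0
  Km_f2ds: 0.001
  R_decay: 20.0
  g_bCa: 0.00025
  i_NaK_max: 0.7
  K_mK: 1.0
  K_mNa: 40.0
  k_NaCa: 0.0005
  gamma_NaCa: 0.5
  n_NaCa: 3.0
  d_NaCa: 0.0
  FRiNaCa: 0.001
  K_cyca: 0.0003
  K_xcs: 0.4
  K_srca: 0.5
  alpha_up: 0.4
  beta_up: 0.03
  K_m_rel: 250.0
  K_leak_rate: 0.05
  K_trans: 50.0
  K_m_Ca_cyt: 0.0005
  K_m_Ca_ds: 0.01
  K_act_rate: 500.0
  K_inact_base: 60.0
  K_prod_decay: 1.0
  Kdecay: 10.0
  Calmod_total: 0.02
  Trop_total: 0.05
  alpha_Calmod: 100000.0
  beta_Calmod: 50.0
  alpha_Trop: 100000.0
  beta_Trop: 200.0
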