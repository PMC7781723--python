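# Calibrated swine configuration, subject 1.
# Units: volumes L, pressures mmHg, time min, compliances L/mmHg,
# resistances mmHg*min/L, rates 1/min, k_Vcap L/min/mmHg.
parameters:
  k_VED0: 0.00714414
  P_0LV: 2.03247
  k_ELV: 65.6531
  R_valve: 0.0416667
  C_A: 0.0031
  C_V: 0.05083
  V_Aun: 0.17072
  nu_cut: 0.00252
  S_sat: 25.0
  P_Aset: 68.3393
  V_total: 2.85
  nu_HR_min: 0.0
  nu_HR_max: 166.0
  C_PRSW_min: 14.509
  C_PRSW_max: 130.1
  R_TPR_min: 14.8333
  R_TPR_max: 19.8333
  V_Vun_Min: 1.47
  V_Vun_Max: 1.625
  k_Vcap: 2.1e-05
  S_F: -1
  nu_HR0_max: 166.0
protocol:
  t_bleedstart: 40.0
  t_bleedend: 73.0
  F_withdrawal: 0.92
  shape: exponential_decay
grid:
  t0: 0.0
  t_end: 500.0
  t_delta: 0.01
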