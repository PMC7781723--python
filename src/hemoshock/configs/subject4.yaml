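# Calibrated swine configuration, subject 4.
# Units: volumes L, pressures mmHg, time min, compliances L/mmHg,
# resistances mmHg*min/L, rates 1/min, k_Vcap L/min/mmHg.
parameters:
  k_VED0: 0.00714414
  P_0LV: 2.03247
  k_ELV: 65.6531
  R_valve: 0.0416667
  C_A: 0.0011
  C_V: 0.0973
  V_Aun: 0.21
  nu_cut: 0.000282
  S_sat: 25.0
  P_Aset: 73.0
  V_total: 4.29
  nu_HR_min: 0.0
  nu_HR_max: 166.2
  C_PRSW_min: 30.509
  C_PRSW_max: 65.1
  R_TPR_min: 16.8333
  R_TPR_max: 18.8
  V_Vun_Min: 1.66
  V_Vun_Max: 2.15
  k_Vcap: 1.0e-07
  S_F: -1
  nu_HR0_max: 166.2
protocol:
  t_bleedstart: 33.3
  t_bleedend: 50.0
  F_withdrawal: 1.73
  shape: exponential_decay
grid:
  t0: 0.0
  t_end: 500.0
  t_delta: 0.01
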