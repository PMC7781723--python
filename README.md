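# hemoshock

A lumped-parameter cardiovascular simulator of controlled hemorrhagic
shock: a single-ventricle, baroreflex-controlled five-ODE circulation
model extended with transcapillary refill, plus ripple-free steady-state
initialization, hemorrhage protocols, Nelder–Mead parameter calibration,
one-at-a-time sensitivity analysis and a synthetic-observation generator.

It is aimed at physiological modelers and trauma-informatics researchers
who need a model that is simple enough to calibrate against sparse
bedside observables — mean arterial pressure (MAP), heart rate (HR) and
cardiac output (CO) — yet rich enough to reproduce the baseline, bleed
and post-bleed phases of a controlled-hemorrhage experiment, including
the pressure recovery after bleeding stops that a refill-free model
cannot produce.

## The model

The heart is a single ventricle whose end-systolic and end-diastolic
volumes relax toward beat-averaged targets at the heart-rate timescale:

- ejection follows the preload-recruitable-stroke-work (PRSW) law — stroke
  work linear in the recruited preload `V_ED − k_VED0` with slope
  `C_PRSW` — floored at the zero-filling-pressure volume `k_VED0`;
- diastolic filling integrates `dV/dt = (P_CVP − P_LV(V))/R_valve` over
  the diastolic interval, with the passive law
  `P_LV(V) = P_0LV·(exp(k_ELV·(V − k_VED0)) − 1)`, in closed form.

Arteries and veins are linear Windkessel compartments
(`P = (V − V_un)/C`) joined by the total peripheral resistance `R_TPR`.
The baroreflex senses arterial pressure through a logistic nonlinearity
centered on the set point `P_Aset` (99% saturation at a deviation of
`S_sat` either way) and drives four effectors — heart rate `ν_HR`,
resistance `R_TPR`, contractility `C_PRSW` and the venous unstressed
volume `V_Vun` — through linear maps of a first-order low-pass drive
`S_E`. The five states are `(V_ES, V_ED, V_A, V_V, S_E)`.

Hemorrhage enters as a negative venous inflow `I_bleed(t)` (total volume,
window, constant or decaying rate shape, optional MAP safety guard), and
transcapillary refill as `I_refill = k_Vcap·(P_CVP0 − P_CVP)` — interstitial
fluid returning to the vasculature in proportion to the venous pressure
deficit. With `k_Vcap = 0` the model reduces exactly to its refill-free
(Zenker-type) predecessor.

Initialization solves the resting constraint chain (drive at the logistic
midpoint, pressure at the set point, cardiac output equal to capillary
flow) so simulations start on the fixed point with no startup transient.
Integration is fixed-step classic RK4. Calibration minimizes the
normalized least-squares cost

    J(θ) = Σ_t [((MAP_exp − MAP_sim)/MAP_exp)² + ((HR_exp − HR_sim)/HR_exp)²
              + ((CO_exp − CO_sim)/CO_exp)²]

by Nelder–Mead over a named subset of the sixteen free parameters, and
sensitivities are one-at-a-time forward differences of the per-channel
normalized mean-squared error under +10% perturbations.

Four calibrated swine configurations ship with the package
(`hemoshock.load_subject(1..4)`).

## Worked example

```python
import hemoshock as hs

cfg = hs.load_subject(1)            # 2.85 L pig, 0.92 L bleed over 40-73 min
ss = hs.initialize(cfg.parameters)
print(f"resting MAP {ss.P_A0:.4f} mmHg, HR {ss.nu_HR0:.0f} /min, "
      f"CO {ss.I_CO0:.5f} L/min")

traj = hs.simulate(cfg.parameters, cfg.protocol, cfg.grid)
end_bleed = traj.at(cfg.protocol.t_bleedend)
final = traj.frame.iloc[-1]
print(f"end of bleed: MAP {end_bleed['P_A']:.2f} mmHg, "
      f"HR {end_bleed['nu_HR']:.1f} /min, CO {end_bleed['I_CO']:.2f} L/min")
print(f"end of run  : MAP {final['P_A']:.2f} mmHg, "
      f"HR {final['nu_HR']:.1f} /min, CO {final['I_CO']:.2f} L/min")
msi = hs.modified_shock_index(traj.frame["nu_HR"], traj.frame["P_A"])
print(f"peak MSI {msi.max():.3f}")
```

prints

```
resting MAP 68.3393 mmHg, HR 83 /min, CO 2.89853 L/min
end of bleed: MAP 31.23 mmHg, HR 113.2 /min, CO 1.55 L/min
end of run  : MAP 56.97 mmHg, HR 150.3 /min, CO 2.71 L/min
peak MSI 3.627
```

Withdrawing 32% of the blood volume roughly halves arterial pressure and
cardiac output and raises heart rate by a third; over the following seven
hours transcapillary refill restores most of the pressure deficit (with
`k_Vcap = 0` the recovery is markedly weaker), while the slow baroreflex
drive keeps pushing heart rate up. The modified shock index HR/MAP — a
triage marker whose values above 1.3 predict mortality — peaks near the
end of the bleed.

The same runs are available from the shell:

```bash
hemoshock simulate src/hemoshock/configs/subject1.yaml -o trajectory.csv
hemoshock synth    src/hemoshock/configs/subject1.yaml -o observations.csv --seed 7
hemoshock fit      src/hemoshock/configs/subject1.yaml observations.csv --fit k_Vcap
hemoshock sensitivity src/hemoshock/configs/subject1.yaml observations.csv
```

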