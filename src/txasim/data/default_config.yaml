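# Default run: adult 2 g IV reference vs pediatric 20-35 mg/kg bolus sweep.
# Model parameters default to the published final-model values; override any
# field of the parameter set here (e.g. cl_typ: 192.0, exp_il8: -0.0887 for
# the parameter-table variant).
model_parameters: {}

adult_population:
  mode: adult
  n_subjects: 1000
  fixed_covariates:
    weight: 80.1   # kg
    plt: 197.0     # K/uL
    nirs: 88.0     # %
    il8: 20.3      # pg/mL

pediatric_population:
  mode: pediatric
  n_subjects: 1000
  ranges:            # closed intervals, sampled uniformly and independently
    weight: [17.7, 58.2]
    plt: [205.0, 433.0]
    nirs: [51.0, 80.0]
    il8: [6.6, 50.2]
    age: [4.7, 15.4]

adult_regimen:
  label: "adult 2 g"
  dose_mg: 2000.0
  infusion_duration: 1.0   # min

pediatric_regimens:
  - {label: "20 mg/kg", dose_per_kg: 20.0, cap_mg: 2000.0, infusion_duration: 1.0}
  - {label: "25 mg/kg", dose_per_kg: 25.0, cap_mg: 2000.0, infusion_duration: 1.0}
  - {label: "30 mg/kg", dose_per_kg: 30.0, cap_mg: 2000.0, infusion_duration: 1.0}
  - {label: "35 mg/kg", dose_per_kg: 35.0, cap_mg: 2000.0, infusion_duration: 1.0}

grid:
  horizon: 480.0   # min; dense-early default grid

threshold: 10.0          # mg/L, ~80% inhibition of fibrinolysis in vitro
auc_windows: [240.0, 480.0]
error_mode: true         # proportional residual error on observations
seed: 20250101
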