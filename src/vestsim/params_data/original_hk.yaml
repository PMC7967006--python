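# Unmodified published point-model parameterization (irregular afferent).
name: original_hk
axon:
  g_Na: 20.0      # mS/cm^2; calibrated (scripts/calibrate_variants.py)
  g_KH: 2.8
  g_KL: 1.1
  g_leak: 0.03
  E_Na: 55.0      # mV
  E_K: -81.0
  E_leak: -65.0
  C_m: 0.9        # uF/cm^2
  area: 1.0e-5    # cm^2
epsc:
  mu0: 3.0        # ms, published resting inter-EPSC interval
  K: 137.5        # pA unitary peak; calibrated to fr_o ~ 52.7 sps
  tau_rise: 0.3   # ms
  tau_decay: 0.5  # ms
coupling_pA_per_uA: 0.945 # calibrated to the -0.5 sps/uA slope
nq_gain: 1.0
fr_o: 52.7        # sps, nominal spontaneous rate
fr_max: null
adaptation:
  G_f: 2.0        # sps/uA
  G_s: 0.5
  tau_f: 0.15     # s
  tau_s: 2.0
  anodic_fast_attenuation: 0.5
  f_c: 1000.0     # Hz
dt_ms: 0.01
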