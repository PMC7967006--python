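# In vivo irregular afferent: fast EPSC arrival (mu0 = 0.75 ms) and the
# non-quantal gain on GVS-injected current.  Axon densities are the shared
# baseline (see original_hk.yaml); in this parameterization the induced
# firing range is carried by EPSC arrival rate + NQ gain rather than by
# further conductance scaling.
name: invivo
axon:
  g_Na: 20.0
  g_KH: 2.8
  g_KL: 1.1      # held fixed; sets irregular-afferent firing statistics
  g_leak: 0.03
  E_Na: 55.0
  E_K: -81.0
  E_leak: -65.0
  C_m: 0.9
  area: 1.0e-5
epsc:
  mu0: 0.75      # ms -> fr_o ~ 100 sps
  K: 137.5       # shared with original_hk (EPSC amplitude constant across conditions)
  tau_rise: 0.3
  tau_decay: 0.5
coupling_pA_per_uA: 1.44  # calibrated to the full-model -1.99 sps/uA slope
nq_gain: 4.5              # non-quantal amplification of GVS current
fr_o: 100.3
fr_max: null
adaptation:
  G_f: 2.0
  G_s: 0.5
  tau_f: 0.15
  tau_s: 2.0
  anodic_fast_attenuation: 0.5
  f_c: 1000.0
dt_ms: 0.01
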