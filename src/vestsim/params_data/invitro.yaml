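# Low-conductance in vitro (explant) afferent: reduced g_Na, no NQ gain,
# low spontaneous rate, firing range clipped at 55 sps.
name: invitro
axon:
  g_Na: 5.0      # reduced vs baseline 20; calibrated to fr_o ~17 sps
  g_KH: 2.8
  g_KL: 1.1
  g_leak: 0.03
  E_Na: 55.0
  E_K: -81.0
  E_leak: -65.0
  C_m: 0.9
  area: 1.0e-5
epsc:
  mu0: 3.0
  K: 137.5
  tau_rise: 0.3
  tau_decay: 0.5
coupling_pA_per_uA: 0.945 # micropipette coupling; shares the original-variant scalar
nq_gain: 1.0
fr_o: 17.5
fr_max: 55.0
adaptation:
  G_f: 2.0
  G_s: 0.5
  tau_f: 0.15
  tau_s: 2.0
  anodic_fast_attenuation: 0.5
  f_c: 1000.0
dt_ms: 0.01
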