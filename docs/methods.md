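# Methods

`vestsim` simulates how continuous (galvanic, "DC") electrical current
modulates the firing of an irregular vestibular afferent, through two
pathways at once: direct polarization of the spike-initiating axon, and
activation of the hair cell's natural adaptation machinery, which reaches
the axon as a change in synaptic event rate.

## Axon model

The axon is a single isopotential compartment with four currents: a
transient sodium current (gates m^3 h), a high-voltage-gated potassium
current KH (0.85 n^2 + 0.15 p), a low-voltage-gated potassium current KL
(w^4 z, half of z non-inactivating) and an ohmic leak.  Gating kinetics are
the Rothman–Manis ventral-cochlear-nucleus formulation that the
vestibular-ganglion point-model literature adapts.  KL density is what makes
the cell fire irregularly: it keeps the resting potential low-impedance and
phasic, so spikes occur only when a synaptic event happens to cross
threshold, and the spike train inherits the randomness of the synaptic
process.

Membrane equation (V in mV, t in ms, conductance densities in mS/cm^2,
injected currents in pA over `area` cm^2):

    C_m dV/dt = -(I_Na + I_KH + I_KL + I_leak) + (i_syn + i_gvs) 1e-6 / area
    dx/dt     = (x_inf(V) - x) / tau_x(V)          for x in {m,h,n,p,w,z}

Defaults: C_m = 0.9 uF/cm^2, area = 1e-5 cm^2 (a ~9 pF cell), E_Na = +55 mV,
E_K = -81 mV, E_leak = -65 mV, g_KL = 1.1 mS/cm^2, g_KH = 2.8 mS/cm^2,
g_leak = 0.03 mS/cm^2.  The sodium density (g_Na = 20 mS/cm^2) and all
constants not available in print were *calibrated once* against the
published firing statistics of the unmodified model (spontaneous rate
52.7 sps, peak GVS-evoked rate ~70 sps with cathodic block, slope
-0.5 sps/uA); the procedure is reproducible with
`scripts/calibrate_variants.py` and the results are frozen in
`src/vestsim/params_data/*.yaml`.  No constant is re-tuned per experiment.

Integration is exponential Euler on the gating variables with a forward
step on V at dt = 0.01 ms (halving dt changes the firing rate by <2%).
Gating steady states and relaxation factors are tabulated on a 0.02 mV grid
and linearly interpolated inside a numba-compiled loop, which makes a 10 s
simulation run in ~0.1 s.  Spikes are upward crossings of -20 mV with a
1 ms refractory merge; model action potentials overshoot well past this
threshold, so detection is insensitive to the exact value (anything in
-30..0 mV gives identical counts).

Numerical guard: the model contains no inward-rectifying current, so strong
anodic current legitimately drives V far below physiological values with
purely passive, stable dynamics; only depolarization beyond +300 mV or NaN
is treated as an integration failure.

## Synaptic drive

Hair-cell vesicle release is an exponential renewal process with mean
inter-event interval mu (ms); each event adds a unit-peak biexponential
EPSC (rise 0.3 ms, decay 0.5 ms) scaled by K = 137.5 pA.  K is identical
across all variants and conditions (EPSC amplitudes are treated as
constant; only arrival rate carries signal).  At rest mu = mu0: 3 ms for
the unmodified and in vitro variants, 0.75 ms for the in vivo variant.

Rate modulation: a target rate fr_target(t) = fr_o + fr_adapt(t) is
converted to the synaptic interval by inverse proportionality anchored at
the resting point,

    mu(t) = mu0 * fr_o / max(fr_target(t), 0.5 sps),   clipped to [0.05, 1e4] ms,

re-evaluated only every t_dmu ms (default t_dmu = mu0).  The piecewise
constancy is itself a model ingredient: enlarging t_dmu to 5 mu0 introduces
a sampling low-pass that reduces cathodic-half gain and drives the phase of
sinusoidal responses below zero at high frequency.

## Electrode coupling and the non-quantal gain

Electrode current (uA, cathodic negative) maps to axon-injected current as
i_axon = -coupling * nq_gain * i_ext, so cathodic current depolarizes.  The
coupling scalar is the one quantity with no printed value and no
first-principles anchor (it absorbs electrode geometry and tissue path), so
it is calibrated per preparation: 0.945 pA/uA for the original/in vitro
parameterizations (fitted to the -0.5 sps/uA slope of the unmodified model)
and 1.44 pA/uA for the in vivo variant (fitted to the complete model's
-1.99 sps/uA slope).  The non-quantal (calyx) effect is a static gain of
4.5 on GVS-injected current only — never on EPSC current — present in the
in vivo variant and absent in vitro.

## Hair-cell adaptation

The adaptation pathway is linear and time-invariant: with drive
x(t) = -i_ext(t) (cathodic positive),

    fr_adapt(t) = G_f HP_{tau_f}[x_f](t) + G_s HP_{tau_s}[x](t),

first-order high-passes with tau_f = 0.15 s and tau_s = 2 s, followed by a
first-order low-pass at f_c = 1 kHz (the ceiling on how fast firing can
follow input).  The fast-component drive x_f is attenuated by 0.5 during
anodic input (the fast component is weaker for inhibitory stimuli; the 0.5
factor is a package choice, and results are insensitive to values in
0.3-0.7 because the fast transient is brief).  Gains default to
G_f = 2 sps/uA and G_s = 0.5 sps/uA, chosen so a 10 uA cathodic step
produces a ~25 sps onset transient — the size of the in vitro transient
relative to its 0-55 sps firing range; `haircell.fit_adaptation_gains` is
the fitting routine used to derive such gains from step-response traces.
The frequency response

    H(f) = [G_f s tau_f/(1+s tau_f) + G_s s tau_s/(1+s tau_s)] / (1 + i f/f_c)

is a band-pass centered near 1/tau_f: phase lead ~+55 deg at 0.1 Hz,
decaying to ~0 by 4-8 Hz.

Total rate: fr(t) = clip(fr_adapt + fr_axon, 0, fr_max), with fr_max =
55 sps in vitro.  The clipped sum, with fr_axon = fr_o, reproduces the
baseline-dependent plateau asymmetry of the in vitro preparation
(anodic-on-anodic steps floor at 0, cathodic-on-cathodic ceiling at 55),
while the in vivo model responds identically from every baseline.

## Model variants

| | original_hk | invivo | invitro |
|---|---|---|---|
| g_Na (mS/cm^2) | 20 | 20 | 5 |
| mu0 (ms) | 3 | 0.75 (0.48 in the complete model) | 3 |
| NQ gain | 1 | 4.5 | 1 |
| coupling (pA/uA) | 0.945 | 1.44 | 0.945 |
| spontaneous rate (sps) | ~53 | ~95-100 (120 complete) | ~17 |

Two deliberate departures from the obvious reading of the source
parameterization, both forced by the kinetics used here and recorded as the
package's own choices:

- The in vivo variant does not scale g_Na/g_KH above baseline.  In these
  kinetics, scaling conductances up raises the spontaneous rate past
  100 sps without widening the GVS-induced range; the wide induced range is
  instead carried by fast EPSC arrival plus the NQ gain.
- The complete in vivo model uses mu0 = 0.48 ms, calibrated to the defining
  property of that condition (spontaneous rate 120 sps), because mu0 =
  0.25 ms produces ~225 sps here.

Two known quantitative divergences follow from this model family and are
left visible rather than tuned away: without the NQ gain the mu0 = 0.75
variant's slope over +-45 uA is ~0 (a shallow sodium-inactivation dip, vs
the published -0.32 sps/uA) and its maximum over the cathodic sweep is
~105 sps rather than 188; and the complete model's maximum induced rate is
~230-240 sps, ~10% above the published 211 +- 8.7.

## Statistics

- Firing rate: spike count over the analysis window (the step window for
  sweeps); CV = std/mean of ISIs, undefined below three spikes.
- Rate-vs-current slope: ordinary least squares on the population-mean rate
  over the +-45 uA linear region (below cathodic block), with a 95%
  bootstrap-over-neurons CI (500 resamples, seeded).
- CV* conformance: fraction of (mean ISI, CV) points inside a configurable
  two-curve envelope.  The default envelope is synthetic (power-law band),
  for testing the machinery; the published empirical boundary curves are
  not digitized, so coverage percentages are demonstrated qualitatively
  only.
- Step-response fits: double exponential plus offset (`curve_fit`, bounded;
  fast tau in [1 ms, 0.3 s], slow tau in [0.3 s, 20 s]) on 50-100 ms boxcar
  rate traces averaged across neurons.
- Sinusoidal metrics: half-cycle mean rates plus the phase of the first
  Fourier harmonic of the cycle-folded spike histogram, referenced to the
  cathodic stimulus peak (positive = lead).  Phase is flagged undefined at
  zero first-harmonic amplitude.
- Cluster-based permutation test: pointwise two-sample t thresholded at the
  two-sided p<0.05 critical value, clusters scored by summed |t|, null from
  label permutations of the per-neuron traces; type-I error verified <=
  alpha + 2 SE under null simulations.

## Synthetic data and what passing tests show

`experiments.generate_fixtures` produces periodic, Poisson,
sinusoidally-modulated Poisson and double-exponential-rate fixtures with
known ground truth; these validate the estimators independently of the
biophysics.  The EPSC generator itself is the model's noise source — there
is no additional channel noise, electrode noise or inter-neuron parameter
heterogeneity, so across-population variability in simulations is purely
synaptic-sampling variability and is narrower than in real recordings.
Tests passing on this generator demonstrate internal consistency of model +
estimators at the published operating points, not that real afferents have
these parameters.

## Problem sizes

Population experiments use N = 19 neurons (the replicated studies' own
sample size) with 5 s records per amplitude step and 10 s records for
spontaneous-rate estimates; amplitude grids use 5 uA spacing.  Sinusoidal
runs use >=5 cycles or 20 s, whichever is longer, with N = 3; adaptation
step fits use N = 8 and 12 s steps.  A full replication pass simulates
roughly 1.5 h of membrane time and completes in a few minutes on one CPU.

## Known limitations

- No inward rectifier / HCN current: deep hyperpolarization under strong
  anodic current is unopposed (harmless for spike statistics — the cell is
  silent there).
- The axon is strictly phasic: sustained DC without EPSCs yields only onset
  spikes, so "GVS-only" drive produces silence rather than low-CV tonic
  firing; both outcomes demonstrate that EPSC arrival is required for
  natural firing statistics.
- Single hair cell, single afferent; no efferent modulation, no
  morphology, no tissue-impedance frequency dependence.
- The electrode coupling scalar is preparation-specific and calibrated, not
  derived from field geometry.
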