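# Methods

`tcburst` simulates a thalamocortical spiking network in which perceptual
awareness is carried by dendrite-dependent burst firing of layer-5
pyramidal-tract (L5_PT) cells, gated by the matrix thalamus. This note
records the model equations, the parameter resolutions we had to make, the
numerical scheme, the calibration, and the known limitations — in that
order.

## Model

**Cells.** Three spiking cell classes follow Izhikevich adaptive quadratic
integrate-and-fire dynamics,

    C v' = k (v - v_r)(v - v_t) - u + I,   u' = a (b (v - v_r) - u),

with reset `v -> c, u -> u + d` at `v >= v_peak`: the somatic compartment of
90 L5_PT cells, 90 fast-spiking basket cells, and 10 matrix-thalamus relay
cells. Each L5_PT cell carries a second, apical-tuft compartment,

    C v' = -l (v - v_r) + g f(v) + m H(t - t_s) + u + I,
    u' = a (b (v - v_r) - u),   f(v) = 1 / (1 + exp(-(v + 38)/6)),

a phenomenological model of the dendritic Ca²⁺ plateau potential: the
regenerative nonlinearity `f` creates, at a saddle-node bifurcation
(I_B1 = 538.911 pA), a stable plateau state that becomes globally attracting
at a second saddle-node (I_B2 = 647.375 pA). `H` is a unit square pulse
(0.5 ms delay, 2 ms duration) marking a back-propagating action potential
(bAP) of amplitude m = 2600 pA; overlapping windows from burst spikes sum.

**Coupling.** Soma→tuft communication is gated by a saturating coupling
variable per cell, driven by that cell's thalamic partner's spikes
(`g' = -g/800ms + (1-g) Σδ`). It is the probability that (i) a somatic spike
back-propagates, and (ii) a plateau onset switches the somatic reset pair
from regular spiking (c=-65, d=250) to intrinsic bursting (c=-55, d=150).
One Bernoulli draw is made per plateau onset and holds for that plateau;
whenever the tuft falls back below -30 mV the soma reverts to RS. In the
noise-free probe mode both gates become deterministic thresholds at 0.5 so
the whole system is noiseless.

**Network.** Cortical cells sit at 90 equidistant sites on the unit circle
(2° of orientation preference per site, one lap = 180°). Weights are
Gaussians of chord distance, `w = λ exp(-d²/2σ²)`, with local excitation
(σ_EE = 0.5) and broad inhibition and E→I coupling (σ = 2): a Mexican-hat
that yields winner-take-all competition between opposite half-rings.
Synapses are conductance-based with single-exponential decay (AMPA/GABA_A
6 ms, NMDA 100 ms), the NMDA Mg²⁺ gate `((v+80)/60)² / (1 + ((v+80)/60)²)`,
and an 85 nS hard cap on individual NMDA conductances. Ten thalamic cells
wire 9:1 — each one integrates AMPA input (weight 4) from 9 contiguous L5
cells and projects back to the same cells' tufts (weights 10 AMPA + 10
NMDA). A slow adaptation conductance on each L5 soma (Δg = 0.065 nS per
spike, τ = 2 s, reversal -80 mV) destabilises dominance and drives
alternations.

**Drives.** Every L5 soma receives 600 Hz and every tuft 50 Hz of
independent Poisson input onto AMPA. The tactile stimulus is a 200 ms
current pulse (0–350 pA) with index-space Gaussian footprint
`exp(-((i-N)/20)²)`; rivalry is two independent per-cell Poisson drives
(1200–1800 Hz) with footprints `exp(-((i-N_{L,R})/18)²)` centred 45 sites
(90°) apart. Footprints use periodic index distance. Simulated optogenetic /
pharmacological perturbations add a constant current (±100…400 pA) to the
apical compartments or thalamic cells of one half-ring or the whole ring.

## Parameter resolutions

Four table/text ambiguities had to be resolved; all are exposed as arguments
so each resolution can be switched off:

1. **Basket recovery rate a = 0.15/ms** (not 0.01). The basket row is the
   canonical fast-spiking interneuron (C=20, k=1, v_r=-55, v_t=-40, b=8,
   c=-55, d=200, v_peak=25), whose published recovery rate is 0.15. With
   a = 0.01 the slow recovery variable caps basket firing near 30–60 Hz,
   which cannot silence a monocularly driven population: rivalry loses
   winner-take-all entirely. a = 0.15 restores the fast-spiking phenotype
   and alternation.
2. **Thalamic recovery sensitivity b = 15 nS** (not 0.01), the canonical
   thalamocortical relay value. It sets thalamic rheobase to ~150 pA so a
   single stray cortical spike does not fire the thalamus and saturate
   coupling; with it, all four dominant-state statistics (burst fraction,
   above-B1 fraction, coupling, distance-to-B1) fall inside the reported
   mean ± SD bands.
3. **Background scope.** The 600 Hz somatic background targets L5 somas
   (and 50 Hz the tufts) only. Driving baskets or thalamus with it produces
   tonic inhibition (silencing the baseline entirely) or tonically saturated
   coupling (removing the thalamic gate), respectively.
4. **Recurrent E→E target = soma** (basal dendrite). Routing recurrence to
   the tuft abolishes winner-take-all (`RunConfig.ee_target` switches this).

The apical recovery parameter prints as "130 ms⁻¹" and is implemented as a
130 ms time constant (a = 1/130 per ms); the regenerative nonlinearity is
the logistic with half-activation -38 mV and slope 6 mV, which reproduces
the tangency roots v* = -44.6601 / -31.3399 mV and both bifurcation
currents analytically.

**External-drive weight.** The unitary conductance jump per external Poisson
spike is not stated; it is the single calibration knob (`RunConfig.w_ext`).
It was set once to 3.0 nS as the joint operating point where (i) the
baseline is asynchronous-irregular (sparse localized bursts, ISI CV ≈ 1.9,
E/I conductance ratio ≈ 0.9), (ii) rivalry alternates with ~2 s dominance
epochs, and (iii) the dominant-population state statistics sit in their
reported bands.

## Numerics

Hybrid scheme at dt = 0.1 ms: conductances, coupling and adaptation decay by
their exact exponential factors and receive instantaneous jumps; membrane
equations advance by forward Euler; threshold crossings are clamp-and-reset
at step boundaries. Spikes emitted at step k reach conductances at step k+1;
no other delays. One seeded RNG stream with a fixed draw order inside the
compiled kernel makes runs bit-reproducible per (config, seed); runs abort
with a diagnostic if any |v| exceeds 500 mV (integration blow-up) or a spike
buffer overflows. State traces (regime flags, apical input current,
coupling) are recorded at 1 ms by default; halving dt changes a single
neuron's 1 s spike count by ≤ 2 spikes at constant drive.

"Apical input current" means the external terms of the tuft equation
(synaptic + bAP + perturbation), i.e. the bifurcation parameter against
which I_B1 is defined; leak, regenerative and recovery terms are part of the
vector field, not the input.

## Analysis conventions

* Population rates: 1 ms bins, 100 ms causal boxcar (results are stable for
  50–200 ms kernels), averaged over the 45-site half-ring masks.
* Dominance: one side's rate exceeds the other's by strictly more than 5 Hz
  for at least 250 ms; detection starts after a 1 s burn-in; periods touching
  the analysis-window edges are censored out of duration statistics but
  still count switches.
* Alternation rate: full perceptual cycles per minute (= side switches / 2).
  The raw switch rate is reported alongside. The cycles convention is the
  only one under which the published duration and rate figures are mutually
  consistent (~3 s epochs at matched drive ↔ ~10 cycles/min).
* Detection: whole-ring L5 spike count in the 1000 ms post-onset window;
  the optimal integer criterion minimises misses + false alarms across all
  intensities (ties break to the smallest criterion); perturbation arms
  reuse the control criterion. Neurometric curves use tie-aware ROC areas
  (Mann–Whitney U / n₁n₂) normalised to [0, 1] across conditions as
  (AUC - min)/(max - min).
* Distribution fits: Gamma and lognormal MLE with location fixed at zero,
  normal MLE; model comparison by mean per-sample negative log-likelihood.

## Problem sizes

Default experiment protocols use 30 s runs. The test suite and the
acceptance script use scaled-down seed counts chosen as the package's
standard quick-verification sizes: 10 seeds for the matched-drive (1400 Hz)
rivalry condition, 8 seeds for the 1350/1500 Hz Levelt conditions and the
1400/1250 Hz asymmetric condition, 4 seeds for the remaining grid points,
8 trials per intensity per detection arm, and 8 seeds per rivalry
perturbation arm.

## What the simulations do and do not establish

The synthetic drives emulate steady monocular gratings and whisker
deflections as stationary Poisson/current inputs; they contain no stimulus
dynamics, eye movements, or behavioural feedback, so passing tests speak to
the circuit mechanism, not to fits of any animal's trial-by-trial data.

Known quantitative limitations at the calibrated operating point:

* Dominance durations are too regular: pooled Gamma shape ≈ 9–11 versus the
  reported ≈ 4.85. Switching here is paced tightly by the deterministic
  adaptation cycle (noise-free probes oscillate with 2.3–3.5 s periods,
  matching the ~3 s scale), with too little stochastic spread.
* Duration sensitivity to drive is too weak: the ±7% monocular-rate range
  (1250–1500 Hz) moves mean durations by ~10%, not the ~2× needed for the
  reported 6.5 s / 7.75-cycles-per-minute extremes. The deterministic
  oscillator is release-limited (stronger drive stabilises dominance)
  rather than escape-limited at low drive, so the fourth-proposition trend
  is flat at the default weight and emerges only at stronger drive weights
  where everything alternates too fast.
* Symmetric apical excitation leaves the alternation rate flat instead of
  slowing it; all other perturbation orderings — including the degenerate
  mechanism signature (thalamic inhibition acting through coupling, apical
  inhibition through distance-to-bifurcation) — reproduce.

These three are left as failing checks rather than re-tuned, because every
attempted re-tuning that improved them pushed the dominant-state statistics
out of their reported bands.
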