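# Methods

`normnet` implements a two-layer spiking circuit model of visual cortex and
the analysis pipeline for studying how divisive normalization varies across
neurons, why, and what that heterogeneity buys the population code.  This
note records the model, its parameters and units, the numerical choices, and
the places where a design decision was genuinely open.

## Model overview

Two layers of neurons are arranged on uniform grids covering the rectangle
Γ = [0,2] × [0,1] (dimensionless cortical coordinates).

* **V1 (feedforward layer).**  5000 linear–nonlinear–Poisson neurons on a
  100×50 grid.  Neurons on the left half (x < 1) form population V1₁ with
  receptive fields centered on image location 1 at (0.5, 0.5); the right
  half forms V1₂ centered on (1.5, 0.5).  Each neuron filters its location's
  25×25-pixel image patch with a Gabor receptive field (envelope SD σ = 0.2,
  wavelength λ = 0.6, both in domain units) at the neuron's preferred
  orientation, half-rectifies the filtered value, and emits spikes as an
  inhomogeneous Poisson process.
* **V4/MT (recurrent layer).**  20 000 excitatory (E) and 5000 inhibitory
  (I) exponential integrate-and-fire neurons on 200×100 and 100×50 grids,
  recurrently coupled and driven by both V1 populations.

Preferred orientations come from pinwheel maps: the orientation at (x, y) is
half the complex argument of a superposition of n = 30 plane waves of
wavelength Λ = 0.125 with random binary propagation signs and uniform
phases.  The E and I grids sample one continuous V4/MT field; the V1 map is
generated independently.  A note on conventions: the orientation is taken as
arg(z)/2 wrapped to [0, π), i.e. orientation is half the phase of the
complex order parameter.  This is the standard convention for orientation
maps and is the one dimensionally consistent with the cos θ terms in the
Gabor filters; a normalization by 2π instead of 2 would compress
orientations into a quarter turn.

## Stimuli

Two Gabor images of orthogonal orientations (defaults 0 and π/2, contrast
0.5 each) are shown at the two locations, individually or together.  Images
are 25×25 pixels sampling a square patch of side 0.5 domain units
(≈ ±1.25 envelope SDs) centered on the image; the patch extent is a
configuration knob that is fixed before calibration and never revisited.
Every pixel carries independent Ornstein–Uhlenbeck noise
τₙ dξ = −ξ dt + σₙ dW with τₙ = 40 ms and σₙ = 3.5, giving stationary
per-pixel variance σₙ²/(2τₙ).  Superimposed ("plaid") stimuli are pixelwise
sums of two orthogonal Gabors at one center, without clipping; in the plaid
protocol each component (and the plaid) is presented at both image
locations so that both V1 populations stay driven.

For the manifold-capacity experiment the package generates a synthetic
stand-in for a natural-photograph collection: spectrally shaped Gaussian
noise with a 1/f² spatial power spectrum, rescaled per image to the Gabor
contrast range.  These images share the second-order statistics of natural
scenes (which is what the V1 filter bank sees) but none of their
higher-order structure; capacity results are therefore validated as
*properties* (ordering between network variants, agreement with a
brute-force separability oracle) rather than as absolute numbers tied to a
specific photo set.

## V1 calibration

The calibration constraints are: population-mean rate 10 Hz for a driven V1
population (image present at the reference contrast 0.5) and 5 Hz for an
undriven one (noise alone).  The filter model leaves two free scale factors
— a rate gain g (Hz per filter-response unit) and an effective noise scale
κ multiplying ξ — and both constraints are met jointly.  Using the closed
form for a rectified Gaussian, E[(μ + sZ)₊] = μΦ(μ/s) + sφ(μ/s), the ratio
driven/spontaneous is monotone in κ, so κ is found by 1-D root finding and
g follows from the spontaneous target.  Spontaneous activity is thus
entirely rectified noise, and the feedforward drive ratio between stimulus
conditions, ((10+5)+(5+10))/(10+10) = 1.5, anchors the mode of the
normalization-index distribution.

In simulation the OU field advances on a 2-ms clock with the exact OU
one-step update (rates held constant within each block, which is safe for
τₙ = 40 ms), and Poisson spikes are drawn by Bernoulli thinning per 0.05-ms
bin, implemented exactly via geometric skips.

## V4/MT neurons and synapses

EIF parameters (E / I): τ_m = 15 / 10 ms, E_L = −60 mV, V_T = −50 mV,
V_th = −10 mV, Δ_T = 2 / 0.5 mV, V_re = −65 mV, τ_ref = 1.5 / 0.5 ms.
Membrane equations are integrated by forward Euler with dt = 0.05 ms; when
the membrane is more than 20 Δ_T past V_T the exponential term would cross
threshold within a fraction of a step, so the spike is taken immediately
(this also makes the Δ_T → 0 limit reduce exactly to the LIF closed-form
rate).  On spiking, the membrane is clamped at V_th for the refractory
period and then reset (the alternative, clamping at V_re, is behaviorally
identical for all downstream statistics).  There are no transmission
delays.

Synapses are current-based normalized double exponentials,
η(t) = (e^{−t/τ_d} − e^{−t/τ_r})/(τ_d − τ_r), with τ_r/τ_d = 1/5 ms (E),
1/8 ms (I); feedforward synapses mix a fast (same as E) and a slow
(2/100 ms) component with weights 0.2/0.8.  Kernel states advance by exact
exponential updates (two auxiliary states per kernel).  Currents are
expressed as I/C_m in mV/ms, and each type (feedforward E, recurrent E,
recurrent I) is sampled every 10 ms.

## Connectivity

Synaptic weights (mV): J_ee = 80, J_ei = −240, J_ie = 40, J_ii = −300,
J_eF = 160, J_iF = 140, each scaled by 1/√N with N = N_e + N_i.  The √N
scaling is the balanced-network convention: it keeps single-synapse
amplitudes physiological (≈ 0.5 mV for E→E at full size) and the network in
the regime where O(√N)-strong excitation and inhibition cancel dynamically.
A 1/N scaling with these J values would give microvolt synapses and a
nearly silent network.

Mean connection probabilities p̄ and out-degrees K^out = p̄·N_target:
p̄_ee = 0.01 (K = 200), p̄_ei = 0.04 (800), p̄_ie = 0.03 (150), p̄_ii = 0.04
(200), p̄_eF = 0.05 (1000), p̄_iF = 0.05 (250) at full scale.  Each source
neuron draws exactly K^out targets with replacement (multiple contacts are
repeated edges).  85% of the draws are *local*: target offsets are sampled
from an isotropic Gaussian (σ_e = σ_i = 0.2 recurrent, σ_ffwd = 0.1
feedforward), wrapped on Γ, and mapped to the nearest grid neuron — this
sampling realizes the wrapped-Gaussian connection probability exactly up to
grid discretization.  For the two excitatory projections onto E neurons
(E→E and V1→E) the remaining 15% are *long-range*: drawn uniformly from
similarly tuned neurons, cos(θ_pre − θ_post) ≥ 0.6, independent of
distance.  The tuning similarity uses the plain cosine of the orientation
difference as the connection rule; an orientation-doubled convention
cos(2Δθ) is available as a configuration switch.  Inhibitory projections
and projections onto I neurons are purely spatial.

Variants:

* **Matched in-degree.**  Every neuron receives exactly the population-mean
  number of inputs of each type (p̄·N_source), drawn from the same
  spatial/tuning kernels with out-degrees free.  This removes the
  in-degree and current heterogeneity while preserving every other
  parameter.
* **Random (disordered).**  Erdős–Rényi connectivity with the same
  out-degrees; the two V1 source populations project to target sets
  sharing a configurable overlap fraction (1 = whole network, 0 = disjoint
  halves).

Desk scaling: a scale factor s shrinks every grid axis by √s (so population
sizes by ≈ s) and leaves p̄ and the J/√N rule untouched, which shrinks
out-degrees by s.  Defaults used in this repository: s = 0.25 for the
quantitative desk runs (5000 E, 1250 I, 1250 V1), s = 0.1 for the
directional comparisons, s ≈ 0.02–0.05 for test fixtures.  The balanced
residual current |⟨FF⟩+⟨rE⟩+⟨rI⟩| shrinks like 1/√N, so balance is looser
at desk scale than at full scale; all desk-scale acceptance checks are
calibrated to that reality (signs, orderings, and the scaled tolerances).

## Analyses

* **Firing rates** are means over the post-burn-in epoch (the first 1 s of
  every simulation is excluded everywhere).
* **Normalization index** NI = (FR₁ + FR₂)/FR_both per neuron; units with
  FR_both ≤ 0 are excluded.  The *current* NI applies the same ratio to the
  time-averaged signed current of one type; for inhibition the signs
  cancel, so the index is positive like the rate index.  Correlation
  analyses include units whose rate is within one population SD of the
  population mean in all three conditions.
* **Spike-count correlations**: Pearson correlations of counts in 200-ms
  windows stepped by 50 ms, pooled across simulations of a condition.  The
  overlapping windows autocorrelate successive samples; no decorrelation
  correction is applied (fidelity to the standard procedure is preferred
  over statistical nicety, and only means of r are consumed downstream).
  Binning conventions: NI heatmap bins of width 0.25 on [1, 3]; the
  r-vs-|ΔNI| curve uses pairs with mean NI within ±0.25 of 1.5; the
  r-vs-mean-NI curve uses pairs with |ΔNI| < 0.5; the tuning-similarity
  comparison contrasts |ΔNI| < 0.5 against |ΔNI| > 1 pairs in eight
  tuning-correlation bins.
* **Current covariance decomposition**: with E = feedforward + recurrent
  excitation and I = recurrent inhibition on the 10-ms cadence,
  Cov(T₁,T₂) = Cov(E₁,E₂) + Cov(E₁,I₂) + Cov(I₁,E₂) + Cov(I₁,I₂) holds as
  an identity; components are binned with NI₁ ∈ [1, 1.5] (partner NI
  varying) or |ΔNI| < 0.6 (similar pairs).
* **Contrast sensitivity**: conditions c₁ = 0.5 + Δc, c₂ = 0.5 − Δc; the
  spread (SD) of relative rate changes r/r₀ per (Δc, NI bin), where r₀ is
  the rate at Δc = 0; units with r₀ ≤ 0 are excluded.
* **Trial-based data conventions** (for external count matrices): trials
  where a unit's count is > 3 SD from its per-condition mean are flagged
  (an SD of zero makes any deviation deviant); units must pass a
  blank-vs-driven two-sample t-test at p < 0.01; same-electrode pairs are
  excluded when electrode ids are provided.

## Linear Fisher information

Trials follow the ON/OFF protocol: stimulus 1 constant; stimulus 2 present
during 200-ms ON windows separated by 300-ms OFF intervals, its contrast
(0.5 ± 0.005) or orientation (π/2 ± 0.01 rad) randomized per ON interval
with balanced labels; during OFF, V1₂ fires as independent Poisson at 5 Hz.
Counts are from excitatory V4/MT units in the ON windows; the first count
of each simulation is dropped; connectivity is fixed across simulations
while membrane initial conditions are re-randomized.

The bias-corrected estimator is

  Î_bc = d′ᵀ[(Q₁+Q₂)/2]⁻¹ d′ · (2N_tr − N − 3)/(2N_tr − 2) − 2N/(N_tr δx²),

valid when 2N_tr − 2 > N + 1.  A ridge of 1e−6·trace/N is added only when
the pooled covariance is numerically singular, and is always reported.
Information per spike divides Î_bc by the mean total count of the sampled
group; group sizes are log-spaced and the number of random samplings per
size falls from 200 to 14 proportionally to log N up to N = 545 and is 5
beyond.  Saturation is summarized by ordinary least squares of 1/I_N on
1/N; I_∞ is the reciprocal intercept, reported as ∞ when the intercept is
non-positive (information not saturating).

The V1 input information is computed analytically from the filter model:
counts are linear in the integrated pixel noise, whose variance over a
window T is Var(ξ_T) = σₙ²[T − τₙ(1 − e^{−T/τₙ})] (the unique grouping with
the correct σₙ²T large-T asymptotics, verified against brute-force OU
integration), plus independent Poisson variance with the rectified-Gaussian
mean rate on the diagonal.  Neurons whose noise-free response rectifies to
zero carry no signal derivative.  This bound is network-independent and
upper-bounds any information measured from V4/MT counts.

## Manifold capacity

Each manifold is the set of excitatory population responses (100-ms counts)
to one image across trials, with M = 0.2·N trials for N sampled units.
After global mean subtraction, each manifold is embedded in the affine span
of its own trials (center = trial mean; coordinates = SVD basis of the
centered trials, scaled by the center norm, with the center direction as a
constant extra coordinate).  For each Gaussian sample (t⃗, t₀) the anchor
point solves min ‖v − t‖² subject to v·s ≤ −κ over the manifold points —
solved in dual form as a nonnegative least-squares problem (Cholesky of the
Gram matrix + NNLS; interior samples take the touching point as anchor).
Capacity is the reciprocal of ⟨‖v − t‖²⟩ averaged over n_t = 200 Gaussian
samples (shared across manifolds for variance reduction) and combined over
manifolds by the inverse mean; dimension is D_M = ⟨(t⃗·ŝ)²⟩ and radius
R_M = √⟨‖s̃‖²⟩ using the coordinates relative to the center norm.  The
squared form of D_M is used (the unsquared average is inconsistent with the
ball-manifold calibration D_M ≈ D, which this implementation verifies); a
deterministic sign convention on the SVD coordinates makes all three
quantities exactly invariant under global rotations of response space.  The
test suite ships a brute-force oracle — random ±1 dichotomies with linear
program feasibility, bisected over the number of manifolds — which the
mean-field capacity matches within 10% at the Cover limit and within 20%
for Gaussian-blob ensembles.

## Problem sizes and reproducibility

Quantitative desk runs use scale 0.25 with 2–3 simulations of 10–20 s per
condition; the directional comparisons use scale 0.1 with proportionally
smaller protocols (tuning curves from 4-s runs, Fisher trials from 4×20-s
runs, capacity from 12 synthetic images × 32 trials).  These sizes were
chosen once as the smallest at which the studied effects are comfortably
resolved.  Every random element derives from one root seed through named
child seeds (maps, connectivity, stimuli/noise, initial conditions, spike
generation), so identical configurations are bit-reproducible and
individual stages can be re-randomized independently.

## Known limitations

* Desk-scale statistics are attenuated versions of full-scale ones: finite
  simulation time adds estimation noise to per-neuron indices, which
  weakens index–index correlations (most visibly the inhibitory-current
  correlation), and looser balance at small N raises mean rates somewhat.
* Scaling down also *shifts* one class of statistics: out-degrees shrink
  with s, so the stimulus-invariant part of NI heterogeneity contributed by
  in-degree variability (CV ∝ 1/√K) grows relative to the
  stimulus-specific part.  Quantities that measure stimulus specificity of
  normalization — e.g. the correlation of NI across stimulus rotations —
  are therefore systematically higher at desk scale than at full scale.
* The analytic V1 bound linearizes around the rectified operating point;
  it slightly overstates the information carried by neurons operating near
  the rectification threshold.
* The natural-image stand-ins share only second-order statistics with real
  photographs; absolute capacity values are not comparable with ones
  computed on a specific photo collection, although variant orderings are.
* One E and one I class, no transmission delays, no plasticity, no
  conductance-based synapses; attention-related modulations are out of
  scope.
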