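# Methods

This note documents the models, statistics and numerical choices behind
`thetaseq`, in the order data flows through the package.

## Scientific setting

During sequence working memory, medial-temporal-lobe neurons lock their
spiking to theta-band (2–8 Hz) oscillations of the local field
potential (LFP), and the *phase* at which a neuron fires can depend on
the position its preferred stimulus (PS) occupied in the remembered
sequence, even when delay firing *rates* carry no position information.
The package provides the full analysis chain for this phenomenon —
phase extraction, a circular variance-explained statistic with
permutation inference, phase-order classification, position decoding —
together with a synthetic session generator that plants the effect at
known strength, and a rate recurrent network model whose stimulus-evoked
phase resets predict which phase orders should occur.

## Synthetic sessions (`thetaseq.synthetic`)

The generator emulates a modified Sternberg task: per trial, 4 of 8
stimuli are presented at a 400 ms stimulus onset asynchrony (SOA; 200 ms
on-screen), followed by a delay drawn uniformly from 2.5 ± 0.1 s, then a
probe. In balanced mode every stimulus occupies every position equally
often (with 224 trials: 28 per stimulus × position), implemented by
column-balanced sampling with random row repair.

The LFP is a 1/f background (spectral exponent 1, unit variance) plus a
theta tone (default 2.8 Hz, amplitude 1) whose amplitude is multiplied
by `delay_power_boost` (default 3) during the delay, with 100 ms cosine
ramps to limit spectral splatter. The tone's phase is drawn per trial
and recorded as ground truth.

Spikes are inhomogeneous Poisson (Bernoulli thinning on the 1 ms grid)
with rate

    r(t) = r_base · g_stim(t) · exp(κ_pos cos(θ(t) − μ_pos)) / I0(κ_pos)

during the delay of PS trials. The I0 normalization makes the mean rate
independent of κ, deliberately decoupling rate coding from phase coding
so that a positive phase result can never be a rate artifact. During
encoding, g_stim applies an evoked gain at the preferred stimulus scaled
by a primacy gradient (1.0, 0.85, 0.7, 0.55 for positions 1–4; other
stimuli receive 20% of the gain). Ordering modes set the per-position
preferred phases μ_pos: `forward` / `reverse` (60° steps by default),
`arbitrary` (random permutation of the same phase set), or
`reset_model`, where μ_pos follows the phase-reset prediction below.
When the PS is absent (NPS trials) locking uses a weaker κ (default 0.5)
at the unit's mean phase; the paper does not state this magnitude, so it
is an explicit free parameter.

What the generator does **not** emulate: epileptic artifacts, electrode
drift, spike-sorting errors, bursting, cross-frequency coupling, or
between-unit rate heterogeneity beyond the configured parameters.
Passing tests therefore demonstrate correctness of the analysis chain
under the planted model, not robustness to every pathology of human
microwire data.

All randomness derives from a single session seed split into named
substreams (ground truth, trials, LFP, spikes), so each component is
independently reproducible. Sessions round-trip through HDF5 bit-
identically; trial tables export to CSV and configs to YAML.

## Spectral analysis (`thetaseq.spectral`)

Time–frequency decomposition uses complex Morlet wavelets with c = 7
cycles (σ_t = c / 2πf, truncated at ±3.5 σ_t) on the log-spaced grid
1.5, 1.75, 2.03, 2.37, 2.8, 3.2, 3.7, 4.4, 5.1, 5.9, 6.9, 8 Hz, at
1 kHz sampling. Kernels are scaled so a unit-amplitude tone yields
coefficients of magnitude ≈ 1. Conventions fixed here because the
analysis needs *some* choice:

* **Phase:** 0 at the cosine peak, increasing with time, in [0, 2π).
  All modules share it.
* **Edges:** reflect padding plus a per-frequency validity mask (half a
  wavelet support at each end); spikes on invalid samples are excluded
  and counted rather than silently phase-labelled.
* **Spike phase:** nearest-sample lookup. At 1 kHz and ≤ 8 Hz the
  worst-case phase error is 2π·8·0.0005 < 1.5°, so interpolation would
  add complexity without precision.

Power is z-scored per frequency against a 1 s pre-stimulus baseline;
delay spectra average the last 1.5 s before probe onset, and the delay
window for spike phases is the last 2 s before the probe. With short
baselines the per-trial z statistic is heavy-tailed (few independent
power samples per theta cycle), so summaries across trials use medians.

## Circular statistics (`thetaseq.circular`)

Per-trial mean phase is the circular mean of delay spike phases;
zero-spike trials contribute nothing. For trials grouped by the PS
position j, the circular variance explained is

    V_j^w = 1 − |(1/N_j) Σ_k e^{iθ_k}|        (within condition j)
    V^w   = (1/N) Σ_j N_j V_j^w               (trial-count weighted)
    V^a   = 1 − |(1/N) Σ_k e^{iθ_k}|          (across all trials)
    V_ex  = 1 − V^w / V^a.

Inference shuffles condition labels (default 1,999 permutations; the
null is computed vectorized over permutations) with the add-one
p-value p = (1 + #{null ≥ observed}) / (1 + N). A unit counts as
phase-coding when p < 0.05 at two or more grid frequencies. Proportions
get percentile bootstrap CIs (1,999 resamples); families of p-values can
be corrected with the Simes step-up rule; effect sizes use Hedges' g.
V_ex is undefined when all phases coincide (V^a = 0) and this raises
rather than returning a sentinel. V_ex has a small positive
finite-sample bias under the null — this is why inference is
permutation-based rather than threshold-based.

Von Mises fits are maximum likelihood: μ is the circular mean and κ
inverts A(κ) = I1/I0 = R by the Best–Fisher piecewise approximation plus
Newton refinement, capped at κ = 10³ (flagged) when R → 1. A binned
variant (20 bins by default; the bin count is unstated in the source
literature) is offered for histogram-style fits. Rayleigh's test uses
the standard Z = nR² statistic with the Zar approximation for p, falling
back to a Monte-Carlo null below n = 5.

A rate-matched subsampling control equalizes spike counts between
conditions by randomly subsampling the larger sample, with a
repeated-draw interface for averaging; the original control procedure is
not fully described in the source literature, so this is a documented
stand-in.

## Phase order and the reset model (`thetaseq.order`)

Per-position mean phases are anchored by subtracting their circular
mean, then sorted counter-clockwise; the resulting permutation of
positions is classified up to rotation (1,2,3,4 ≡ 4,1,2,3 ≡ 3,4,1,2 ≡
2,3,4,1). Four positions give 24/4 = 6 rotation classes; `forward` is
the class of (1,2,3,4), `reverse` of (4,3,2,1), `other` the complement.
Chance levels are computed by exhaustive enumeration, never hard-coded:
forward 1/6, reverse 1/6, other 4/6 under the mutually exclusive
partition. Because a commonly quoted triple (1/6, 1/6, 5/6) sums to more
than 1, the complementary reading "not forward" = 5/6 is also reported;
neither is asserted as the only reading. Exact phase ties break toward
the lower position index and are flagged. When the across-position
resultant vanishes (perfectly symmetric patterns) anchoring is
undefined; classification then proceeds on the unanchored pattern, which
is safe because the rotation class is invariant to the anchoring
rotation.

If each stimulus resets its unit's oscillation to a fixed phase, the
phase of position k (0-based) relative to a free-running reference at
f_osc is

    φ_k = φ0 + 2π · f_osc · k · SOA  (mod 2π),

so the predicted rotation class depends only on the fractional part of
f_osc · SOA. Integer f_osc · SOA collapses all positions onto one phase
(degenerate, flagged). A fractional advance below 1/4 cycle always
predicts the forward class. For empirical tests φ0 defaults to the
reference phase at first-stimulus onset. Prediction–observation match
rates are tested against a null that shuffles the (frequency, SOA)
assignment across units.

## Decoding (`thetaseq.decoding`)

Position is decoded from per-trial mean phases with an RBF-kernel SVM
(one-vs-one, 4 classes, chance 25%). Angles are embedded as (cos θ,
sin θ) before the kernel — raw angles would tear the topology at the
wrap-around. Accuracy is the mean over repeated stratified 85/15
train/test splits; significance uses a label-shuffle null (101 shuffles
by default; 199 for rate controls) with add-one rank p-values. The RBF
scale is set from the median pairwise training distance and C = 1, for
determinism given the seed; no inner hyperparameter search. Held-out
sets are sized at least one trial per class so stratification is
well-defined at small n. Pseudo-populations pool non-simultaneous units
by resampling trials without replacement within class and concatenating
features; the per-class pseudo-trial count is the minimum across
contributing units, and units lacking two trials in any class are
dropped with a log entry. `PhasePositionDecoder` follows the
scikit-learn estimator contract and composes with sklearn model
selection.

## Rate RNN (`thetaseq.rnn`)

Dynamics (Euler, step Δt, α_i = Δt/τ_i):

    x[n+1] = (1−α)∘x[n] + α∘(J φ(x[n]) + I u[n]) + √(2α σ_ξ²)∘ε[n],

with linear readout y = wᵀx and LFP proxy LFP[n] = Σ_ij |J_ij| φ(x_j[n])
(summed absolute synaptic input; nonnegative since φ ≥ 0). The task
mirrors the human one: 4 of 8 input channels pulse for 0.2 s at the SOA,
a delay follows, the same four stimuli return in matched or shuffled
order (±1 target during a decision window after the probe; evaluation
sets use unique sequence combinations with exactly half matches, 224 by
default). The loss is the mask-normalized squared readout error plus
λ_FR · mean(φ²) and λ_osc · reg_osc, where

    reg_osc = −‖(1/T) Σ_n LFPbar[n] e^{−i2π f_osc n Δt}‖,

computed on the amplitude-normalized LFP, LFPbar = (LFP − μ)/(√2 σ). On
a pure integer-cycle sinusoid at f_osc this equals exactly −0.5, its
minimum. For *reporting* oscillation strength we use the spectrum of the
std-normalized LFP, (LFP − μ)/σ, whose component amplitude at f_osc is
√2 times the regularizer magnitude and reaches 1/√2 ≈ 0.707 for a pure
sinusoid; trained-model amplitudes are therefore directly comparable to
values near 0.7 for strongly oscillatory solutions.

**Training shaping.** The order match/non-match decision is an
XOR-type computation over item–position bindings: no linear feature of
the decision-period state separates match from non-match, and an
untrained network carries no sample memory into the probe period (the
passive trace decays within the delay), so the plain loss sits on a
long plateau — memory is only useful once the comparison exists, and
the comparison can only form once memory exists. Training therefore
supports two optional shaping aids, both pure training-procedure
devices that are switched off (and, for the auxiliary readouts,
discarded) at evaluation time:

* an **auxiliary memory loss** (`lam_aux`): 32 extra linear readouts are
  trained to report which stimulus occupied each sequence position
  (4 × 8 one-hot targets) from delay onset onward, forcing an
  order-bound memory of the sample to persist into the probe period;
  the weight starts high and anneals down once the main loss engages,
* a **probe curriculum** (`set_mismatch_frac`): a fraction of early
  non-match trials swap one probe item for an absent stimulus, giving an
  item-identity mismatch signal before the harder order-only mismatch.

Validation accuracy is always measured on the unmodified task with the
main readout only.

Choices the source literature leaves open, fixed here as config with
defaults: activation φ = rectified tanh (nonnegative, saturating, so
the rate penalty has something to push against); Dale's law enforced by
sign-projecting columns of J after every optimizer step (80% excitatory;
inhibitory columns scaled at initialization for E/I balance, J rescaled
to spectral radius 1.5); per-unit time constants log-uniform on
50–700 ms; Δt = 20 ms; σ_ξ = 0.02; readout from rates (y = wᵀφ(x));
Adam with global-norm gradient clipping, float32 arithmetic; accuracy
= sign of the mask-averaged readout. Gradients are derived analytically
and backpropagated through time, including through the LFP
normalization inside reg_osc; they are validated against finite
differences in the test suite. Training stops at 95% validation
accuracy or the iteration budget.

The heterogeneous time constants are load-bearing, not cosmetic: with
uniform 100 ms units the network learns the delay memory and the
comparison of the *final* probe item, but mismatches detected early in
the probe are not retained to the decision window and accuracy ceilings
near 85–90%. Units with multi-hundred-millisecond time constants
provide a substrate on which detected-mismatch signals persist through
the remaining probe items, and with them the same training recipe
reaches criterion within a few thousand iterations. The hard-negative
oversampling targets exactly that failure class (non-matches whose
final item is unchanged).

Model phase analysis mirrors the empirical chain: stimulus-responsive
units by one-sided Wilcoxon signed-rank (baseline vs stimulus period,
p < 0.001), preferred stimulus by maximal evoked rate; the reference
oscillation is a sinusoid at the LFP spectral peak with phase 0 at the
last stimulus onset; per-trial phases are rate-weighted circular means
over delay samples whose rate exceeds the unit's 50th percentile.
Model-inclusion criteria follow the 0.5 Hz (LFP peak vs regularization
frequency) and 0.2 Hz (V_ex frequency) rules.

## Problem sizes in the shipped tests

The test suite and acceptance script run everything at desk scale, as
the package's own standard configuration for verification: sessions of
32–224 trials with up to 30 units; 199–1,999 label permutations (the
499-permutation setting is checked for agreement against 1,999 on
shared data); 101 decoding shuffles; Monte-Carlo enumeration checks at
10⁶ draws; and a single scaled-down network (N = 100, Δt = 20 ms,
1.5 s delay) for the training-to-criterion check. Larger replications
(e.g. 40 models across four regularization frequencies) are available
through the CLI `sweep` command.

## Known limitations

* The generator's phase-locking is stationary within the delay; real
  locking strength drifts within and across trials.
* The reset-model φ0 estimator for empirical data is one documented
  choice among several defensible ones.
* The RNN hyperparameters are not tuned to reproduce any particular
  published network; only the qualitative mechanism (oscillation at the
  regularized frequency, stimulus-locked phase resets, SOA × frequency
  dependence of phase order) is claimed.
* Rate-matched subsampling is a plausible stand-in for an incompletely
  specified control.
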