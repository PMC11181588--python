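# Methods

This note documents the modelling and numerical choices behind the package:
what each stage computes, which parameters matter, how the synthetic data
are constructed, and what the tests do and do not establish.

## Wavelet coherence

The connectivity estimator is the classic smoothed-wavelet-spectrum
construction.  Each channel is transformed with a complex Morlet wavelet
(ω₀ = 6, implemented as PyWavelets' `cmor` with bandwidth 2.0 and center
frequency 6/2π), on a logarithmic frequency grid (default 24 voices over
0.5–30 Hz).  Cross- and auto-spectra are smoothed and the coherence ratio

WC = |⟨W_x W_y*⟩| / (⟨|W_x|²⟩ ⟨|W_y|²⟩)^{1/2}

is clipped to [0, 1].  Without smoothing the ratio is identically 1, so the
smoothing operator *is* the estimator's resolution/variance trade-off.

**Smoothing.**  Two-way smoothing, as in the standard practice for wavelet
coherence: a frequency-dependent moving sum over the time window
θ(f) = c/f with **c = 30 cycles**, plus a boxcar across **0.75 octave** of
adjacent voices.  The spans were calibrated against the closed-form oracle
for two signals sharing a band-limited source with independent equal-power
noises, whose magnitude coherence is snr/(1+snr): at SNR = 1 the estimator
returns 0.512 ± 0.073 over 50 eight-second draws (oracle: 0.5), and for
independent signals the floor is ≈ 0.26 at 8 s.  Narrower smoothing biases
the estimate upward sharply (with c = 5 and time-only smoothing the SNR = 1
estimate is ≈ 0.69) because a short record holds only ~10 independent
wavelet coefficients per voice; this is why the defaults are deliberately
wide.  Setting `scale_smoothing_octaves=0` and a tiny `smoothing_cycles`
reproduces the degenerate single-sample window, which the code detects and
warns about (coherence ≡ 1).

**Noise floor.**  Finite-window coherence of independent signals is not
zero; the floor falls roughly as (record length)^{-1/2} and is ≈ 0.35 at
4 s, ≈ 0.26 at 8 s for theta-band records with the default smoothing.  All
quantitative uses of per-epoch coherence in the package treat values near
the floor as non-edges: `screen_noise_floor` estimates the floor robustly
from the off-diagonal entries themselves (median + 2 MAD) and zeroes
everything at or below it.  This is the same idea as screening group-mean
connectivity at an absolute 0.6 — an absolute cut is only meaningful for
one particular record length and smoothing, so the package uses the
adaptive form.

**Scalarization.**  A channel pair's connectivity is the mean of the
coherence map over all times and all analysis frequencies in the requested
band.  One matrix per epoch is the atomic unit; group averages are used for
statistics and for the training graph (below).

## Graph operators

From symmetric nonnegative weights W (zero diagonal): degree vector
D, normalized Laplacian L = I − D^{-1/2}WD^{-1/2} (spectrum in [0, 2]),
Chebyshev filtering via the T_k recurrence on L̃ = 2L/λ_max − I (λ_max
exact in the oracle path, ≈ 2 in the fast path), and the renormalized
first-order operator P = D̃^{-1/2}(W+I)D̃^{-1/2}, a symmetric contraction
(spectral radius ≤ 1) that is well-defined for isolated nodes thanks to the
self-loop.  The recurrence path is verified against an explicit
eigendecomposition oracle to 1e-8 relative error; coherence weights are
used as-is (no binarization) once past the noise-floor screen.

## The network

Feature maps are (batch, nodes, time, features).  Each ST-Conv block is

1. causal temporal convolution (left-padded; the same kernel bank for every
   node) with ReLU,
2. spatial graph convolution P X Θ per time step with ReLU,
3. channel attention: σ(MLP(avg-pool) + MLP(max-pool)) per feature, pooling
   over nodes × time; the printed form of the attention equation wraps only
   the average branch in σ, but the accompanying text describes element-wise
   summation of the two MLP outputs before the gate, which is the
   established convention and what is implemented,
4. a second causal temporal convolution, then layer normalization,

wrapped in an additive residual shortcut (1×1 projection when feature
counts differ, subsampled when the block strides time).  The classifier
head averages each block's output over time, flattens nodes × features, and
integrates all blocks' flatten layers linearly into class logits.

Ablations: TRCN replaces the graph stage with identity; SRGCN replaces both
temporal stages with identity.

**Defaults and why.**  Temporal kernels (8, 8, 4, 2) with strides
(4, 4, 2, 2) — per-depth kernel/step schedules are part of the temporal
design, and the stride pyramid matters here: the class-discriminative
signal in connectivity data is a *temporal statistic* (rectified amplitude
of graph-mixed signals), so the head must see time-aggregated features;
classification quality is otherwise insensitive to these hyper-parameters.
Block feature sizes (1→8→8→8), (8→8→8→8) and attention reduction 4 keep the
model at ~2.5 k parameters, appropriate for datasets of a few hundred
epochs.  Layer normalization is applied per sample over all non-batch axes:
normalizing each position across features alone would cancel the node-
amplitude differences that carry the connectivity signal (the activations
are nearly rank-one across features).  For the same reason the attention
MLP's output layer starts at zero — gates begin neutral at σ(0) = 0.5 — and
the shortcut projection starts at 0.1 scale, so an untrained model passes
the graph-conv signal through undistorted.  These initialization choices
were found by probing untrained feature maps with a linear readout: random
attention gates and a full-scale raw-signal shortcut each destroy the
class signal before training can use it.

**Training graph.**  By default the model uses one propagation operator per
training run, built from the *training fold's* mean connectivity after
noise-floor screening (label-blind, so no leakage into test folds).  A
shared graph lets the spatial convolution read each epoch's cross-channel
correlation directly: the variance of Σ_j P_ij x_j varies with the epoch's
inter-channel correlation under a fixed mixing pattern.  With per-epoch
graphs (available via `graph_mode="per-epoch"`), weakly-coupled epochs get
near-identity operators, no mixing happens, and the signal is structurally
invisible to the forward pass — a linear probe of the features drops from
perfect separation to chance.  Whether the original protocol built graphs
per epoch, per subject, or per group is not documented; the shared-graph
reading is the one under which the architecture functions as intended.

**Causality.**  The temporal convolutions are strictly causal (verified by
perturbation: changing the input after t never changes outputs before t),
and the graph stage is per-time-step.  The attention gate and layer
normalization pool over the whole window, so the model as a whole is
causal only up to those stages; this mirrors the architecture as described.

## Training and evaluation

Adam (lr 1e-3, β = 0.9/0.999) with decoupled-style weight decay 1e-3,
batch size 32 (16 in the experiments here), cross-entropy loss; none of
these were documented in the source protocol.  Early stopping holds out a
stratified 10% validation split inside each training fold, stops after
`patience` epochs without validation-loss improvement (default 10), and
restores the best-validation weights.  Metrics are computed from confusion
counts at argmax, reported as percentages rounded to two decimals; ROC
points come from threshold sweeps on the positive-class (SZ) probability
and AUC by trapezoidal integration (scikit-learn).  Cross-validation is
stratified by class; subject-grouped folds are available when epochs carry
subject identifiers, and are the right choice for real data (epoch-level
splitting of overlapping windows leaks information across folds).

## Synthetic data

Each epoch mixes unit-variance band-limited Gaussian sources: a coupled
pair (i, j) with strength ρ shares a source s_ij via
x_i = √ρ s_ij + √(1−ρ) n_i, so the pair's in-band coherence approaches ρ,
scaled down by a pink (1/f) background whose power is 1/snr of the
foreground (default snr = 4).  Sources are filtered noise, not sinusoids,
so coherence is frequency-localized and the estimator is genuinely
exercised.  Defaults: 19 channels (10–20 montage), 256 Hz, 4-second epochs
— the shortest window at which per-epoch coherence separates designed
edges (≈ 0.57) from the estimator floor (≈ 0.42) — theta-band sources, and
two classes that differ only in coupling: four disjoint fronto-central/
temporal pairs (Fp1–F3, Fp2–F4, Fz–Cz, F7–T7) at 0.9 in the control-like
class vs 0.2 in the patient-like class, emulating the reduced
fronto-central connectivity reported for schizophrenia.  Channel-wise
marginal statistics are identical between classes by construction, so a
classifier can only succeed through inter-channel structure — passing the
pipeline test demonstrates connectivity-based classification, not spectral
shortcuts.

What the generator does *not* emulate: volume conduction and reference
effects (which inflate zero-lag coherence between neighbors on real EEG),
artifacts, non-stationarity within epochs, subject-level variability, and
realistic 1/f exponents per channel.  Accuracy numbers on this generator
are therefore an upper bound on what the same pipeline would achieve on
clinical recordings; the published clinical accuracies depend on data this
package does not ship.

## Problem sizes

The experiments are sized for a single CPU: recordings are decimated to a
128 Hz working rate before connectivity and model work (the band of
interest ends at 30 Hz), the full-pipeline test runs 100 epochs per class
with tenfold CV and 30 training epochs per fold, and the acceptance script
runs 60 epochs per class with 5 folds.  Monte-Carlo calibrations use 50
seeded draws of 8-second records.

## Known limitations

- Attention pools over nodes and time jointly; a time-only pooling variant
  is not implemented.
- The EDF reader takes the channel labels as stored; montage matching
  beyond case-insensitive name lookup (e.g. `T7` vs `T3` aliasing) is the
  caller's responsibility.
- The coherence estimator includes cone-of-influence edge samples in band
  means (a mask is not currently exported); with the wide default
  smoothing, edge effects are part of the calibrated floor.
- `run_cv_experiment` retrains from scratch per fold; there is no warm
  starting or hyper-parameter search.
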