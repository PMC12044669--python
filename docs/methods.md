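# Methods

## The problem and the modeling assumptions

Resting-state EEG of depressed patients shows altered band-power
structure — most prominently elevated alpha (8–13 Hz) and theta (4–8 Hz)
power. The package treats healthy-vs-MDD screening as binary epoch
classification: each 5-second window of a 19-channel recording is one
sample, labeled with its subject's diagnosis (0 healthy, 1 MDD). This
assumes the discriminative signal is stationary enough to appear in short
windows and is carried by amplitude statistics rather than fine temporal
structure.

## Synthetic cohort generator

No clinical recordings ship with the package; the generator emulates the
statistical structure the pipeline exploits.

Per channel, the signal is a sum of one sinusoid per canonical band —
frequency drawn uniformly inside the band (kept min(0.5 Hz, 10% of the
band width) clear of the edges so finite-window spectral leakage cannot
push the tone's peak into a neighbor band), uniform phase, amplitude fixed
by the subject's class — plus pink (1/f-power) noise, plus optional
0.5-s raised-cosine blink bumps on the frontal channels (Fp1, Fp2, F7, F8)
arriving as a Poisson process.

Default condition (microvolts, healthy / MDD):

| band  | healthy | MDD  |
|-------|---------|------|
| delta | 10      | 10   |
| theta | 6       | 9    |
| alpha | 8       | 16   |
| beta  | 4       | 4    |
| gamma | 1.5     | 1.5  |

with pink-noise RMS 5 µV and blink rate 0/min. The MDD profile doubles
alpha and raises theta by half; the absolute scales are typical resting
scalp amplitudes. Cohort defaults are 30 healthy and 33 MDD subjects at
256 Hz. Each subject's random stream is derived by SHA-256 hashing of the
subject id under the cohort seed, so enlarging a cohort never changes
existing subjects' data.

What the generator does **not** emulate: inter-subject amplitude
variability within a class (each class has exactly one amplitude profile),
nonstationarity, volume-conduction correlation between channels, EMG/ECG
artifacts, and eyes-open/eyes-closed differences. The classes are
therefore separable essentially by per-channel variance, and classifiers
reach near-perfect held-out accuracy on the defaults. Passing the
end-to-end tests consequently demonstrates that the pipeline *recovers a
band-power class effect when one exists* — a correctness property of the
machinery, not a claim about clinical effect sizes.

Recording length is exposed (`duration_s`, default 300 s); tests and the
acceptance script use 60-s recordings (14 epochs/subject), which keeps the
full 63-subject pipeline under a minute while leaving hundreds of epochs
for the classifiers.

## Preprocessing

* **Filter.** The default is the literal ideal mask: rFFT per channel,
  zero every bin outside the closed passband [0.5, 60] Hz, inverse rFFT.
  It is exactly idempotent and annihilates out-of-band tones to numerical
  precision, but rings on transients; a zero-phase windowed-sinc FIR
  (`filtfilt`, default 513 taps) is the practical alternative.
* **Epochs.** Half-open windows [start, start + τ) at starts 0, Δ, 2Δ, …
  while start + τ fits, so every epoch has exactly round(τ·fs) samples and
  the count is ⌊(T − τ)/Δ⌋ + 1. A closed interval would duplicate one
  boundary sample between the window arithmetic and the sample count.
* **Features.** σ uses the population divisor N. Skewness and kurtosis
  are the plain standardized moments (kurtosis not excess-adjusted);
  channels with σ = 0 report 0 for both, avoiding 0/0. Feature layout is
  channel-major: 19 channels × (mean, std, ptp, rms, skew, kurt).
* **Band power** integrates a Welch PSD (4-s Hann segments) over half-open
  bands by the rectangle rule, so a disjoint band partition sums to the
  total power.

## Encoders

Both deep models run on the in-package NumPy module library (`nn.py`)
with hand-written backward passes — required because split learning
exchanges dL/dz explicitly at the cut layer. Every backward pass is
finite-difference checked in the test suite.

* **Transformer.** Each epoch's 114 features become 19 tokens (one per
  channel, 6 descriptors). Tokens are linearly embedded to d_model = 32,
  summed with *learned* positional encodings over the channel index, pass
  through 2 post-norm encoder blocks (4-head self-attention,
  d_k = 8, feed-forward width 64, residuals + layer norm), and are
  mean-pooled. Channels-as-tokens lets attention model inter-channel
  dependencies; with positional encodings zeroed the latent is provably
  permutation-invariant over channels (tested), so the learned encodings
  are what gives electrodes an identity. Supervision is a temporary
  softmax head trained with cross-entropy by Adam (lr 1e-3, batch 64, 30
  epochs by default) and discarded; features are z-scored with statistics
  from the fitted data only.
* **Autoencoder.** MLP 114 → 64 → 16 → 64 → 114 (ReLU), minimizing the
  per-sample squared reconstruction norm by Adam. With the linear
  configuration its optimum is the best rank-d reconstruction, which the
  tests verify against a truncated SVD.

Model sizes are small on purpose: the feature space is 114-dimensional
and desk-scale; all sizes are constructor parameters.

## Hybrid and voting

The hybrid freezes the fitted encoder and grid-searches a classical head
on the latents (default: random forest, the strongest pairing). Prediction
is exactly head∘encoder — asserted as an invariant. The generic bagging
combiner takes the per-sample modal label; 0/1 ties resolve to label 0,
a deterministic documented rule (consequence: a majority of margin one
*can* be flipped into a tie by duplicating a minority voter — the tests
pin down exactly which duplicate-member properties hold).

## Split learning

Design choices where the protocol is genuinely open:

* **Two-phase training.** A gradient loop cannot train a random-forest
  head. Phase A uses a differentiable softmax head on the server for the
  activation/gradient exchange; Phase B freezes every client encoder and
  refits a random forest on pooled latents. Inference uses the forest.
* **Label sharing.** The server computes the loss, so labels ride in the
  activation packet. The privacy contract covers raw signals and features
  only: the packet schema has exactly (client_id, z, labels, batch_index),
  and the audit asserts both the schema and that the payload width equals
  the latent size (32), never the 114-feature width.
* **Scheduling.** Sequential round-robin over clients, one batch each per
  turn; the server's φ is the only shared state, and clients never
  synchronize θᵢ. The per-batch loss is the batch's mean cross-entropy.
* **Exactness of the cut.** dL/dz is computed at the same φ the loss was
  evaluated with (the server steps φ afterwards), so with k = 1 and a
  shared initialization the split loop reproduces centralized training of
  the composed model *bitwise* — the equivalence test observes a gap of
  exactly 0 over 50 steps.
* **Transport** is in-process with explicit JSON serialization, making
  the packet audit and the transfer-time component meaningful without
  sockets. T_inference(i) = T_local(i) + T_transfer(i) + T_server holds by
  construction (T_server is the forest prediction time averaged over
  clients); measured values are hardware-dependent and never asserted.
* **Partitioning.** Subject mode (default) deals whole subjects to
  clients per class round-robin after a seeded shuffle — no subject
  straddles clients and every client holds both classes; epoch mode deals
  rows the same way.

## Evaluation

All metric arithmetic is computed from confusion counts in-package
(scikit-learn serves only as a cross-check oracle in tests). MDD (label 1)
is the positive class; healthy metrics swap TP↔TN, FP↔FN. Report-level
single Precision/Recall/F1 columns are support-weighted averages; weighted
recall equals accuracy identically. 0/0 ratios are 0 by convention.
Display rounding is half-up to 4 decimals. ROC handles score ties by
grouping thresholds; the trapezoidal AUC then equals
P(s⁺ > s⁻) + ½ P(s⁺ = s⁻) exactly.

k-fold CV is stratified at the epoch level by default, matching the
apparent convention of epoch-level splits; a group-aware subject mode is
provided because epoch-level splits leak overlapping windows of one
subject across train and test, which inflates accuracy. Neither mode is
asserted as "the" reference protocol.

## Numerical notes and limitations

* All trainable state is float64; Adam is elementwise with default
  (0.9, 0.999) moments.
* Seeds: every stochastic component takes an explicit seed; no global
  random state is touched. Subject streams are stable under cohort
  recomposition.
* EDF writing quantizes to 16 bits over a declared physical range
  (default ±500 µV; step ≈ 0.015 µV); out-of-range samples clip with a
  warning. Integer sampling rates and whole seconds only.
* The ideal filter assumes periodicity over the record; use FIR mode for
  signals with strong edge transients.
* Grid search CV scores are epoch-level within the provided data; with
  overlapping epochs from few subjects they are optimistic relative to
  subject-level generalization.
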