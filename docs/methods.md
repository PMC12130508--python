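# Methods

This note records the models, defaults and numerical choices behind
`airsig`, and what the synthetic experiments do and do not establish.

## The attribution game

Channels are players in a cooperative game.  For a coalition S of channels,
the characteristic value v(S) is the validation accuracy of a classifier
trained on the corpus restricted to S, under one fixed subject-stratified
80/20 split and one fixed training seed shared by *all* coalitions of a run
— so differences between coalition values reflect the channels, not
resampling noise.  (Per-coalition reseeding is possible by recomputing with
a different `TrainConfig.seed`.)

The empty coalition cannot train a model.  Its value defaults to chance
accuracy 1/n_classes, which makes the efficiency identity
Σφ = v(P) − v(∅) read "the channels jointly explain the accuracy gain over
guessing".  A `zero` baseline mode is available: lowering v(∅) by 1/n_classes enters
each φᵢ only through its single size-0 term, whose weight is 1/p, so every
φᵢ grows by exactly 1/(p·n_classes).  Both conventions are exposed because
the convention behind the published percentages is not documented.

Shapley values are computed by the exact subset-sum formula with factorial
weights accumulated in double precision; the test suite checks it against
an independent permutation-average implementation (all p! orderings) to
1e−12 for p ≤ 6, and checks the dummy-player, symmetry, additivity and
efficiency axioms on constructed and random games.

Percentage shares are 100·φᵢ/Σφⱼ.  Noisy desk-scale accuracies can make
some φᵢ negative; shares clip negatives to zero and renormalize (with a
warning), since shares are a display convention while φ itself is reported
unclipped.  A fully degenerate game (no channel with positive contribution)
yields NaN shares rather than an error, so axiom sweeps over random games
never abort.

## Synthetic corpus generator

Real in-air signature corpora are distributed only on request, so the
generator emulates their structure:

- **Subject latent ("motor program")** — per (subject, channel), a sum of
  K = 6 sinusoids with random amplitudes, phases and low frequencies
  (periods of ~12–200 samples), normalized to unit variance.  Smooth,
  subject-stable, and repetition-variable once noise is added; no
  biomechanical claim is made.
- **Channel informativeness ι_c ∈ [0, 1]** — the channel signal is
  √ι_c·u + √(1−ι_c)·e with e an independent smooth unit-variance process
  per repetition, so ι_c is exactly the fraction of (pre-scaling) variance
  carried by the subject latent when `repetition_noise_sd` is 1 (its
  default).  This is the ground truth that attribution experiments recover.
- **Sessions** — rounds 1–5 are session 1, rounds 6–10 session 2
  (collection sessions were separated by days); session-2 records get an
  additive per-(subject, channel) offset ~ N(0, `session_shift_sd`²),
  default 0.3.
- **Dwell noise** — the first and last `dwell_steps` samples (default 5)
  are i.i.d. Gaussian, mimicking the user staring at the device around the
  start/finish button presses.  They are kept, not filtered.
- **Sampling** — per-record interval drawn uniformly from 215–230 ms (the
  slowest SDK mode) unless fixed; record lengths jitter ±10 % around
  `duration_steps` (default 1000) to force downstream length
  standardization.
- **Determinism** — every record draws from an RNG stream keyed by
  (seed, subject, round), so dropping a record never shifts any other; the
  same config and seed reproduce a corpus bit-for-bit.
- **Missing records** — the documented 23-entry (participant, round,
  section) loss pattern of the phone corpus ships as a constant and can be
  applied to any corpus of sufficient size; training compensates with
  per-record sampling weights expected/actual per subject (weights, not
  record duplication, keep corpus counts truthful; duplication could be
  emulated by integer weights).
- **Device scaling** — per-device channel offsets/scales put values in the
  ballpark of the published sample rows (phone accelerometer near gravity,
  small smartwatch magnitudes).  Cosmetic only; attribution is scale-free.

What the generator does **not** model: real amplitude spectra, inter-channel
kinematic coupling, forgeries, long-term signature drift.  Passing recovery
tests therefore shows the *pipeline* is correct (it finds the channels that
carry subject information when the ground truth is known), not that any
particular channel dominates in real data.

## Preprocessing

Records are linearly resampled to a configurable standard length (default
1000, matching the heatmap horizon; desk experiments use 64–128).  The
split is stratified per subject — floor(nᵢ·0.2) test records, minimum 1
when nᵢ ≥ 5, at least one record always kept in training — because
closed-set identification requires every subject in the training set; a
plain random split exists for ablation.  The per-subject heatmap summary
averages the 9 channels and all repetitions into one series per subject,
truncated (or upsampled) to the horizon; its min–max normalization is a
display choice.

## DTW

The accumulated-cost matrix is (n+1)×(m+1) with D[0,0] = 0 and the rest of
the first row/column +∞; D[i,j] = |aᵢ−bⱼ| + min of the three predecessor
cells, each scaled by a tuning coefficient (all 1.0 by default; the local
cost can be switched to squared difference).  The description of a
four-neighbor minimum in the source material does not correspond to a
standard recurrence, so the classic three-predecessor form is used.
Traceback prefers diagonal, then vertical, then horizontal — deterministic
paths.  The DP kernel is numba-compiled; the test oracle enumerates all
admissible warping paths recursively and must agree exactly for n·m ≤ 36.

Relative average DTW reduces each record to its channel mean (consistent
with the heatmap summary) and reports, per subject, the mean distance from
its signatures to all other subjects' signatures.

Descriptors: mean, SD, RMS (time domain); dominant frequency and spectral
centroid of the de-meaned magnitude spectrum in Hz (frequency domain);
permutation entropy of order 3, delay 1, normalized by log 3! (complexity).
The concrete descriptor set is this package's choice — the source material
names the three domains but not the formulas.

## Model zoo

The seven classifiers are implemented on a small numpy layer library with
hand-written backprop (batch layout: batch × length × channels).  Every
layer and every full architecture is validated against central finite
differences; parameters whose gradient is legitimately annihilated
downstream (a convolution bias feeding a batch norm) are covered by the
absolute tolerance term of that check.

Architecture notes:

- Convolutions use 'same' padding except the Encoder, whose source
  specifies padding 0 (valid); with a GAP head 'same' vs 'valid' is
  immaterial to FCN/ResNet heads.
- The Encoder's attention splits the final 512 feature channels in half,
  softmaxes the first half over time and uses it to weight-and-sum the
  second; its dropout rate is unstated in the source and defaults to 0.2.
- ResNet uses three residual blocks with filters 64 → 128 → 256
  (kernels 8/5/3 in each block), identity shortcuts when widths match and
  1×1-conv + batch-norm shortcuts otherwise.
- InceptionTime is a single network (no 5-network ensemble): two blocks of
  three inception modules (bottleneck 32, five parallel convs with kernels
  3/5/8/11/17 plus a max-pool→1×1 branch, 32 filters each), with residual
  connections input→block 1 and block 1→block 2, then GAP and a fully
  connected head.
- Time-CNN's source states only a softmax classification layer; ReLU is
  used after its convolutions.
- MLP hidden widths are 732 as published; no dropout (unstated), which only
  strengthens the overfit sanity check.

Training: weighted softmax cross-entropy (sample weights from the
missing-record re-weighting), mini-batches shuffled by a seeded generator,
per-channel z-scoring with training-set statistics (input normalization is
unstated in the source; it is on by default and recorded in provenance).
Optimizers follow the published table — Adam everywhere except Adadelta
(MLP) and SGD with momentum 0.9 (MC-DCNN).  The published settings
(learning rate 1e−5, 1500 epochs) sit behind `paper_defaults`; desk
defaults are 100 epochs, batch 16, and per-optimizer practical rates
(Adam 1e−3, Adadelta 1.0, SGD 0.01), because a 1500-epoch × 140-cell grid
is not a desk-scale computation.  Everything is single-threaded numpy and
deterministic given the seed.

Batch size is never stated in the source; 16 is the default and is part of
the cached-configuration hash.

## Class activation maps

CAM(t) = Σₖ wₖᶜ·fₖ(t) over the last convolutional feature maps with the
linear head weights of class c, linearly upsampled to the input length and
min–max normalized (a constant map normalizes to all zeros).  Negative
pre-normalization values are kept and rescaled, matching a signed
most-to-least-distinguishable rendering.  Supported: FCN, ResNet,
InceptionTime; the non-GAP architectures raise.  The class visualized
defaults to the record's true class; any class index can be requested.

## Problem sizes used in tests and the acceptance script

Desk experiments are scaled so the full suite runs in about a minute:
corpora of 4–10 subjects with 40–160-step records, input lengths 32–128,
reduced layer widths (e.g. FCN filters 16/32/16), 2–60 epochs.  The
importance-recovery experiment uses 10 subjects × 10 repetitions, 4
channels (informativeness 0.9 vs 0.05), all 16 coalitions, an FCN with
filters 16/32/16, 40 epochs, 3 seeds.  The corpus-size checks generate the
full 427-subject and 22-subject profiles at their default 1000-step
duration.  The 512-coalition full-width runs remain supported through the
same API/CLI and are flagged long-running.

## Known limitations

- The game is exhaustive by design; no sampling approximation is provided,
  so p is capped at 20 and full-scale runs are expensive (2⁹ trainings per
  device per run).
- v(S) is a point estimate from one split/seed; φ inherits that noise.
  Negative φ under noise is reported, not hidden.
- The numpy networks target correctness and determinism, not throughput;
  there is no GPU path.
- Attitude/gyroscope units are taken as radians by convention; the source
  states units only for the accelerometer, and no cross-device unit
  harmonization is attempted.
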