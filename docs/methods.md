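# Methods

## Problem and scope

`swisc` scores chronic mouse electrophysiology — four channels (frontal
ECoG, left and right hippocampal depth LFP, nuchal EMG) sampled at 2 kHz —
into per-epoch labels over five states: wake, NREM, REM, seizure and the
postictal state. Epochs are 20 s by default, with a 4 s mode for
fragmentation-oriented analyses. The package covers the whole path from raw
arrays to corrected hypnograms: conditioning, feature extraction, sequence
classification, a model grid search, an evaluation suite, a scoring-rule
correction layer, and a synthetic-data generator that makes every stage
trainable and testable without animal data.

## Signal conditioning

Stages run in a fixed order per channel, per file:

1. **High-pass**: first-order Butterworth at 1 Hz, applied causally
   (single pass). Removes DC and electrode drift.
2. **Decimation** 2 kHz → 200 Hz (factor 10) through a zero-phase
   anti-aliasing filter. The filter family and corner are a design choice:
   Chebyshev type-I with 0.05 dB ripple at 0.8× the post-decimation Nyquist
   (the conventional decimation default); order 2 for ECoG and 8 for the
   hippocampal and EMG channels. Only this stage is zero-phase.
3. **Z-scoring** over the whole file per channel (population SD). A
   zero-variance channel aborts the file — such recordings are corrupt.
4. **Epoching** into (n_epochs, 4, epoch_len·200) tensors; a trailing
   partial epoch is truncated, never padded. A 12 h file yields
   (2160, 4, 4000) at 20 s epochs or (10800, 4, 800) at 4 s.

A note on the order-2 ECoG anti-aliasing filter: its stopband is shallow
(a 150 Hz tone retains roughly half its power after the zero-phase pass
pair), so ECoG retains more aliased high-frequency energy than the
depth/EMG channels. The tests document this asymmetry rather than hide it.

## Features

Six canonical bands (half-open intervals; a shared edge belongs to the
upper band): delta 2–4 Hz, low theta 4–7, high theta 7–13, beta 13–30, low
gamma 30–55, high gamma 65–100. The 55–65 Hz interval is excluded
everywhere so mains noise can never enter the feature space. Band powers
are computed twice — as sums of one-sided FFT magnitudes and as sums of
Welch PSD bins (1 s Hann segments, 50 % overlap, density scaling) — and
each is normalized by its own 2–55 Hz broadband aggregate, making the
features scale-free. A delta/(low-theta) ratio is computed per spectrum
(the broadband factor cancels) and clipped to [1e−6, 1e6] so suppressed or
epileptiform epochs cannot produce non-finite features.

Because the Welch estimate uses Hann windows at 1 Hz resolution, a tone at
a band edge leaks a measurable fraction (~17 % for 3 Hz) into the adjacent
bin; FFT-magnitude and Welch fractions therefore agree in which band
dominates but not to within a few percent. Tests assert dominance, not
numerical identity, across the two spectral routes.

Per channel and epoch: six time-domain statistics (mean, median, SD,
variance, skewness, excess kurtosis — Fisher, bias-uncorrected, defined as
0 for constant segments), the 6+1 FFT quantities, and the 6+1 PSD
quantities. The EMG channel adds twenty 1 s RMS amplitudes; in the 4 s
mode the four 1 s RMS values are each repeated five times so the block
keeps its 20-slot layout. Four named sets: `dt_rms` (28 features with all
channels), `stat_rms` (44), `fft_rms` (48), `full` (100). A channel mask
supports reduced montages (e.g. bilateral hippocampus only → 40 features);
masking out EMG drops the RMS block. The ordered feature-name manifest is
part of the on-disk format, and trained models refuse matrices whose
manifest hash differs from the one they were fitted on.

## Class weighting

With T classes present and N_C epochs of class C out of N, the balanced
weight is SK_C = N/(T·N_C). Those raw weights span orders of magnitude when
seizures are rare, so they are log-smoothed and anchored on wake:

    Weight_C = ln(SK_C) − ln(SK_wake) + 1 = ln(N_wake/N_C) + 1.

Weight(wake) is exactly 1 for any distribution. A class outnumbering wake
by more than a factor of e gets a non-positive weight; the literal formula
is kept, with a warning and an optional floor (0.01 in the standard
pipeline).

## Classifiers and training

Five families share the interface: a linear SVM baseline (hinge loss, L2,
SGD, ≤1000 iterations, class-weighted, fed the plain per-epoch vector) and
four sequence networks operating on center-aligned windows of 1, 3, 5 or 7
epochs (boundary epochs are padded by edge replication, and windows never
cross file boundaries):

- **dense**: time-distributed linear layer → flatten → 5-way softmax;
- **lstm**: LSTM (full sequences) → 40 % dropout → flatten → softmax;
- **bilstm**: bidirectional LSTM (L units per direction) → dropout →
  flatten → softmax;
- **stacked_bilstm**: four BiLSTM layers halving in width (floor division)
  → dropout → flatten → softmax.

The reference configuration (`swisc_config()`) is the 7-window, full
feature set, 200-unit-per-direction BiLSTM with an L1 activity penalty of
1e−4 on the recurrent output; the penalty is applied only to this final
configuration, not during grid screening.

Because no deep-learning framework is a dependency, the networks are
implemented directly in numpy with hand-written backpropagation (through
time for the recurrent layers), Glorot/orthogonal initialization and a
forget-gate bias of 1. The loss is class-weighted categorical
cross-entropy; the optimizer is Nadam at its canonical defaults (lr 1e−3,
β₁ 0.9, β₂ 0.999). Training stops at the epoch budget (20 for screening,
60 for final training) or when the monitored loss (validation when
provided, else training) improves by less than 0.001 for five consecutive
epochs. The mini-batch is one recording's epoch count (2160 for 12 h/20 s
files). All randomness — initialization, shuffling, dropout — derives from
one integer seed, so training is bit-reproducible on a single device.
Feature columns are standardized to the training set's mean/SD before
entering a network (stored with the model); this conditioning choice keeps
the heterogeneous feature scales (ratios vs. z-scored statistics) from
dominating early gradients.

Inference is deterministic (dropout off); labels are the argmax of the
softmax, ties to the lowest index. SVM "probabilities" are a softmax over
the margin scores and are intended only for ranking.

## Grid search

The default space crosses 4 feature sets × 4 neural families × 3 layer
sizes (50/100/200) × 4 sequence lengths (1/3/5/7) = 192 configurations,
plus one SVM per feature set → 196. Enumeration is a pure, ordered
function of the space. Each configuration trains under the screening
budget and is scored on validation data; failures are recorded and the
grid continues; per-configuration reports stream to disk so interrupted
grids resume. Final-stage retraining is a rerun of top configurations with
`budget=60`.

## Metrics

Per-state precision, recall and F1 with macro and prevalence-weighted
averages, overall agreement (% matching epochs), Cohen's κ and the 5×5
confusion matrix (rows = truth). AUCPR is a Riemann sum of precision over
recall at 200 evenly spaced probability thresholds, per one-hot state;
thresholds are processed in descending order so recall grows
monotonically. The seizure false-alarm rate of a file is
(classifier seizure runs − expert seizure runs)/hours, where a run is a
maximal block of contiguous seizure epochs; the per-file values are
averaged. The signed difference is kept (under-detection shows as a
negative contribution) with an optional clamp at zero.

## Scoring-rule layer

Two transition rules are enforced on hypnograms: REM may only follow NREM,
and NREM is only legal in runs of ≥2 epochs. Seizure/postictal epochs are
never altered and count as wake for transition legality (so REM emerging
from a postictal block is a violation); a REM run opening a file has no
preceding state and is not flagged. The correction policy — a design
choice, since only the rules themselves are canonical — relabels a
violating run to the preceding sleep-wake state (wake when none exists)
and rescans to a fixed point, bounded by one pass per epoch. The corrector
is idempotent and its output always passes the detector (property-tested).

## Synthetic data

The generator emulates what scorers actually look at:

- **wake**: broadband theta-through-gamma EEG, EMG tone 0.8 with phasic
  bursts (0.6/s, 0.2–0.8 s, ×4 amplitude);
- **NREM**: delta-dominated EEG (weight 2.6 vs ≤0.6 elsewhere), amplitude
  ×1.25, EMG tone 0.3, no bursts;
- **REM**: prominent hippocampal theta (weights 2.2/2.6 on the 4–13 Hz
  bands), low delta, EMG atonia (tone 0.08);
- **seizure**: a train of biphasic (Ricker, 30 ms) spikes whose rate
  sweeps linearly 8 → 3 Hz and whose amplitude ramps 4 → 12, ≥5 s long;
- **postictal**: wake-shaped spectrum multiplied by a suppression factor
  of 0.3, EMG nearly silent.

Each bout is rendered as white noise shaped in the frequency domain by the
state's band-weight envelope over a 1/√(1+f) background, normalized to the
state's RMS amplitude. State dwell times follow a semi-Markov chain at
epoch granularity (means: wake 280 s, NREM 220 s, REM 90 s; NREM ≥2
epochs; NREM→REM with probability 0.5, REM→wake always), so the epoch
labels obey the scoring rules by construction. Seizures arrive at 1/h
(Poisson) inside sufficiently long wake bouts, last 12–40 s, and are
always followed by a 60–120 s postictal block. A severity knob adds
interictal Ricker spikes and attenuates theta to emulate epileptic
background slowing (off by default). Epoch labels use the half-or-more
majority rule with ties to the state occupying the epoch's first second,
and a seizure override: >5 s of seizure claims the epoch, and a short or
straddled seizure claims the epoch holding its largest share.

What the generator does **not** emulate: real spike-wave morphology
diversity, electrode artifacts, state-transition ambiguity, circadian
structure, inter-subject spectral variability beyond the seeded noise, or
genuinely hard REM/wake discriminations. Passing the synthetic study shows
the pipeline is wired correctly end to end and that the architecture can
exploit state-specific spectra; it does not certify performance on animal
recordings.

## Standard synthetic study

Six subjects × 2 h at 2 kHz (the first four with seizures), split 4/2 by
subject: epileptic subjects train, saline-like subjects test. The model is
the 7-window, full-feature, 50-unit BiLSTM trained ≤20 epochs with the
floored class weights. Problem sizes were chosen to keep the whole study a
few minutes on one CPU core while leaving every stage at its standard
settings; raw synthesis is held in float32 and subjects are processed one
at a time to bound memory. At these conditions the study reaches ≈99 %
held-out agreement with zero false-alarm seizure runs, and the 4 s rerun
agrees with the subepoched 20 s scores at ≈99 %. `scripts/acceptance.py`
recomputes these quantities from scratch at any seed.

## Numerical choices and edge cases

- Argmax ties break to the lowest class index (wake first).
- Skew/kurtosis of constant segments are defined as 0.
- The delta/theta ratio is clipped to [1e−6, 1e6].
- Zero broadband power raises a degenerate-epoch error rather than
  emitting NaN features.
- Softmax/cross-entropy are computed jointly with max-subtraction and a
  1e−12 floor inside the log.
- Recordings with NaN/Inf anywhere are rejected at the door, mirroring the
  exclusion of corrupt files from curated datasets.

## Known limitations

- The numpy training loop is single-threaded BLAS-bound; it is sized for
  desk-scale studies, not thousand-hour corpora.
- SVM decision scores are not calibrated probabilities.
- The correction layer's replacement policy is one reasonable choice among
  several; it is deliberately pluggable.
- EDF/MAT import cover the common lab layouts only (no annotations, no
  variable-rate channels).
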