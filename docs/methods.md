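# Methods

This note documents the detector's architecture, the training and
evaluation protocol, and the numerical design choices, in enough detail
to re-derive every constant in the code.

## Problem statement

Given a one- or two-lead ECG record, output the sample index of every
QRS complex. Detection is scored against reference beat annotations
with a ±150 ms tolerance (one-to-one matching): sensitivity
`Sen = TP/(TP+FN)`, precision `Pre = TP/(TP+FP)`, error rate
`Err = (FP+FN)/(TP+FN+FP)`, per-AAMI-type false-negative rates, and the
timing margin (mean ± sd of |offset| over true positives).

## Preprocessing

Every record is brought to a canonical form before the network sees it:

1. resample to 250 Hz (polyphase; annotation indices are rescaled and
   rounded half away from zero);
2. zero-phase Butterworth band-pass 0.5–35 Hz, order 3 per pass.
   Forward–backward filtering squares the magnitude response, giving
   ≈ −24 dB at 50 Hz mains and < −40 dB below 0.1 Hz while keeping
   5–25 Hz (the QRS band) within a fraction of a dB, and introduces no
   group delay that would bias beat timing;
3. z-score each lead (flat leads map to zeros);
4. duplicate a single lead into two channels — the network always takes
   a two-channel input.

## Architecture

The network is a 1-D feature pyramid: an encoder at three temporal
scales and a top-down decoder that merges them, with a shared location
head at every scale.

- **Stem**: dense convolution, kernel 19, 2 → 32 channels, instance
  norm, ReLU.
- **Encoder**: three stages at 32 / 64 / 128 channels, two residual
  blocks per stage. A residual block is a single depthwise kernel-19
  convolution + instance norm + ReLU inside an identity skip
  (`y = relu(x + IN(dw(x)))`). Stages are joined by kernel-1 stride-2
  convolutions (they also widen the channels), each with instance norm
  and ReLU, so the three scales run at 250 / 125 / 62.5 Hz.
- **Decoder (FPN)**: kernel-1 lateral convolutions project each stage
  to a common width of 24; the coarser map is upsampled (nearest
  neighbour, ×2) and added; each merged map is smoothed by a depthwise
  kernel-19 convolution.
- **Head (weight-shared across scales)**: convolution kernel 5 to one
  channel, sigmoid, then a stride-1 moving-average pool of width 9.

Bias convention: convolutions directly followed by instance norm carry
no bias (the norm cancels it); the lateral and smoothing convolutions
are not normalized and do carry biases; the head is bias-free. With
this convention the default model has exactly **26,976** trainable
parameters, decomposed as stem 1,216 + residual blocks 8,512 +
downsampling 10,240 + laterals 5,448 + smoothers 1,440 + head 120. The
receptive field of the deepest output is 1 + 18·(1 + 2·1 + 2·2 + 2·4) +
4·(18 + 4 + 8) = 391 samples = 1.564 s at 250 Hz — wide enough to span
any physiological RR interval at a glance, which is what lets a purely
convolutional model replace adaptive thresholding.

Named presets: `default` (above); `desk` (channels 8/16/32, FPN width
8, ~4k parameters) for quick CPU runs; `mwsk`/`mwlk` (kernel 9 / 29)
and `mwsc` (single input channel) ablations.

All layers are implemented directly in NumPy with hand-written backward
passes (the package deliberately has no deep-learning framework
dependency); every gradient is validated against central finite
differences in float64 in the test suite.

## Targets and loss

Each resolution gets an integer label per output sample: **1** within
75 ms of the nearest beat, **0** further than 150 ms from every beat
but between the first and last annotation, **−1** (ignore) otherwise —
the 75–150 ms border zone, the unannotated record ends, and the first
and last 200 ms of every segment. Both thresholds are strict, and
coarse grids are labeled on their own time axes, never by subsampling.

The loss is binary cross-entropy averaged over non-ignored points per
resolution, then averaged (unweighted) over the non-empty resolutions.
Probabilities are clipped at 1e-7; a batch where every resolution is
fully masked is an error, not a zero.

## Training protocol

Adam (lr 1e-3, weight decay 1e-8), batch 32, 5 epochs, 60-s segments;
the checkpoint with the lowest validation loss is kept (ties go to the
earlier epoch). Per-segment augmentation: with probability 0.3 one of
baseline wander / muscle artifact / electrode motion is mixed into each
lead at a uniform 4–12 dB SNR; each channel's sign flips with
probability 0.5 and channels swap with probability 0.5; 10% of batches
are purely simulated 200–280 BPM segments. The family of augmentations
follows the published protocol; the rates are package defaults (the
protocol names the noise types but not the probabilities) and are all
configurable through `Hyper`.

## Synthetic data

The simulator renders evenly spaced beats — `n = round(bpm·dur/60)`
(half-up), beat k at `(k + ½)·dur/n` — as Ricker wavelets
(σ = duration/7, truncated to the stated total duration), amplitude
3–5 mV, duration 50–100 ms, with a 0.8-scaled second lead and optional
white noise at an exact segment-level SNR. The Ricker (Gaussian
second-derivative) pulse is used instead of a first-derivative pulse so
that the annotated sample coincides with the waveform's extremum, which
is the invariant detection is scored against. Noise generators:
baseline wander is a sinusoid whose frequency is drawn from an
equal-weight Gaussian mixture centered at 0.05/0.15/0.25 Hz
(sd = mean/3, non-positive draws rejected); muscle artifact is white
Gaussian noise; electrode motion is white noise band-passed to 5–15 Hz.
The simulator makes no claim of physiological realism beyond the QRS:
no P/T waves, no heart-rate variability, and a perfectly correlated
second lead. Its purpose is controlled, fully annotated data for
training and for exercising the pipeline's contracts.

## Inference

Detection uses the full-resolution heat map: every local maximum above
0.5 is a candidate (plateaus emit their center once), and greedy
non-maximum suppression keeps the highest-probability candidate within
each closed 200 ms window. Detections are mapped back to the record's
native sampling rate. The threshold is fixed; there is no search-back,
no adaptive thresholding and no RR-interval post-processing — misses
under heavy noise are accepted rather than patched downstream.

## Evaluation

Matching is one-to-one and greedy in ascending detection order; each
detection takes the nearest still-unmatched annotation if it is strictly
within tolerance (default 0.15 s; 0.075 s reproduces the stricter
convention used for short 500 Hz records). Equidistant ties go to the
earlier annotation. Multi-record results pool the raw counts and
offsets before computing percentages — never averages of per-record
percentages.

## Scale of the bundled experiments

The test suite's end-to-end run trains the full-width `default` model
for 2 epochs on 200 synthetic 60-s records with batch size 8 — at this
dataset size the smaller batch gives 50 optimizer steps, which is what
the heat maps need to converge; it completes in a few minutes on a
single CPU core and reaches Sen/Pre = 100/100 on clean held-out data,
100/100 at 6 dB white noise, and Sen 97.8 at 200–280 BPM. These sizes
are the package's own desk-scale choices for a self-contained,
download-free experiment; benchmark-scale training on PhysioNet
databases uses the defaults (batch 32, 5 epochs) and the documented
`ar_ds2` record split (`qrspeak train --split ar_ds2`).

## Known limitations

- The WFDB subset reader covers single-file records in formats 16 and
  212 with `.atr` beat annotations — enough for the common PhysioNet
  databases, not the full format family.
- Fixed detection threshold (0.5) and no search-back: borderline beats
  under heavy noise are missed rather than recovered.
- The simulator's regular rhythm cannot probe RR-variability behaviour.
- Training is CPU-bound NumPy; benchmark-scale runs are hours, not
  minutes.
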