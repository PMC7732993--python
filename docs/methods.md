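# Methods

## Problem and approach

Long-term EEG monitoring of epilepsy patients produces days of multichannel
signal in which ictal episodes (seizures) occupy a tiny fraction of the
record. `seizfcn` detects those episodes with a deliberately minimal recipe:
the raw amplitude matrix of the EEG — channels as rows, time samples as
columns — is treated as a grayscale image, and a small fully convolutional
network (FCN) classifies every 64-sample stretch of it as ictal or
inter-ictal. The only pre-processing is montage construction and clipping
scalp amplitudes at ±250 µV to tame movement and electrode artifacts; there
is no filtering, no spectral transform, and no hand-crafted feature
extraction.

## Signal representation

* **Units and time.** Amplitudes are µV everywhere; times are seconds from
  recording start; intervals are half-open `[onset, offset)`.
* **Montage.** Scalp recordings use the standard 23-pair longitudinal
  bipolar chain common to the CHB-MIT corpus (`FP1-F7, F7-T7, …`), pinned
  in `representation.CHB23_PAIRS`; the trailing duplicate `T8-P8` pair is
  retained deliberately so the channel count stays at 23, matching the
  source files this montage imitates. Intracranial montages are derived
  automatically as differences of adjacent contacts within each
  depth-electrode bundle (`A1-A2, A2-A3, …`); a single-contact bundle
  contributes no pairs.
* **Saturation.** Clipping to ±250 µV is applied after montage
  construction and only to scalp-derived channels; intracranial amplitudes
  pass through unchanged. Whether clipping should precede or follow the
  subtraction is genuinely open; clipping afterwards guarantees the bound
  holds on the matrices the network actually sees.
* **Windows.** Training images are 4-s slices (N × 1024 at 256 Hz); window
  start times are snapped to the nearest sample, so the augmentation shifts
  of 1/8 s and 1/16 s are exact 32- and 16-sample steps.

## Sampling and splits

Ictal windows are slid across the complete seizure with a small shift
(defaults: 1/8 s; 1/16 s for EPILEPSIAE-style data), giving
`floor((D−4)/shift)+1` windows per seizure of duration `D`; a window must
lie entirely inside the seizure, so no straddling windows dilute the
positive class. Negatives are drawn half from a *near* pool (windows within
150 s of a seizure boundary, stepped at 1/4 s or 1/8 s) and half from a
*far* pool (non-overlapping 4-s windows elsewhere), at a configurable
negative:positive ratio (default 1:1). If one pool cannot fill its share
the other tops it up. The 9-s minimum seizure duration used for
EPILEPSIAE-style data is strict (`duration ≥ 9 s` is kept) and defaults to
*off* (`min_seizure_duration=0`) so scalp-corpus flows are unaffected; set
it to 9 for EPILEPSIAE-style runs.

Test recordings are never subsampled: evaluation always runs densely over
complete recordings. Splits are leave-one-patient-out, 3-fold
cross-validation over patients (patients partitioned by id order; balancing
by hours or seizure count is not attempted), or the chronological
first-seizures split: per patient, seizures ordered by recording start time
then onset (ties by recording id), the earliest `floor(0.8·n)` (min 1, max
n−1) train, the rest — plus seizure-free recordings — test. A patient with
a single seizure cannot be split and is placed entirely in the test side
with a warning.

## The detector

Three blocks of `conv1d(k=8) → batch-norm → ReLU → maxpool(4)` (128 filters
each, dropout 0.1 after blocks 1–2 and 0.3 after block 3), then two 1×1
convolutions (128 → 128 → 2) and a softmax over the class axis.
Convolutions are length-preserving; each pool truncates the remainder, so
the three 4× pools yield exactly `floor(L/64)` predictions for an input of
length L — one probability pair per 64 samples, for arbitrary-length
inputs. At 23 input channels this is 303,618 trainable parameters.

Choices the architecture description leaves open, pinned here: temporal
kernel width 8 (receptive field ≈ 0.9 s at 256 Hz, and the parameter count
stays within the published 314k budget), max-pooling, head width 128. The
training loss is per-bin cross-entropy with the window's label applied to
all 16 bins of a 4-s window; optimization is Adam (lr 1e-3, batch 64, ≤ 30
epochs) with L2 weight decay 1e-4 on convolution weights only, early
stopping on a held-out slice of the training windows (patience 3), and the
best-validation weights restored. The reported loss curve is the epoch-end
loss over the training slice in inference mode, which is deterministic and
free of dropout/minibatch noise. The whole network, its backward pass and
the optimizer are implemented directly on NumPy float32 arrays; with a
fixed seed, training is bit-reproducible on a single CPU thread.

**Transfer.** A pretrained model is adapted to a different electrode set by
prepending a 1×1 convolution from the new channel count onto the trained
input width; when the widths coincide the adapter is identity-initialised
and predictions are bit-unchanged until finetuning. Layers may be frozen by
name prefix during finetuning; frozen batch-norm layers also keep their
running statistics.

**Dense inference.** Long recordings are processed in 65,536-sample chunks
with 256-sample overlapping context margins — wider than the ~150-sample
receptive field and a multiple of the 64-sample stride, so chunked output
equals a single full-length pass while memory stays bounded.

## Evaluation

Ground truth per output bin: a bin is ictal iff more than half of its
64-sample span lies inside an annotated seizure. Accuracy, specificity,
precision, recall and F-measure follow the textbook confusion-matrix
formulas on a 0–100 scale; a zero-denominator metric is reported as
undefined and excluded from aggregation, never coerced to 0. Average
precision is the step-wise area under the precision–recall curve over every
distinct probability threshold (scikit-learn's estimator, which implements
exactly that sum). The operating threshold maximises F over the distinct
probabilities of the evaluation tracks themselves, ties broken toward the
higher threshold (fewer alarms); this mirrors the protocol the pipeline is
built to reproduce but is optimistic, and reports flag it — a fixed
threshold is available via `threshold_policy="fixed"`.

False alarms per hour: binarise the track, cut the recording into
consecutive segments (30 s by default; the segment length is a config field
because published descriptions of this rule disagree between 30 s and
10 s), raise an alarm when more than 50% of a segment's bins are positive,
and count alarms that intersect no annotated seizure, divided by the
recording hours. A trailing partial segment is dropped from alarm counting
while hours use the full track extent. FPR/h is monotonically
non-increasing in the threshold. Per-patient metrics aggregate as
unweighted mean ± sample standard deviation (ddof 1; a single patient
reports 0), plus a trimmed FPR summary over values within the 95th
percentile.

## Synthetic EEG generator

The generator exists so every stage is testable without clinical data. Per
channel it sums AR(1)-filtered white noise (pole 0.95) with a shared slow
AR(1) component (pole 0.995) carrying 30% of the variance — giving a
1/f-like spectrum, ~0.3 inter-channel correlation, and a 30 µV RMS
background typical of scalp EEG. Seizures are amplitude-modulated
sinusoids whose frequency falls linearly across the event within 3–12 Hz,
with 1-s raised-cosine onset/offset ramps, ~15% slow amplitude modulation
and per-channel random phase (so bipolar differences retain the rhythm);
they are confined to a contiguous block of ⌈N/4⌉ "focus" channels and
scaled to a configurable multiple (default 4×) of the background RMS.
Sparse 350–600 µV Gaussian transients on single channels exercise the
saturation stage. Events keep 60-s mutual gaps and 5-s edge margins so
near/far inter-ictal pools stay non-empty. Identical configs (seed
included) produce bit-identical recordings; cohorts derive per-recording
seeds from a master seed by `SeedSequence` spawning.

What the generator does **not** emulate: volume conduction and realistic
scalp topographies, sleep architecture, non-stationary background state
changes, the artifact taxonomy of real wards, or cross-patient variability
in seizure morphology beyond randomised frequency trajectories. Passing
the end-to-end benchmark therefore shows the pipeline is correct and the
detector can latch onto evolving rhythmic discharges under class imbalance
— it does not certify clinical performance.

## Reference benchmark sizes

The built-in synthetic benchmark (`seizfcn.experiments`) uses 5 patients ×
two 10-minute recordings, one planted 10–40 s gain-4 seizure per recording,
leave-one-patient-out with one fold trained by default, training windows at
a 1-s ictal shift, and at most 8 epochs — a few minutes on one CPU at full
model width. Typical results recover the planted seizures with per-bin
F-measure in the high 90s and zero false alarms per hour; these numbers are
recomputed, never stored, by `scripts/acceptance.py` and the test suite.

## Known limitations

* The EDF writer emits plain 16-bit EDF with 1-s records and drops
  sub-second trailing samples; EDF+ discontinuous records and non-EEG
  auxiliary channels are out of scope. Mixed per-channel sampling rates
  are rejected rather than resampled.
* EPILEPSIAE-style multi-file sessions are treated as independent
  recordings; no cross-file concatenation is attempted.
* The best-F protocol shares data between threshold selection and
  evaluation (flagged in every report).
* Training at clinical scale (hundreds of hours) is out of scope for the
  NumPy implementation; the architecture is small enough that this is a
  throughput, not a correctness, limit.
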