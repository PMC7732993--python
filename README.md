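# seizfcn

Automatic epileptic-seizure detection from raw multichannel EEG, for
researchers and engineers building or evaluating seizure-monitoring
pipelines. The package treats EEG as an *imaged* signal — the raw amplitude
matrix of channels × time, with no filtering or spectral transform — and
runs a lightweight fully convolutional network (FCN) over it to produce a
dense ictal-probability track, one prediction per 64 input samples.

## The method in brief

Given a recording `X ∈ ℝ^{N×L}` (N montage channels, µV, 256 Hz):

1. **Represent** — build the bipolar montage (the standard 23-pair
   longitudinal scalp chain, or adjacent-contact pairs within each
   intracranial electrode bundle), clip scalp amplitudes to ±250 µV, and
   slice 4-s windows `N × 1024` for training.
2. **Sample** — augment the rare ictal class with overlapped windows slid
   across each seizure (1/8-s shift), and subsample inter-ictal windows
   half *near* the seizures (within 150 s) and half *far* from them.
3. **Detect** — a 3-block FCN, `[conv1d(k=8) → batchnorm → ReLU →
   maxpool(4)] × 3` with 128 filters, dropout 0.1/0.3, then two 1×1
   convolutions and a softmax: 303,618 parameters, `⌊L/64⌋` probability
   pairs for an input of any length L. Trained with Adam + L2 weight
   decay; a 1×1 channel-adapter layer transfers a pretrained scalp model
   to intracranial electrode sets.
4. **Evaluate** — per-bin accuracy/specificity/precision/recall/F,
   average precision over the full PR sweep, best-F thresholding, and
   false alarms per hour: consecutive 30-s segments alarm when >50% of
   their bins are positive, and an alarm is false when it touches no
   annotated seizure.

A seeded synthetic-EEG generator (1/f-like correlated background, planted
rhythmic 3–12 Hz discharges at a controlled amplitude gain, high-amplitude
artifacts) makes the entire pipeline testable without clinical recordings;
`docs/methods.md` describes the model, the generator and every default in
detail.

## Worked example

```python
from seizfcn.experiments import synthetic_detection_benchmark
from seizfcn.pipeline import run_experiment

cfg = synthetic_detection_benchmark(seed=1, out_dir="runs/bench")
report = run_experiment(cfg)
for name, (mean, std) in report.aggregate.items():
    print(f"{name:20s} {mean:6.2f} ± {std:.2f}")
```

This generates a 5-patient synthetic cohort (two 10-minute recordings per
patient, one planted gain-4 seizure each), trains the 23-channel base FCN
on four patients and evaluates densely on the held-out patient's complete
recordings. On one CPU it takes about a minute and prints:

```
accuracy              99.88 ± 0.00
specificity           99.96 ± 0.00
precision             99.00 ± 0.00
recall                98.03 ± 0.00
f_measure             98.51 ± 0.00
average_precision     99.01 ± 0.00
fpr_per_hour           0.00 ± 0.00
```

i.e. the detector recovers the planted seizures almost bin-perfectly
(98.5% F-measure on 0.25-s prediction bins) with zero false alarms per
hour; standard deviations are 0 because a single LOO fold evaluates one
patient. Every artifact of the run — split plan, dataset manifest, model
checkpoint, per-recording prediction tracks, report — lands under
`runs/bench/`.

The same pipeline is scriptable from the shell:

```bash
seizfcn synth --patients 3 --duration 600 --out data/ --seed 7
seizfcn run --config experiment.yaml --out runs/exp1
seizfcn predict --model runs/exp1/loo-SP01.model.npz --edf data/SP01_r01.edf \
                --out SP01_r01.track.csv
seizfcn evaluate --tracks runs/exp1 --annotations data/summary.txt
```

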