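"""Canonical experiment configurations.

The synthetic detection benchmark is the package's reference end-to-end
study: a five-patient cohort (two 10-minute recordings per patient, two
planted gain-4 seizures per patient lasting 10-40 s), leave-one-patient-out
training of the default 23-channel base FCN at reduced scale (1-s ictal
shift, at most 8 epochs), and dense evaluation on the held-out patient's
complete recordings under the 30-s false-alarm rule. The sizes are chosen
so the whole run takes a few minutes on one CPU while still exercising
every pipeline stage at full model width.
"""

from __future__ import annotations

from .pipeline import ExperimentConfig


def synthetic_detection_benchmark(
    seed: int,
    out_dir: str,
    max_folds: int | None = 1,
    max_epochs: int = 8,
) -> ExperimentConfig:
    return ExperimentConfig(
        out_dir=out_dir,
        seed=seed,
        split="LOO",
        max_folds=max_folds,
        montage="chb23",
        synth=dict(
            n_patients=5,
            n_channels=21,
            duration=600.0,
            seizure_rate=6.0,                  # one seizure per 10-min recording
            seizure_duration_range=(10.0, 40.0),
            ictal_amplitude_gain=4.0,
        ),
        sampling=dict(ictal_shift=1.0, near_shift=1.0, interictal_per_ictal=1.0),
        train=dict(max_epochs=max_epochs, patience=2),
    )
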