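import numpy as np
import pytest

from seizfcn import ModelConfig, SynthConfig, TrainConfig, build_model, generate_cohort
from seizfcn.core import Recording
from seizfcn.representation import WindowImage


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_model_cfg():
    """Small FCN for fast training tests; same topology, fewer filters."""
    return ModelConfig(
        n_input_channels=4, filters_per_block=16, head_filters=16, seed=11
    )


@pytest.fixture(scope="session")
def tiny_train_cfg():
    return TrainConfig(max_epochs=5, batch_size=16, patience=5, seed=11)


def make_toy_windows(n_per_class=24, n_channels=4, width=256, seed=3):
    """Linearly separable toy set: ictal = strong rhythm on noise."""
    rng = np.random.default_rng(seed)
    wins = []
    t = np.arange(width)
    for label in ("ictal", "interictal"):
        for _ in range(n_per_class):
            x = rng.normal(0, 30, (n_channels, width))
            if label == "ictal":
                phase = rng.uniform(0, 2 * np.pi)
                x += 120 * np.sin(2 * np.pi * 6 * t / 64 + phase)[None, :]
            wins.append(WindowImage(matrix=x.astype(np.float32), t0=0.0, label=label))
    return wins


@pytest.fixture(scope="session")
def toy_windows():
    return make_toy_windows()


@pytest.fixture(scope="session")
def small_cohort():
    """3 patients x 2 short recordings with one planted seizure each."""
    cfg = SynthConfig(
        n_channels=8,
        duration=180.0,
        seizure_rate=20.0,
        seizure_duration_range=(8.0, 15.0),
        ictal_amplitude_gain=4.0,
        seed=0,
    )
    return generate_cohort(3, cfg, seed=5)


def noise_recording(duration=600.0, n_channels=4, fs=256.0, seed=9, patient="PX", rec="PX_r01"):
    rng = np.random.default_rng(seed)
    n = int(duration * fs)
    return Recording(
        patient_id=patient,
        recording_id=rec,
        channel_labels=[f"CH{i}" for i in range(n_channels)],
        modality=["scalp"] * n_channels,
        signal=rng.normal(0, 20, (n_channels, n)),
        sampling_rate=fs,
    )


@pytest.fixture()
def tiny_built_model(tiny_model_cfg):
    return build_model(tiny_model_cfg)
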