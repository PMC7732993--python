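"""Seeded synthetic EEG with planted, annotated seizures.

The generator emulates the statistical structure the detection pipeline is
built for: 1/f-like multichannel background (AR(1) noise per channel plus a
shared slow component giving moderate inter-channel correlation), sparse
high-amplitude artifacts that exercise the ±250 µV saturation stage, and
ictal episodes rendered as evolving rhythmic discharges (amplitude-modulated
sinusoid, frequency decreasing across the event, 1-s onset/offset ramps)
confined to a contiguous "focus" block of channels.

Identical :class:`SynthConfig` (seed included) yields bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .core import INTRACRANIAL, SCALP, ConfigError, Patient, Recording, SeizureEvent

#: canonical 10-20 label order used for scalp recordings; the first 21 cover
#: every electrode referenced by the standard CHB-MIT bipolar chain
SCALP_LABELS_1020 = [
    "FP1", "FP2", "F3", "F4", "F7", "F8", "FZ",
    "C3", "C4", "CZ", "T7", "T8", "P3", "P4",
    "P7", "P8", "PZ", "O1", "O2", "FT9", "FT10",
]

BACKGROUND_RMS_UV = 30.0  # typical ongoing scalp EEG amplitude
_AR_CHANNEL = 0.95        # per-channel AR(1) pole -> low-pass 1/f-like shape
_AR_SHARED = 0.995        # shared slow component pole
_SHARED_VAR_FRACTION = 0.3  # -> inter-channel correlation ~0.3
_EDGE_MARGIN_S = 5.0
_EVENT_GAP_S = 60.0       # keeps near/far inter-ictal pools non-empty
_RAMP_S = 1.0


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic recording."""

    n_channels: int = 21
    sampling_rate: float = 256.0
    duration: float = 3600.0
    seizure_rate: float = 3.0          # events / hour
    seizure_duration_range: tuple[float, float] = (10.0, 120.0)
    ictal_freq_range: tuple[float, float] = (3.0, 12.0)
    ictal_amplitude_gain: float = 4.0  # multiplier over background RMS
    artifact_rate: float = 6.0         # events / hour
    modality: str = SCALP              # scalp | intracranial | mixed
    seed: int = 0

    def validate(self) -> None:
        if self.n_channels < 1:
            raise ConfigError("n_channels must be >= 1")
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be > 0")
        if self.duration <= 0:
            raise ConfigError("duration must be > 0")
        if self.seizure_rate < 0:
            raise ConfigError("seizure_rate must be >= 0")
        lo, hi = self.seizure_duration_range
        if lo < 4.0:
            raise ConfigError(
                "seizure_duration_range minimum must be >= 4 s "
                "(windows must fit inside seizures)"
            )
        if hi < lo:
            raise ConfigError("seizure_duration_range must be (min, max) with min <= max")
        flo, fhi = self.ictal_freq_range
        if not (0 < flo <= fhi):
            raise ConfigError("ictal_freq_range must satisfy 0 < min <= max")
        if self.ictal_amplitude_gain <= 0:
            raise ConfigError("ictal_amplitude_gain must be > 0")
        if self.artifact_rate < 0:
            raise ConfigError("artifact_rate must be >= 0")
        if self.modality not in (SCALP, INTRACRANIAL, "mixed"):
            raise ConfigError(f"modality must be scalp|intracranial|mixed, got {self.modality!r}")


def _channel_labels(config: SynthConfig) -> tuple[list[str], list[str]]:
    """Labels and per-channel modality for a config."""
    n = config.n_channels
    if config.modality == SCALP:
        if n <= len(SCALP_LABELS_1020):
            labels = SCALP_LABELS_1020[:n]
        else:
            labels = SCALP_LABELS_1020 + [
                f"EXG{i:02d}" for i in range(1, n - len(SCALP_LABELS_1020) + 1)
            ]
        return labels, [SCALP] * n
    if config.modality == INTRACRANIAL:
        # depth-electrode bundles of four adjacent contacts: A1..A4, B1..B4, ...
        labels = []
        bundle = 0
        while len(labels) < n:
            name = chr(ord("A") + bundle % 26) * (bundle // 26 + 1)
            labels.extend(f"{name}{i}" for i in range(1, 5))
            bundle += 1
        return labels[:n], [INTRACRANIAL] * n
    # mixed: first half scalp 10-20, rest intracranial bundles
    n_scalp = n // 2
    scalp = _channel_labels(replace(config, modality=SCALP, n_channels=n_scalp))
    intra = _channel_labels(replace(config, modality=INTRACRANIAL, n_channels=n - n_scalp))
    return scalp[0] + intra[0], scalp[1] + intra[1]


def _background(rng: np.random.Generator, n_channels: int, n_samples: int) -> np.ndarray:
    """AR(1) noise per channel plus a shared slow component, RMS-normalised."""
    shared = lfilter([1.0], [1.0, -_AR_SHARED], rng.standard_normal(n_samples))
    shared /= max(np.sqrt(np.mean(shared**2)), 1e-12)
    own = lfilter(
        [1.0], [1.0, -_AR_CHANNEL], rng.standard_normal((n_channels, n_samples)), axis=1
    )
    own /= np.maximum(np.sqrt(np.mean(own**2, axis=1, keepdims=True)), 1e-12)
    x = math.sqrt(_SHARED_VAR_FRACTION) * shared + math.sqrt(1 - _SHARED_VAR_FRACTION) * own
    return BACKGROUND_RMS_UV * x


def _plan_events(
    rng: np.random.Generator, config: SynthConfig, n_events: int, recording_id: str
) -> list[SeizureEvent]:
    lo, hi = config.seizure_duration_range
    durations = rng.uniform(lo, min(hi, max(lo, config.duration / 3)), size=n_events)
    events: list[tuple[float, float]] = []
    for dur in durations:
        if config.duration < dur + 2 * _EDGE_MARGIN_S:
            raise ConfigError(
                "duration too short for a seizure of the requested length "
                "(field: duration / seizure_duration_range)"
            )
        placed = False
        for _ in range(1000):
            onset = rng.uniform(_EDGE_MARGIN_S, config.duration - _EDGE_MARGIN_S - dur)
            ok = all(
                onset + dur + _EVENT_GAP_S <= e_on or e_off + _EVENT_GAP_S <= onset
                for e_on, e_off in events
            )
            if ok:
                events.append((onset, dur + onset))
                placed = True
                break
        if not placed:
            raise ConfigError(
                "duration too short to place the requested number of "
                "non-overlapping seizures (field: duration / seizure_rate)"
            )
    events.sort()
    return [SeizureEvent(recording_id, on, off) for on, off in events]


def _ictal_waveform(
    rng: np.random.Generator, config: SynthConfig, n_focus: int, n_samples: int
) -> np.ndarray:
    """(n_focus, n_samples) rhythmic discharge, per-channel phase and weight."""
    fs = config.sampling_rate
    t = np.arange(n_samples) / fs
    flo, fhi = config.ictal_freq_range
    mid = 0.5 * (flo + fhi)
    f_start = rng.uniform(mid, fhi)
    f_end = rng.uniform(flo, mid)
    # linearly decreasing instantaneous frequency; phase is its integral
    dur = n_samples / fs
    inst = f_start + (f_end - f_start) * t / max(dur, 1e-9)
    phase = 2 * np.pi * np.cumsum(inst) / fs
    ramp = np.ones(n_samples)
    n_ramp = min(int(_RAMP_S * fs), n_samples // 2)
    if n_ramp > 0:
        up = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        ramp[:n_ramp] = up
        ramp[-n_ramp:] = up[::-1]
    am = 1.0 + 0.15 * np.sin(2 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi))
    amp = config.ictal_amplitude_gain * BACKGROUND_RMS_UV * math.sqrt(2.0)
    phases = rng.uniform(0, 2 * np.pi, size=n_focus)
    weights = rng.uniform(0.75, 1.0, size=n_focus)
    wave = np.sin(phase[None, :] + phases[:, None])
    return amp * weights[:, None] * (am * ramp)[None, :] * wave


def generate_recording(
    config: SynthConfig,
    patient_id: str = "SP00",
    recording_id: str | None = None,
    n_seizures: int | None = None,
) -> tuple[Recording, list[SeizureEvent]]:
    """Generate one recording and its planted seizure annotations.

    ``n_seizures`` overrides the count implied by ``config.seizure_rate``
    (used by :func:`generate_cohort` to guarantee split-scheme invariants).
    """
    config.validate()
    rec_id = recording_id if recording_id is not None else f"{patient_id}_r01"
    rng = np.random.default_rng(config.seed)
    n_samples = int(round(config.duration * config.sampling_rate))
    labels, modality = _channel_labels(config)

    signal = _background(rng, config.n_channels, n_samples)

    if n_seizures is None:
        n_seizures = int(round(config.seizure_rate * config.duration / 3600.0))
    events = _plan_events(rng, config, n_seizures, rec_id) if n_seizures else []

    n_focus = math.ceil(config.n_channels / 4)
    fs = config.sampling_rate
    for ev in events:
        i0, i1 = int(round(ev.onset * fs)), int(round(ev.offset * fs))
        focus0 = int(rng.integers(0, config.n_channels - n_focus + 1))
        signal[focus0 : focus0 + n_focus, i0:i1] += _ictal_waveform(
            rng, config, n_focus, i1 - i0
        )

    n_artifacts = int(round(config.artifact_rate * config.duration / 3600.0))
    n_art_samples = max(int(0.2 * fs), 3)
    for _ in range(n_artifacts):
        ch = int(rng.integers(0, config.n_channels))
        center = int(rng.integers(n_art_samples, n_samples - n_art_samples))
        amp = rng.uniform(350.0, 600.0) * rng.choice([-1.0, 1.0])
        tt = np.arange(-n_art_samples // 2, n_art_samples // 2)
        signal[ch, center + tt] += amp * np.exp(-0.5 * (tt / (n_art_samples / 6)) ** 2)

    rec = Recording(
        patient_id=patient_id,
        recording_id=rec_id,
        channel_labels=labels,
        modality=modality,
        signal=signal,
        sampling_rate=fs,
    )
    return rec, events


@dataclass
class CohortConfig:
    """How :func:`generate_cohort` expands a per-recording template."""

    recordings_per_patient: int = 2
    min_seizures_per_recording: int = 1


def generate_cohort(
    n_patients: int,
    per_patient: SynthConfig,
    seed: int,
    cohort: CohortConfig | None = None,
) -> list[Patient]:
    """Deterministic multi-patient cohort.

    Per-patient and per-recording seeds derive from ``seed`` through
    ``numpy.random.SeedSequence`` spawning, so the cohort is reproducible
    end to end. Every patient gets at least two recordings and at least two
    seizures so that every split scheme (LOO, 3FCV, First-Seizures) is
    exercisable.
    """
    if n_patients < 1:
        raise ConfigError("n_patients must be >= 1")
    per_patient.validate()
    cohort = cohort or CohortConfig()
    if cohort.recordings_per_patient < 2:
        raise ConfigError("recordings_per_patient must be >= 2")

    per_rec = int(round(per_patient.seizure_rate * per_patient.duration / 3600.0))
    per_rec = max(per_rec, cohort.min_seizures_per_recording, 1)

    master = np.random.SeedSequence(seed)
    patients: list[Patient] = []
    for p, child in enumerate(master.spawn(n_patients)):
        pid = f"SP{p + 1:02d}"
        patient = Patient(patient_id=pid)
        for r, rec_seq in enumerate(child.spawn(cohort.recordings_per_patient)):
            rec_seed = int(rec_seq.generate_state(1)[0] % (2**31))
            cfg = replace(per_patient, seed=rec_seed)
            rec, events = generate_recording(
                cfg,
                patient_id=pid,
                recording_id=f"{pid}_r{r + 1:02d}",
                n_seizures=per_rec,
            )
            patient.recordings.append(rec)
            patient.events.extend(events)
        patients.append(patient)
    return patients
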