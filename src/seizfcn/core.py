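"""Core in-memory data model shared by every pipeline stage.

Amplitudes are microvolts (µV) everywhere inside the package; times are
seconds from recording start and intervals are half-open ``[onset, offset)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np

SCALP = "scalp"
INTRACRANIAL = "intracranial"


class SeizFCNError(Exception):
    """Base class for package errors."""


class ConfigError(SeizFCNError):
    """Invalid configuration value; the message names the offending field."""


class FormatError(SeizFCNError):
    """Malformed or unsupported on-disk data."""


class DataError(SeizFCNError):
    """Inconsistent in-memory data (labels, intervals, class balance...)."""


class TrainingError(SeizFCNError):
    """Optimization failure (divergence, empty train set...)."""


@dataclass
class Recording:
    """Multichannel EEG recording.

    signal : (n_channels, n_samples) float array, µV
    modality : per-channel "scalp" or "intracranial"
    """

    patient_id: str
    recording_id: str
    channel_labels: list[str]
    modality: list[str]
    signal: np.ndarray
    sampling_rate: float
    start_time: datetime | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise DataError("signal must be a 2-D channels x samples matrix")
        if self.sampling_rate <= 0:
            raise DataError("sampling_rate must be positive")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise DataError(
                f"{len(self.channel_labels)} labels for "
                f"{self.signal.shape[0]} signal rows"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise DataError("channel_labels must be unique")
        if isinstance(self.modality, str):
            self.modality = [self.modality] * self.signal.shape[0]
        if len(self.modality) != self.signal.shape[0]:
            raise DataError("one modality entry per channel required")
        for m in self.modality:
            if m not in (SCALP, INTRACRANIAL):
                raise DataError(f"unknown modality {m!r}")
        if not np.all(np.isfinite(self.signal)):
            raise DataError("signal contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.signal.shape[1] / self.sampling_rate


@dataclass(frozen=True)
class SeizureEvent:
    """Annotated ictal interval, seconds relative to recording start."""

    recording_id: str
    onset: float
    offset: float
    label: str = "ictal"

    def __post_init__(self) -> None:
        if not (0 <= self.onset < self.offset):
            raise DataError(
                f"invalid event [{self.onset}, {self.offset}) "
                f"for {self.recording_id}: need 0 <= onset < offset"
            )

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class Patient:
    """One subject: its recordings and all annotated seizures."""

    patient_id: str
    recordings: list[Recording] = field(default_factory=list)
    events: list[SeizureEvent] = field(default_factory=list)

    def events_for(self, recording_id: str) -> list[SeizureEvent]:
        return [e for e in self.events if e.recording_id == recording_id]


def check_events_within(events: list[SeizureEvent], recording: Recording) -> None:
    for ev in events:
        if ev.offset > recording.duration + 1e-9:
            raise DataError(
                f"event [{ev.onset}, {ev.offset}) exceeds duration "
                f"{recording.duration:.3f}s of {recording.recording_id}"
            )
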