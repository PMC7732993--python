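"""Imaged-EEG representation: montage, ±250 µV saturation, 4-s windows.

A window image is the raw amplitude matrix of one 4-s slice, channels x
samples, after montage construction and (for scalp channels) clipping to
±250 µV — no filtering or spectral transform.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .core import DataError, Recording, SCALP

#: The de-facto CHB-MIT common longitudinal-bipolar set ("double banana"
#: plus the temporal ring), 23 pairs in the order the source files use.
#: The second T8-P8 is retained to keep the channel count at 23.
CHB23_PAIRS: list[tuple[str, str]] = [
    ("FP1", "F7"), ("F7", "T7"), ("T7", "P7"), ("P7", "O1"),
    ("FP1", "F3"), ("F3", "C3"), ("C3", "P3"), ("P3", "O1"),
    ("FP2", "F4"), ("F4", "C4"), ("C4", "P4"), ("P4", "O2"),
    ("FP2", "F8"), ("F8", "T8"), ("T8", "P8"), ("P8", "O2"),
    ("FZ", "CZ"), ("CZ", "PZ"), ("P7", "T7"), ("T7", "FT9"),
    ("FT9", "FT10"), ("FT10", "T8"), ("T8", "P8"),
]


@dataclass(frozen=True)
class MontageSpec:
    """Referencing scheme: ordered bipolar pairs or monopolar labels."""

    kind: str  # "monopolar" | "bipolar"
    pairs: tuple = ()   # bipolar: ((anode, cathode), ...)
    labels: tuple = ()  # monopolar: (label, ...)

    def __post_init__(self) -> None:
        if self.kind not in ("monopolar", "bipolar"):
            raise DataError(f"montage kind must be monopolar|bipolar, got {self.kind!r}")
        if self.kind == "bipolar" and not self.pairs:
            raise DataError("bipolar montage requires at least one pair")
        if self.kind == "monopolar" and not self.labels:
            raise DataError("monopolar montage requires at least one label")

    @property
    def n_channels(self) -> int:
        return len(self.pairs) if self.kind == "bipolar" else len(self.labels)


def chb23_montage() -> MontageSpec:
    """The pinned 23-channel CHB-MIT common bipolar montage."""
    return MontageSpec(kind="bipolar", pairs=tuple(CHB23_PAIRS))


def monopolar_montage(labels: list[str]) -> MontageSpec:
    return MontageSpec(kind="monopolar", labels=tuple(labels))


_BUNDLE_RE = re.compile(r"^([A-Za-z']+)(\d+)$")


def derive_intracranial_bipolar(labels: list[str]) -> MontageSpec:
    """Adjacent-contact bipolar pairs within each depth-electrode bundle.

    Labels must follow the bundle-name + contact-index convention
    (``A1, A2, ..., B1, ...``); bundles appear in first-label order and a
    single-contact bundle contributes no pairs.
    """
    if not labels:
        raise DataError("empty label list: cannot derive an intracranial montage")
    bundles: dict[str, list[tuple[int, str]]] = {}
    order: list[str] = []
    for lab in labels:
        m = _BUNDLE_RE.match(lab)
        if not m:
            raise DataError(f"unparseable intracranial label {lab!r} (want name+index)")
        name, idx = m.group(1), int(m.group(2))
        if name not in bundles:
            bundles[name] = []
            order.append(name)
        bundles[name].append((idx, lab))
    pairs = []
    for name in order:
        contacts = [lab for _, lab in sorted(bundles[name])]
        pairs.extend(zip(contacts[:-1], contacts[1:]))
    if not pairs:
        raise DataError("no bipolar pairs derivable (all bundles have a single contact)")
    return MontageSpec(kind="bipolar", pairs=tuple(pairs))


def to_bipolar(recording: Recording, montage: MontageSpec) -> Recording:
    """Apply a montage: bipolar = anode - cathode samplewise, montage order.

    A monopolar montage selects/reorders channels. Output channel modality is
    inherited from the anode channel.
    """
    index = {lab: i for i, lab in enumerate(recording.channel_labels)}
    if montage.kind == "monopolar":
        missing = [l for l in montage.labels if l not in index]
        if missing:
            raise DataError(f"montage labels missing from recording: {', '.join(missing)}")
        rows = [index[l] for l in montage.labels]
        return Recording(
            patient_id=recording.patient_id,
            recording_id=recording.recording_id,
            channel_labels=list(montage.labels),
            modality=[recording.modality[r] for r in rows],
            signal=recording.signal[rows],
            sampling_rate=recording.sampling_rate,
            start_time=recording.start_time,
        )
    missing = sorted({l for pair in montage.pairs for l in pair if l not in index})
    if missing:
        raise DataError(f"montage labels missing from recording: {', '.join(missing)}")
    labels, modality, sig = [], [], []
    counts: dict[str, int] = {}
    for anode, cathode in montage.pairs:
        name = f"{anode}-{cathode}"
        counts[name] = counts.get(name, 0) + 1
        if counts[name] > 1:
            name = f"{name}_{counts[name]}"  # duplicated pair (CHB keeps two T8-P8)
        labels.append(name)
        modality.append(recording.modality[index[anode]])
        sig.append(recording.signal[index[anode]] - recording.signal[index[cathode]])
    return Recording(
        patient_id=recording.patient_id,
        recording_id=recording.recording_id,
        channel_labels=labels,
        modality=modality,
        signal=np.asarray(sig),
        sampling_rate=recording.sampling_rate,
        start_time=recording.start_time,
    )


def saturate(signal: np.ndarray, limit: float = 250.0) -> np.ndarray:
    """Clip amplitudes to [-limit, +limit] µV. Total and idempotent."""
    if limit <= 0:
        raise DataError("saturation limit must be > 0")
    return np.clip(signal, -limit, limit)


@dataclass(frozen=True)
class RepresentationConfig:
    window_seconds: float = 4.0
    saturation_limit: float = 250.0
    montage: MontageSpec | None = None  # None -> keep channels as stored

    def __post_init__(self) -> None:
        if self.window_seconds <= 0:
            raise DataError("window_seconds must be > 0")
        if self.saturation_limit <= 0:
            raise DataError("saturation_limit must be > 0")


@dataclass
class WindowImage:
    """One N x W amplitude image with its label and provenance."""

    matrix: np.ndarray
    t0: float
    label: str = "unlabeled"        # ictal | interictal | unlabeled
    provenance: str = "inference"   # ictal-augmented | near-interictal | far-interictal | inference
    recording_id: str = ""
    patient_id: str = ""

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    @property
    def width(self) -> int:
        return self.matrix.shape[1]


def apply_montage_and_saturation(
    recording: Recording, config: RepresentationConfig
) -> Recording:
    """Montage construction followed by scalp-channel saturation.

    Saturation applies post-montage and only to scalp-derived channels; the
    clipping threshold is stated for scalp EEG, intracranial amplitudes pass
    through unchanged.
    """
    rec = recording if config.montage is None else to_bipolar(recording, config.montage)
    scalp_rows = [i for i, m in enumerate(rec.modality) if m == SCALP]
    if scalp_rows:
        sig = rec.signal.copy()
        sig[scalp_rows] = saturate(sig[scalp_rows], config.saturation_limit)
        rec = Recording(
            patient_id=rec.patient_id,
            recording_id=rec.recording_id,
            channel_labels=list(rec.channel_labels),
            modality=list(rec.modality),
            signal=sig,
            sampling_rate=rec.sampling_rate,
            start_time=rec.start_time,
        )
    return rec


def extract_windows(
    recording: Recording,
    starts: list[float],
    config: RepresentationConfig,
    label: str = "unlabeled",
    provenance: str = "inference",
) -> list[WindowImage]:
    """Cut fixed-width window images at the given start times (seconds).

    Start times are snapped to the nearest sample; every window must lie
    inside the recording.
    """
    rec = apply_montage_and_saturation(recording, config)
    fs = rec.sampling_rate
    width = int(round(config.window_seconds * fs))
    out = []
    for i, t0 in enumerate(starts):
        i0 = int(round(t0 * fs))
        if i0 < 0 or i0 + width > rec.n_samples:
            raise DataError(
                f"window start #{i} at {t0:.3f}s is out of range for "
                f"{rec.recording_id} (duration {rec.duration:.3f}s)"
            )
        out.append(
            WindowImage(
                matrix=rec.signal[:, i0 : i0 + width].copy(),
                t0=i0 / fs,
                label=label,
                provenance=provenance,
                recording_id=rec.recording_id,
                patient_id=rec.patient_id,
            )
        )
    return out
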