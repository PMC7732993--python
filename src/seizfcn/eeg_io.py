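"""Recording and annotation I/O.

Formats covered:

* EDF/EDF+ — read through :mod:`mne` (amplitudes converted to µV using the
  header calibration); written by a minimal 16-bit EDF writer so synthetic
  recordings round-trip through the on-disk format the clinical datasets use.
* CHB-MIT summary text — ``File Name / Number of Seizures in File /
  Seizure Start Time ... seconds`` blocks.
* CSV annotation dialect — ``recording_id,onset_s,offset_s``.
* EPILEPSIAE-style metadata — absolute ISO timestamps converted to seconds
  relative to a recording start.

Internal unit is µV; intervals are half-open ``[onset, offset)`` seconds.
"""

from __future__ import annotations

import csv
import io
import logging
import math
import re
import warnings
from datetime import datetime
from pathlib import Path

import numpy as np
from scipy.signal import filtfilt, firwin

from .core import FormatError, Recording, SeizureEvent, SCALP

logger = logging.getLogger(__name__)

_EDF_HEADER = 256
_DIG_MAX = 32767


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _scan_edf_header(path: Path) -> tuple[list[str], list[int]]:
    """Return (channel labels, samples-per-record) from the raw EDF header.

    Used to validate uniform sampling rates and recover the original labels
    before any reader-side renaming.
    """
    with open(path, "rb") as fh:
        head = fh.read(_EDF_HEADER)
        if len(head) < _EDF_HEADER:
            raise FormatError(f"{path}: truncated or empty EDF header")
        if not head[:8].strip().startswith(b"0"):
            raise FormatError(f"{path}: not an EDF file (bad version field)")
        try:
            ns = int(head[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise FormatError(f"{path}: malformed channel count") from exc
        if ns < 1:
            raise FormatError(f"{path}: no signal channels")
        rest = fh.read(ns * 256)
        if len(rest) < ns * 256:
            raise FormatError(f"{path}: truncated EDF signal header")
    labels = [rest[i * 16 : (i + 1) * 16].decode("ascii", "replace").strip() for i in range(ns)]
    spr_off = ns * 216
    spr = [
        int(rest[spr_off + i * 8 : spr_off + (i + 1) * 8].decode("ascii").strip())
        for i in range(ns)
    ]
    return labels, spr


def _dedupe(labels: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for lab in labels:
        if lab in seen:
            seen[lab] += 1
            new = f"{lab}_{seen[lab]}"
            logger.warning("duplicate channel label %r disambiguated to %r", lab, new)
            out.append(new)
        else:
            seen[lab] = 0
            out.append(lab)
    return out


def read_edf(
    path: str | Path,
    patient_id: str | None = None,
    modality: str | list[str] = SCALP,
) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (amplitudes in µV)."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    labels, spr = _scan_edf_header(path)
    data_labels = [l for l in labels if "annotation" not in l.lower()]
    data_spr = [s for l, s in zip(labels, spr) if "annotation" not in l.lower()]
    if len(set(data_spr)) > 1:
        from collections import Counter

        majority = Counter(data_spr).most_common(1)[0][0]
        offenders = sorted({l for l, s in zip(data_labels, data_spr) if s != majority})
        raise FormatError(
            f"{path}: mixed per-channel sampling rates are unsupported "
            f"(channels: {', '.join(offenders)})"
        )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on malformed files
        raise FormatError(f"{path}: failed to parse EDF ({exc})") from exc
    signal_uv = raw.get_data() * 1e6  # mne returns volts for EEG dimensions
    if signal_uv.shape[0] != len(data_labels):
        data_labels = list(raw.ch_names)  # fall back to reader's channel set
    meas = raw.info.get("meas_date")
    start = datetime.fromtimestamp(meas.timestamp()) if meas is not None else None
    return Recording(
        patient_id=patient_id or path.stem.split("_")[0],
        recording_id=path.stem,
        channel_labels=_dedupe(data_labels),
        modality=modality,
        signal=signal_uv,
        sampling_rate=float(raw.info["sfreq"]),
        start_time=start,
    )


def _fmt8(value: float) -> bytes:
    """Format a number into EDF's 8-character ASCII numeric field."""
    for fmt in ("%8g", "%8.4g", "%8.3g", "%8.2g"):
        s = fmt % value
        if len(s) <= 8:
            return s.strip().ljust(8).encode("ascii")
    raise FormatError(f"value {value} does not fit an EDF numeric field")


def write_edf(path: str | Path, recording: Recording) -> None:
    """Write a recording as 16-bit EDF (one-second data records).

    Trailing samples that do not fill a whole record are dropped with a
    warning; synthetic recordings always have whole-second durations.
    """
    path = Path(path)
    fs = recording.sampling_rate
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    n_ch, n_samples = recording.signal.shape
    n_records = n_samples // spr
    if n_records * spr != n_samples:
        logger.warning(
            "dropping %d trailing samples not filling a 1-s EDF record",
            n_samples - n_records * spr,
        )
    sig = recording.signal[:, : n_records * spr]

    phys_max = np.maximum(np.abs(sig).max(axis=1) * 1.001, 1.0)
    start = recording.start_time or datetime(2000, 1, 1, 0, 0, 0)

    buf = io.BytesIO()
    buf.write(b"0".ljust(8))
    buf.write(f"X X X {recording.patient_id}".ljust(80)[:80].encode("ascii"))
    buf.write(f"Startdate X X X {recording.recording_id}".ljust(80)[:80].encode("ascii"))
    buf.write(start.strftime("%d.%m.%y%H.%M.%S").encode("ascii"))
    buf.write(str(_EDF_HEADER + n_ch * 256).ljust(8).encode("ascii"))
    buf.write(b" " * 44)
    buf.write(str(n_records).ljust(8).encode("ascii"))
    buf.write(b"1".ljust(8))
    buf.write(str(n_ch).ljust(4).encode("ascii"))

    for lab in recording.channel_labels:
        buf.write(lab.ljust(16)[:16].encode("ascii"))
    for mod in recording.modality:
        buf.write(("EEG" if mod == SCALP else "iEEG").ljust(80).encode("ascii"))
    buf.write(b"uV".ljust(8) * n_ch)
    for pm in phys_max:
        buf.write(_fmt8(-pm))
    for pm in phys_max:
        buf.write(_fmt8(pm))
    buf.write(str(-_DIG_MAX).ljust(8).encode("ascii") * n_ch)
    buf.write(str(_DIG_MAX).ljust(8).encode("ascii") * n_ch)
    buf.write(b" " * (80 * n_ch))  # prefiltering
    buf.write(str(spr).ljust(8).encode("ascii") * n_ch)
    buf.write(b" " * (32 * n_ch))

    scale = _DIG_MAX / phys_max
    digital = np.rint(sig * scale[:, None]).astype("<i2")
    for r in range(n_records):
        block = digital[:, r * spr : (r + 1) * spr]
        buf.write(block.tobytes())  # channel-major within the record

    path.write_bytes(buf.getvalue())


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

_CHB_FILE_RE = re.compile(r"^File Name:\s*(\S+)", re.I)
_CHB_START_RE = re.compile(r"^Seizure(?:\s+\d+)?\s+Start Time:\s*([\d.]+)\s*sec", re.I)
_CHB_END_RE = re.compile(r"^Seizure(?:\s+\d+)?\s+End Time:\s*([\d.]+)\s*sec", re.I)


def read_chb_annotations(path: str | Path) -> list[SeizureEvent]:
    """Parse a CHB-MIT-style summary file (or the CSV dialect) into events."""
    path = Path(path)
    text = path.read_text()
    first = text.splitlines()[0] if text.strip() else ""
    if "recording_id" in first:
        return read_csv_annotations(path)
    events: list[SeizureEvent] = []
    current: str | None = None
    pending_start: float | None = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        m = _CHB_FILE_RE.match(line)
        if m:
            current = Path(m.group(1)).stem
            pending_start = None
            continue
        m = _CHB_START_RE.match(line)
        if m:
            pending_start = float(m.group(1))
            continue
        m = _CHB_END_RE.match(line)
        if m:
            if current is None or pending_start is None:
                raise FormatError(f"{path}:{lineno}: seizure end without file/start context")
            end = float(m.group(1))
            if end <= pending_start:
                raise FormatError(
                    f"{path}:{lineno}: seizure end {end}s <= start {pending_start}s"
                )
            events.append(SeizureEvent(current, pending_start, end))
            pending_start = None
    return events


def read_csv_annotations(path: str | Path) -> list[SeizureEvent]:
    """Parse the ``recording_id,onset_s,offset_s`` CSV dialect."""
    path = Path(path)
    events = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            onset, offset = float(row["onset_s"]), float(row["offset_s"])
            if offset <= onset:
                raise FormatError(f"{path}:{lineno}: offset {offset} <= onset {onset}")
            events.append(SeizureEvent(row["recording_id"], onset, offset))
    return events


def write_csv_annotations(path: str | Path, events: list[SeizureEvent]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["recording_id", "onset_s", "offset_s"])
        for ev in events:
            w.writerow([ev.recording_id, f"{ev.onset:.6f}", f"{ev.offset:.6f}"])


def write_chb_summary(
    path: str | Path, per_recording: list[tuple[str, float, list[SeizureEvent]]]
) -> None:
    """Write a CHB-MIT-style summary: (file name, duration s, events) blocks."""
    lines = []
    for name, _dur, events in per_recording:
        lines.append(f"File Name: {name}")
        lines.append(f"Number of Seizures in File: {len(events)}")
        for i, ev in enumerate(events, start=1):
            lines.append(f"Seizure {i} Start Time: {ev.onset:.0f} seconds")
            lines.append(f"Seizure {i} End Time: {ev.offset:.0f} seconds")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_epilepsiae_annotations(
    path: str | Path,
    recording_start: datetime,
    recording_id: str | None = None,
    recording_duration: float | None = None,
) -> list[SeizureEvent]:
    """Convert absolute-timestamp metadata rows to recording-relative events.

    Expects a CSV with ``recording_id,onset,offset`` columns holding ISO-8601
    timestamps. Events entirely outside the recording are dropped with a
    warning; events straddling a boundary are clipped and flagged.
    """
    path = Path(path)
    events = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            rid = row.get("recording_id", recording_id or "")
            if recording_id is not None and rid != recording_id:
                continue
            onset = (datetime.fromisoformat(row["onset"]) - recording_start).total_seconds()
            offset = (datetime.fromisoformat(row["offset"]) - recording_start).total_seconds()
            if offset <= onset:
                raise FormatError(f"{path}:{lineno}: offset not after onset")
            if offset <= 0 or (recording_duration is not None and onset >= recording_duration):
                logger.warning("%s:%d: event outside recording dropped", path, lineno)
                continue
            clipped_on = max(onset, 0.0)
            clipped_off = offset if recording_duration is None else min(offset, recording_duration)
            if (clipped_on, clipped_off) != (onset, offset):
                logger.warning("%s:%d: event clipped to recording bounds", path, lineno)
            events.append(SeizureEvent(rid, clipped_on, clipped_off))
    return events


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def downsample(recording: Recording, target_rate: float) -> Recording:
    """Anti-aliased integer-factor decimation (zero-phase FIR low-pass).

    The low-pass cutoff is 0.4 x target_rate, comfortably below the new
    Nyquist, so ictal rhythms below ~100 Hz pass undistorted when going
    from 1024 Hz to 256 Hz.
    """
    factor_f = recording.sampling_rate / target_rate
    factor = int(round(factor_f))
    if abs(factor_f - factor) > 1e-9 or factor < 1:
        raise FormatError(
            f"sampling rate {recording.sampling_rate} Hz is not an integer "
            f"multiple of target {target_rate} Hz"
        )
    if factor == 1:
        return recording
    numtaps = 8 * factor + 1
    taps = firwin(numtaps, 0.4 * target_rate, fs=recording.sampling_rate)
    filtered = filtfilt(taps, [1.0], recording.signal, axis=1)
    out = filtered[:, ::factor]
    assert out.shape[1] == math.ceil(recording.n_samples / factor)
    return Recording(
        patient_id=recording.patient_id,
        recording_id=recording.recording_id,
        channel_labels=list(recording.channel_labels),
        modality=list(recording.modality),
        signal=out,
        sampling_rate=float(target_rate),
        start_time=recording.start_time,
    )
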