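"""Training-set construction under extreme class imbalance.

The positive (ictal) class is augmented by sliding a 4-s window across the
complete seizure duration with a small shift (1/8 s for CHB-MIT-style data,
1/16 s for EPILEPSIAE-style). Negatives are subsampled into a *near* pool
(windows within 150 s of a seizure boundary, stepped at a coarser shift)
and a *far* pool (non-overlapping windows elsewhere). Test recordings are
never subsampled: evaluation runs densely over whole recordings.

Three split schemes are supported: 3-fold cross-validation over patients,
leave-one-patient-out, and the chronological "first seizures" split that
trains on the earliest 80% of each patient's seizures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import DataError, Patient, Recording, SeizureEvent
from .representation import RepresentationConfig, WindowImage, extract_windows

logger = logging.getLogger(__name__)

_EPS = 1e-9


@dataclass(frozen=True)
class SamplingConfig:
    """Knobs of the augmentation / subsampling scheme.

    ``min_seizure_duration`` defaults to 0 (off); EPILEPSIAE-style configs
    set it to 9 s to drop very short seizure segments before augmentation.
    The negative:positive ratio and the near/far proportions are left
    configurable (1:1 and 0.5 by default).
    """

    ictal_shift: float = 1.0 / 8.0
    near_shift: float = 1.0 / 4.0
    near_margin: float = 150.0
    min_seizure_duration: float = 0.0
    window_seconds: float = 4.0
    interictal_per_ictal: float = 1.0
    near_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ictal_shift <= 0 or self.near_shift <= 0 or self.window_seconds <= 0:
            raise DataError("shifts and window_seconds must be > 0")
        if self.near_margin <= 0:
            raise DataError("near_margin must be > 0")
        if not 0 <= self.near_fraction <= 1:
            raise DataError("near_fraction must lie in [0, 1]")
        if self.interictal_per_ictal < 0:
            raise DataError("interictal_per_ictal must be >= 0")


def filter_seizures(
    events: list[SeizureEvent], min_duration: float
) -> list[SeizureEvent]:
    """Drop events strictly shorter than ``min_duration`` (order preserved).

    The boundary is strict: an event of exactly ``min_duration`` is kept.
    """
    return [e for e in events if e.duration >= min_duration]


def ictal_starts(event: SeizureEvent, config: SamplingConfig) -> list[float]:
    """Overlapped window starts covering the complete seizure duration.

    starts = onset, onset+shift, ... while start + window <= offset;
    count = floor((D - window)/shift) + 1 for D >= window, else empty.
    """
    d = event.duration
    w = config.window_seconds
    if d < w - _EPS:
        logger.warning(
            "seizure [%s, %s) of %s shorter than the %.1fs window; no ictal windows",
            event.onset, event.offset, event.recording_id, w,
        )
        return []
    count = int(np.floor((d - w) / config.ictal_shift + _EPS)) + 1
    return [event.onset + k * config.ictal_shift for k in range(count)]


def _overlaps(a0: float, a1: float, b0: float, b1: float) -> bool:
    return a0 < b1 - _EPS and b0 < a1 - _EPS


def interictal_pools(
    recording: Recording,
    events: list[SeizureEvent],
    config: SamplingConfig,
) -> tuple[list[float], list[float]]:
    """(near, far) candidate window starts, both seizure-free.

    near: windows fully inside [onset-margin, onset) or [offset, offset+margin],
    stepped at ``near_shift``, excluding overlap with any seizure.
    far: non-overlapping stride-4s windows outside every near zone and seizure.
    """
    w = config.window_seconds
    dur = recording.duration
    if dur < w:
        raise DataError(f"recording {recording.recording_id} shorter than one window")
    seiz = [(e.onset, e.offset) for e in events]

    near: list[float] = []
    for ev in events:
        zones = [
            (max(ev.onset - config.near_margin, 0.0), ev.onset),
            (ev.offset, min(ev.offset + config.near_margin, dur)),
        ]
        for z0, z1 in zones:
            k = 0
            while True:
                s = z0 + k * config.near_shift
                k += 1
                if s + w > z1 + _EPS:
                    break
                if s < 0 or s + w > dur + _EPS:
                    continue
                if any(_overlaps(s, s + w, a, b) for a, b in seiz):
                    continue
                near.append(s)
    near = sorted(set(round(s, 9) for s in near))

    avoid = seiz + [
        (max(e.onset - config.near_margin, 0.0), min(e.offset + config.near_margin, dur))
        for e in events
    ]
    far = []
    n_far = int(np.floor(dur / w + _EPS))
    for k in range(n_far):
        s = k * w
        if s + w > dur + _EPS:
            break
        if any(_overlaps(s, s + w, a, b) for a, b in avoid):
            continue
        far.append(s)
    return near, far


def interictal_starts(
    recording: Recording,
    events: list[SeizureEvent],
    config: SamplingConfig,
    n_ictal: int | None = None,
) -> list[tuple[float, str]]:
    """Subsampled interictal window starts with provenance tags.

    The number drawn is ``interictal_per_ictal x n_ictal`` (``n_ictal``
    defaults to the augmented ictal count of this recording's own events),
    split ``near_fraction`` : rest between the near and far pools, drawn
    without replacement with the config seed.
    """
    near, far = interictal_pools(recording, events, config)
    if not near and not far:
        if events:
            raise DataError(
                f"{recording.recording_id}: seizure margins exhaust the recording; "
                "no interictal windows available"
            )
        raise DataError(f"{recording.recording_id}: no interictal data")
    if n_ictal is None:
        n_ictal = sum(len(ictal_starts(e, config)) for e in events)
    n_total = int(round(config.interictal_per_ictal * n_ictal))
    if n_total <= 0:
        return []
    n_near = min(int(round(config.near_fraction * n_total)), len(near))
    n_far = min(n_total - n_near, len(far))
    if n_far < n_total - n_near:  # far pool exhausted; top up from near
        n_near = min(n_total - n_far, len(near))
    rng = np.random.default_rng([config.seed, 1])
    picked_near = rng.choice(len(near), size=n_near, replace=False) if n_near else []
    picked_far = rng.choice(len(far), size=n_far, replace=False) if n_far else []
    out = [(near[i], "near-interictal") for i in sorted(picked_near)]
    out += [(far[i], "far-interictal") for i in sorted(picked_far)]
    return out


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Train/test assignment at recording granularity.

    For the first-seizures scheme, ``train_events`` additionally restricts
    which seizures of a train recording may contribute ictal windows.
    """

    kind: str  # "3FCV" | "LOO" | "FirstSeizures"
    name: str
    train_recordings: set[tuple[str, str]] = field(default_factory=set)  # (patient, recording)
    test_recordings: set[tuple[str, str]] = field(default_factory=set)
    train_events: list[SeizureEvent] | None = None

    def __post_init__(self) -> None:
        if self.train_recordings & self.test_recordings:
            raise DataError(f"split {self.name}: train and test overlap")


def _event_sort_key(patient: Patient, ev: SeizureEvent):
    rec = next(r for r in patient.recordings if r.recording_id == ev.recording_id)
    start = rec.start_time.timestamp() if rec.start_time else 0.0
    return (start, ev.onset, ev.recording_id)


def make_split(
    cohort: list[Patient], kind: str, fraction: float = 0.8
) -> list[SplitPlan]:
    """Build split plans: LOO, 3FCV over patients, or FirstSeizures.

    * LOO: one plan per patient, holding that patient out entirely.
    * 3FCV: patients partitioned (by id order) into 3 groups; 3 plans.
    * FirstSeizures: a single plan; per patient, seizures sorted
      chronologically, the first ``floor(fraction*n)`` (min 1, max n-1) and
      their recordings train, the rest plus interictal-only recordings test.
    """
    if not cohort:
        raise DataError("empty cohort")
    all_recs = {(p.patient_id, r.recording_id) for p in cohort for r in p.recordings}

    if kind.upper() == "LOO":
        plans = []
        for held in cohort:
            test = {(held.patient_id, r.recording_id) for r in held.recordings}
            plans.append(
                SplitPlan("LOO", f"loo-{held.patient_id}", all_recs - test, test)
            )
        return plans

    if kind.upper() == "3FCV":
        pids = sorted(p.patient_id for p in cohort)
        groups = [set(pids[i::3]) for i in range(3)]
        plans = []
        for i, grp in enumerate(groups):
            test = {pr for pr in all_recs if pr[0] in grp}
            plans.append(SplitPlan("3FCV", f"fold-{i + 1}", all_recs - test, test))
        return plans

    if kind.lower() in ("firstseizures", "first-seizures", "first_seizures"):
        train: set[tuple[str, str]] = set()
        train_events: list[SeizureEvent] = []
        for patient in cohort:
            evs = sorted(patient.events, key=lambda e: _event_sort_key(patient, e))
            n = len(evs)
            if n < 2:
                logger.warning(
                    "patient %s has %d seizure(s); excluded from FirstSeizures training",
                    patient.patient_id, n,
                )
                continue
            k = min(max(int(np.floor(fraction * n)), 1), n - 1)
            head = evs[:k]
            train_events.extend(head)
            train |= {(patient.patient_id, e.recording_id) for e in head}
        test = all_recs - train
        return [SplitPlan("FirstSeizures", "first-seizures", train, test, train_events)]

    raise DataError(f"unknown split kind {kind!r}")


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    train_windows: list[WindowImage]
    test_recordings: list[tuple[Patient, Recording, list[SeizureEvent]]]
    n_ictal: int = 0
    n_interictal: int = 0


def assemble_dataset(
    cohort: list[Patient],
    plan: SplitPlan,
    config: SamplingConfig,
    rep_config: RepresentationConfig,
) -> Dataset:
    """Labelled train windows plus whole test recordings for dense inference.

    Ictal windows are fully contained in annotated seizures; interictal
    windows intersect none. Under FirstSeizures, ictal windows come only
    from the plan's train events, while all of a train recording's seizures
    are still excluded from its interictal pools (no label noise).
    """
    by_id = {p.patient_id: p for p in cohort}
    train_windows: list[WindowImage] = []
    n_ictal = n_inter = 0

    for pid, rid in sorted(plan.train_recordings):
        patient = by_id[pid]
        rec = next(r for r in patient.recordings if r.recording_id == rid)
        events = filter_seizures(patient.events_for(rid), config.min_seizure_duration)
        if plan.train_events is not None:
            allowed = {(e.recording_id, e.onset, e.offset) for e in plan.train_events}
            pos_events = [e for e in events if (e.recording_id, e.onset, e.offset) in allowed]
        else:
            pos_events = events
        pos_starts = [s for e in pos_events for s in ictal_starts(e, config)]
        if pos_starts:
            train_windows.extend(
                extract_windows(rec, pos_starts, rep_config, "ictal", "ictal-augmented")
            )
            n_ictal += len(pos_starts)
        neg = interictal_starts(rec, events, config, n_ictal=len(pos_starts))
        for prov in ("near-interictal", "far-interictal"):
            starts = [s for s, p in neg if p == prov]
            if starts:
                train_windows.extend(
                    extract_windows(rec, starts, rep_config, "interictal", prov)
                )
                n_inter += len(starts)

    if n_ictal == 0 or n_inter == 0:
        raise DataError(
            f"train set for plan {plan.name} has a single class "
            f"(ictal={n_ictal}, interictal={n_inter})"
        )

    test = []
    for pid, rid in sorted(plan.test_recordings):
        patient = by_id[pid]
        rec = next(r for r in patient.recordings if r.recording_id == rid)
        test.append((patient, rec, patient.events_for(rid)))

    logger.info(
        "plan %s: %d ictal / %d interictal train windows, %d test recordings",
        plan.name, n_ictal, n_inter, len(test),
    )
    return Dataset(train_windows, test, n_ictal, n_inter)
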