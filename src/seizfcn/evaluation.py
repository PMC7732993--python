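"""Event-level scoring of dense prediction tracks.

Sample-level confusion metrics (per 64-sample output bin over complete test
recordings), average precision over the full threshold sweep, best-F
thresholding, and the false-alarm-per-hour rule: the recording is cut into
consecutive 30-s segments; a segment raises an alarm when more than half of
its prediction bins are binarised positive, and the alarm is false when the
segment intersects no annotated seizure. All rates are reported on a 0-100
scale; per-patient results aggregate as unweighted mean ± sample standard
deviation, with undefined metrics excluded (never coerced to 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, precision_recall_curve

from .core import DataError, SeizureEvent
from .fcn_model import PredictionTrack

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalConfig:
    fpr_segment: float = 30.0       # seconds per alarm segment
    occupancy_rule: float = 0.5     # fraction of positive bins raising an alarm
    threshold_policy: str = "best-f"  # "best-f" | "fixed"
    fixed_threshold: float = 0.5
    percentile_trim: float = 95.0   # FPR summary percentile

    def __post_init__(self) -> None:
        if not 0 < self.occupancy_rule < 1:
            raise DataError("occupancy_rule must lie strictly between 0 and 1")
        if self.fpr_segment <= 0:
            raise DataError("fpr_segment must be > 0")


METRIC_NAMES = (
    "accuracy", "specificity", "precision", "recall",
    "f_measure", "average_precision", "fpr_per_hour",
)


def bin_labels(
    events: list[SeizureEvent], track: PredictionTrack, sampling_rate: float | None = None
) -> np.ndarray:
    """Ground-truth label per prediction bin.

    A bin is ictal iff more than 50% of its 64-sample span lies inside an
    annotated seizure.
    """
    fs = sampling_rate or track.sampling_rate
    for ev in events:
        if ev.recording_id != track.recording_id:
            raise DataError(
                f"event recording {ev.recording_id!r} does not match "
                f"track {track.recording_id!r}"
            )
    n = len(track)
    bin_s = track.stride / fs
    t0 = np.arange(n) * bin_s
    t1 = t0 + bin_s
    labels = np.zeros(n, dtype=np.int64)
    for ev in events:
        overlap = np.minimum(t1, ev.offset) - np.maximum(t0, ev.onset)
        labels |= (overlap > 0.5 * bin_s).astype(np.int64)
    return labels


def confusion_metrics(labels: np.ndarray, predictions: np.ndarray) -> dict[str, float | None]:
    """Accuracy, specificity, precision, recall, F on a 0-100 scale.

    A metric with a zero denominator is reported as ``None`` (undefined),
    never as 0, and callers exclude it from aggregation.
    """
    labels = np.asarray(labels).astype(bool)
    predictions = np.asarray(predictions).astype(bool)
    if labels.shape != predictions.shape:
        raise DataError("labels and predictions must have equal length")
    tp = int(np.sum(labels & predictions))
    tn = int(np.sum(~labels & ~predictions))
    fp = int(np.sum(~labels & predictions))
    fn = int(np.sum(labels & ~predictions))

    def rate(num, den):
        if den == 0:
            return None
        return 100.0 * num / den

    out = {
        "accuracy": rate(tp + tn, tp + tn + fp + fn),
        "specificity": rate(tn, tn + fp),
        "precision": rate(tp, tp + fp),
        "recall": rate(tp, tp + fn),
    }
    p, r = out["precision"], out["recall"]
    if p is None or r is None or p + r == 0:
        out["f_measure"] = None
        logger.info("F-measure undefined (precision=%s recall=%s)", p, r)
    else:
        out["f_measure"] = 2 * p * r / (p + r)
    return out


def average_precision(labels: np.ndarray, probabilities: np.ndarray) -> float:
    """Area under the step-wise precision-recall curve, on [0, 100]."""
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise DataError("average precision undefined without positive labels")
    return 100.0 * float(average_precision_score(labels, np.asarray(probabilities)))


def best_f_threshold(labels: np.ndarray, probabilities: np.ndarray) -> tuple[float, float]:
    """(threshold, F) maximising F over the distinct-probability grid.

    Predictions are positive at ``p >= threshold``; ties break toward the
    higher threshold (fewer alarms).
    """
    labels = np.asarray(labels)
    probabilities = np.asarray(probabilities, dtype=float)
    if len(set(labels.tolist())) < 2:
        raise DataError("best-F threshold needs both classes present")
    prec, rec, thr = precision_recall_curve(labels, probabilities)
    # sklearn returns thresholds ascending; entry i of prec/rec corresponds
    # to predicting positive at probability >= thr[i]
    with np.errstate(invalid="ignore", divide="ignore"):
        f = 2 * prec[:-1] * rec[:-1] / (prec[:-1] + rec[:-1])
    f = np.nan_to_num(f, nan=0.0)
    best = np.flatnonzero(f >= f.max() - 1e-12)[-1]  # highest tying threshold
    return float(thr[best]), float(100.0 * f[best])


def false_alarms_per_hour(
    track: PredictionTrack,
    events: list[SeizureEvent],
    config: EvalConfig,
    threshold: float,
) -> float:
    """False alarms per hour under the fixed-segment majority-occupancy rule.

    The track is binarised at ``threshold`` and partitioned into consecutive
    ``fpr_segment``-second segments (a trailing partial segment is dropped);
    a segment is an alarm iff more than ``occupancy_rule`` of its bins are
    positive, and false iff it intersects no annotated seizure. Hours use
    the full track extent.
    """
    fs = track.sampling_rate
    bin_s = track.stride / fs
    bins_per_seg = int(round(config.fpr_segment / bin_s))
    n = len(track)
    if n < bins_per_seg:
        raise DataError("recording shorter than one false-alarm segment")
    binary = np.asarray(track.probabilities) >= threshold
    n_seg = n // bins_per_seg
    occ = binary[: n_seg * bins_per_seg].reshape(n_seg, bins_per_seg).mean(axis=1)
    alarms = np.flatnonzero(occ > config.occupancy_rule)
    false = 0
    for s in alarms:
        t0, t1 = s * config.fpr_segment, (s + 1) * config.fpr_segment
        if not any(ev.onset < t1 and t0 < ev.offset for ev in events):
            false += 1
    hours = n * bin_s / 3600.0
    return false / hours


@dataclass
class PatientResult:
    patient_id: str
    metrics: dict[str, float | None]
    threshold: float
    n_bins: int
    n_positive_bins: int


@dataclass
class EvalReport:
    per_patient: list[PatientResult]
    aggregate: dict[str, tuple[float, float]] = field(default_factory=dict)
    excluded: dict[str, int] = field(default_factory=dict)
    trimmed_fpr_mean: float | None = None
    config: EvalConfig = field(default_factory=EvalConfig)


def evaluate_patient(
    patient_id: str,
    tracks: list[PredictionTrack],
    events_by_recording: dict[str, list[SeizureEvent]],
    config: EvalConfig | None = None,
) -> PatientResult:
    """Score one patient across all of its test recordings.

    Bins from every recording are pooled for the sample-level metrics and
    AP; the operating threshold follows ``config.threshold_policy`` (best-F
    is computed on the evaluation tracks themselves — an optimistic protocol,
    flagged as such in the report); FPR/h pools false alarms over the
    patient's total recorded hours.
    """
    config = config or EvalConfig()
    labels = np.concatenate(
        [bin_labels(events_by_recording.get(t.recording_id, []), t) for t in tracks]
    )
    probs = np.concatenate([np.asarray(t.probabilities) for t in tracks])

    if config.threshold_policy == "fixed" or len(set(labels.tolist())) < 2:
        threshold = config.fixed_threshold
    else:
        threshold, _ = best_f_threshold(labels, probs)

    metrics = confusion_metrics(labels, probs >= threshold)
    try:
        metrics["average_precision"] = average_precision(labels, probs)
    except DataError:
        metrics["average_precision"] = None

    false_total = 0.0
    hours_total = 0.0
    for t in tracks:
        hours = len(t) * t.stride / t.sampling_rate / 3600.0
        try:
            rate = false_alarms_per_hour(
                t, events_by_recording.get(t.recording_id, []), config, threshold
            )
        except DataError:
            continue
        false_total += rate * hours
        hours_total += hours
    metrics["fpr_per_hour"] = false_total / hours_total if hours_total else None

    return PatientResult(
        patient_id=patient_id,
        metrics=metrics,
        threshold=threshold,
        n_bins=int(labels.size),
        n_positive_bins=int(labels.sum()),
    )


def aggregate(results: list[PatientResult], config: EvalConfig | None = None) -> EvalReport:
    """Unweighted mean ± sample standard deviation across patients."""
    if not results:
        raise DataError("no patient results to aggregate")
    config = config or EvalConfig()
    report = EvalReport(per_patient=results, config=config)
    for name in METRIC_NAMES:
        vals = [r.metrics.get(name) for r in results]
        defined = np.array([v for v in vals if v is not None], dtype=float)
        report.excluded[name] = len(vals) - len(defined)
        if len(defined) == 0:
            continue
        std = float(np.std(defined, ddof=1)) if len(defined) > 1 else 0.0
        report.aggregate[name] = (float(np.mean(defined)), std)
    fprs = np.array(
        [r.metrics["fpr_per_hour"] for r in results if r.metrics.get("fpr_per_hour") is not None]
    )
    if len(fprs):
        cut = np.percentile(fprs, config.percentile_trim)
        report.trimmed_fpr_mean = float(np.mean(fprs[fprs <= cut]))
    return report
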