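import numpy as np
import pytest

from seizfcn import DataError, EvalConfig, PredictionTrack, SeizureEvent
from seizfcn.evaluation import (
    aggregate,
    average_precision,
    best_f_threshold,
    bin_labels,
    confusion_metrics,
    evaluate_patient,
    false_alarms_per_hour,
)

from oracles import (
    brute_average_precision,
    brute_best_f,
    brute_confusion,
    brute_fpr_per_hour,
)


def track(probs, rid="r1", fs=256.0):
    return PredictionTrack(recording_id=rid, probabilities=np.asarray(probs, float),
                           sampling_rate=fs)


class TestBinLabels:
    def test_exact_bin_coverage(self):
        # seizure exactly covering bins 10..20 (0.25 s per bin at 256 Hz)
        t = track(np.zeros(100))
        events = [SeizureEvent("r1", 10 * 0.25, 21 * 0.25)]
        labels = bin_labels(events, t)
        assert labels[10:21].all() and labels.sum() == 11

    def test_minority_overlap_is_negative(self):
        t = track(np.zeros(10))
        events = [SeizureEvent("r1", 0.15, 0.25)]  # 40% of bin 0
        assert bin_labels(events, t).sum() == 0

    def test_total_positives_tracks_event_spans(self):
        rng = np.random.default_rng(5)
        t = track(np.zeros(2000))
        events = []
        cursor = 10.0
        for _ in range(4):
            d = float(rng.uniform(5, 40))
            events.append(SeizureEvent("r1", cursor, cursor + d))
            cursor += d + 30
        labels = bin_labels(events, t)
        expected = sum(e.duration / 0.25 for e in events)
        assert abs(labels.sum() - expected) <= len(events)

    def test_recording_mismatch_rejected(self):
        with pytest.raises(DataError):
            bin_labels([SeizureEvent("other", 0.5, 1.0)], track(np.zeros(10)))


class TestConfusionMetrics:
    def test_worked_example(self):
        labels = np.r_[np.ones(10), np.zeros(90)].astype(bool)
        preds = np.r_[np.ones(8), np.zeros(2), np.ones(2), np.zeros(88)].astype(bool)
        m = confusion_metrics(labels, preds)
        assert m["precision"] == 80.0
        assert m["recall"] == 80.0
        assert m["f_measure"] == 80.0
        assert m["accuracy"] == 96.0
        assert round(m["specificity"], 2) == 97.78

    def test_perfect_prediction(self):
        labels = np.array([0, 1, 1, 0], bool)
        m = confusion_metrics(labels, labels)
        assert all(m[k] == 100.0 for k in m)

    def test_all_negative_prediction_degenerate(self):
        labels = np.array([1, 1, 0, 0], bool)
        m = confusion_metrics(labels, np.zeros(4, bool))
        assert m["recall"] == 0.0
        assert m["precision"] is None  # undefined, not zero
        assert m["f_measure"] is None


class TestAveragePrecision:
    def test_perfect_ranking_is_100(self):
        labels = np.array([1, 1, 1, 0, 0, 0])
        assert average_precision(labels, [0.9, 0.8, 0.7, 0.3, 0.2, 0.1]) == 100.0
        assert average_precision(labels, labels.astype(float)) == 100.0

    def test_anti_ranking_equals_prevalence(self):
        labels = np.array([0, 0, 0, 1])
        ap = average_precision(labels, [0.9, 0.8, 0.7, 0.1])
        assert np.isclose(ap, 25.0)

    def test_six_point_toy_matches_exhaustive_sweep(self):
        labels = np.array([1, 1, 0, 1, 0, 0])
        probs = np.array([0.9, 0.8, 0.7, 0.6, 0.5, 0.4])
        assert np.isclose(average_precision(labels, probs),
                          brute_average_precision(labels, probs))

    def test_no_positives_is_undefined(self):
        with pytest.raises(DataError):
            average_precision(np.zeros(5), np.linspace(0, 1, 5))


class TestBestFThreshold:
    def test_separable_case_perfect_f(self):
        labels = np.array([0, 0, 0, 1, 1])
        probs = np.array([0.1, 0.2, 0.3, 0.8, 0.9])
        t, f = best_f_threshold(labels, probs)
        assert f == 100.0
        assert 0.3 < t <= 0.8  # separates the classes

    def test_matches_exhaustive_sweep(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 80))
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            probs = rng.random(n).round(2)
            t, f = best_f_threshold(labels, probs)
            bt, bf = brute_best_f(labels, probs)
            assert np.isclose(f, bf)
            # implementation threshold achieves the optimal F
            m = brute_confusion(labels, probs >= t)
            got_f = 2 * m["precision"] * m["recall"] / (m["precision"] + m["recall"])
            assert np.isclose(got_f, bf)

    def test_duplicated_samples_leave_threshold_unchanged(self):
        labels = np.array([0, 0, 1, 1, 0, 1])
        probs = np.array([0.2, 0.4, 0.6, 0.9, 0.3, 0.7])
        t1, _ = best_f_threshold(labels, probs)
        t2, _ = best_f_threshold(np.tile(labels, 3), np.tile(probs, 3))
        assert t1 == t2

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            best_f_threshold(np.ones(5), np.linspace(0, 1, 5))


class TestFalseAlarmsPerHour:
    def test_two_false_alarms_in_four_hours(self):
        n = 4 * 3600 * 4  # 4 h of 0.25-s bins
        probs = np.zeros(n)
        probs[0:120] = 1.0        # segment 0 fully positive
        probs[1200:1320] = 1.0    # segment 10 fully positive
        rate = false_alarms_per_hour(track(probs), [], EvalConfig(), 0.5)
        assert rate == 0.5

    def test_all_zero_predictions(self):
        rate = false_alarms_per_hour(track(np.zeros(240)), [], EvalConfig(), 0.5)
        assert rate == 0.0

    def test_alarm_touching_seizure_not_false(self):
        probs = np.zeros(240)
        probs[0:120] = 1.0
        events = [SeizureEvent("r1", 29.75, 40.0)]  # overlaps segment 0 by one bin
        assert false_alarms_per_hour(track(probs), events, EvalConfig(), 0.5) == 0.0

    def test_monotone_nonincreasing_in_threshold(self, rng):
        probs = rng.random(1200)
        t = track(probs)
        rates = [
            false_alarms_per_hour(t, [], EvalConfig(), thr)
            for thr in np.linspace(0, 1, 21)
        ]
        assert all(b <= a for a, b in zip(rates, rates[1:]))

    def test_too_short_recording_flagged(self):
        with pytest.raises(DataError):
            false_alarms_per_hour(track(np.zeros(60)), [], EvalConfig(), 0.5)


class TestOracleEquivalenceOnRandomTracks:
    def test_metrics_match_brute_force(self, rng):
        """Confusion, AP, best-F and FPR/h equal naive implementations on
        200 random short tracks."""
        for _ in range(200):
            n = int(rng.integers(130, 500))
            labels = (rng.random(n) < 0.2).astype(int)
            if labels.sum() in (0, n):
                continue
            probs = np.round(rng.random(n), 3)
            thr = float(rng.random())

            m = confusion_metrics(labels, probs >= thr)
            bm = brute_confusion(labels, probs >= thr)
            for k, v in bm.items():
                if v is None:
                    assert m[k] is None
                else:
                    assert np.isclose(m[k], v), k

            assert np.isclose(average_precision(labels, probs),
                              brute_average_precision(labels, probs))

            t, f = best_f_threshold(labels, probs)
            bt, bf = brute_best_f(labels, probs)
            assert np.isclose(f, bf)

            events = [SeizureEvent("r1", 1.0, 4.0)]
            got = false_alarms_per_hour(track(probs), events, EvalConfig(), thr)
            ref = brute_fpr_per_hour(probs, [(1.0, 4.0)], thr)
            assert np.isclose(got, ref)


class TestAggregation:
    def _result(self, pid, **metrics):
        from seizfcn.evaluation import PatientResult

        base = {k: None for k in
                ("accuracy", "specificity", "precision", "recall",
                 "f_measure", "average_precision", "fpr_per_hour")}
        base.update(metrics)
        return PatientResult(pid, base, 0.5, 100, 10)

    def test_mean_and_sample_std(self):
        rep = aggregate([self._result("a", f_measure=100.0),
                         self._result("b", f_measure=50.0)])
        mean, std = rep.aggregate["f_measure"]
        assert mean == 75.0
        assert round(std, 2) == 35.36

    def test_single_patient_std_zero(self):
        rep = aggregate([self._result("a", recall=80.0)])
        assert rep.aggregate["recall"] == (80.0, 0.0)

    def test_undefined_metrics_excluded_and_counted(self):
        rep = aggregate([self._result("a", precision=60.0), self._result("b")])
        assert rep.aggregate["precision"] == (60.0, 0.0)
        assert rep.excluded["precision"] == 1

    def test_trimmed_fpr_mean(self):
        results = [self._result(str(i), fpr_per_hour=v)
                   for i, v in enumerate([0.0, 0.1, 0.2, 100.0])]
        rep = aggregate(results, EvalConfig(percentile_trim=75.0))
        assert rep.trimmed_fpr_mean == pytest.approx(0.1)


class TestEvaluatePatient:
    def test_end_to_end_patient_scoring(self):
        # 20 minutes of bins; one seizure from 60 s to 90 s, well predicted
        n = 20 * 60 * 4
        probs = np.full(n, 0.05)
        probs[240:360] = 0.95
        events = {"r1": [SeizureEvent("r1", 60.0, 90.0)]}
        res = evaluate_patient("p1", [track(probs)], events)
        assert res.metrics["f_measure"] == 100.0
        assert res.metrics["fpr_per_hour"] == 0.0
        assert res.n_positive_bins == 120
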