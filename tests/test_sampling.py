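import numpy as np
import pytest

from seizfcn import DataError, SeizureEvent
from seizfcn.representation import RepresentationConfig
from seizfcn.sampling import (
    SamplingConfig,
    assemble_dataset,
    filter_seizures,
    ictal_starts,
    interictal_pools,
    interictal_starts,
    make_split,
)

from conftest import noise_recording
from oracles import brute_ictal_start_count


def ev(onset, offset, rid="PX_r01"):
    return SeizureEvent(rid, onset, offset)


class TestFilterSeizures:
    def test_strict_nine_second_floor(self):
        events = [ev(0.0 + i * 100, d + i * 100) for i, d in enumerate([5.0, 8.9, 9.0, 20.0])]
        kept = filter_seizures(events, 9.0)
        assert [e.duration for e in kept] == [9.0, 20.0]

    def test_zero_floor_is_identity(self):
        events = [ev(0, 5), ev(10, 12)]
        assert filter_seizures(events, 0.0) == events

    def test_all_short_leaves_empty(self):
        assert filter_seizures([ev(0, 5)], 9.0) == []


class TestIctalStarts:
    def test_worked_counts(self):
        assert len(ictal_starts(ev(100, 130), SamplingConfig(ictal_shift=1 / 8))) == 209
        assert len(ictal_starts(ev(100, 130), SamplingConfig(ictal_shift=1 / 16))) == 417
        assert len(ictal_starts(ev(100, 104), SamplingConfig())) == 1

    def test_too_short_yields_empty(self):
        assert ictal_starts(ev(10, 13), SamplingConfig()) == []

    def test_matches_enumeration_oracle_over_random_cases(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            d = float(rng.uniform(4.0, 130.0))
            shift = float(rng.choice([1 / 16, 1 / 8, 1 / 4, 0.5, 1.0]) )
            starts = ictal_starts(ev(50.0, 50.0 + d), SamplingConfig(ictal_shift=shift))
            assert len(starts) == brute_ictal_start_count(d, shift)
            # every window fully inside the seizure
            if starts:
                assert starts[0] == 50.0
                assert starts[-1] + 4.0 <= 50.0 + d + 1e-9


class TestInterictalStarts:
    def test_no_seizures_far_pool_covers_recording(self):
        rec = noise_recording(duration=600.0)
        near, far = interictal_pools(rec, [], SamplingConfig())
        assert near == []
        assert len(far) == 600 // 4

    def test_returned_windows_never_intersect_seizures(self):
        rec = noise_recording(duration=600.0)
        events = [ev(200.0, 230.0)]
        out = interictal_starts(rec, events, SamplingConfig(seed=3), n_ictal=60)
        assert out
        for s, _prov in out:
            assert not (s < 230.0 and 200.0 < s + 4.0)

    def test_near_windows_lie_within_closeness_margin(self):
        rec = noise_recording(duration=600.0)
        events = [ev(200.0, 230.0)]
        near, _ = interictal_pools(rec, events, SamplingConfig())
        assert near
        for s in near:
            assert (200.0 - 150.0 <= s and s + 4.0 <= 200.0) or (
                230.0 <= s and s + 4.0 <= 230.0 + 150.0
            )

    def test_empty_recording_pool_error(self):
        rec = noise_recording(duration=3.0)
        with pytest.raises(DataError):
            interictal_starts(rec, [], SamplingConfig())

    def test_deterministic_draw(self):
        rec = noise_recording(duration=600.0)
        events = [ev(100.0, 120.0)]
        a = interictal_starts(rec, events, SamplingConfig(seed=9), n_ictal=40)
        b = interictal_starts(rec, events, SamplingConfig(seed=9), n_ictal=40)
        assert a == b


class TestSplits:
    def test_loo_holds_out_each_patient(self, small_cohort):
        plans = make_split(small_cohort, "LOO")
        assert len(plans) == len(small_cohort)
        for plan, held in zip(plans, small_cohort):
            test_pids = {p for p, _ in plan.test_recordings}
            train_pids = {p for p, _ in plan.train_recordings}
            assert test_pids == {held.patient_id}
            assert held.patient_id not in train_pids

    def test_3fcv_partitions_patients(self, small_cohort):
        plans = make_split(small_cohort, "3FCV")
        assert len(plans) == 3
        seen = []
        for plan in plans:
            seen.extend(p for p, _ in plan.test_recordings)
        # every recording appears in exactly one test fold
        assert sorted(set(seen)) == sorted(p.patient_id for p in small_cohort)

    def test_first_seizures_80_20(self):
        from seizfcn.core import Patient, Recording

        fs = 256.0
        sig = np.zeros((1, int(3000 * fs)))
        rec = Recording("P1", "P1_r01", ["A"], ["scalp"], sig, fs)
        events = [SeizureEvent("P1_r01", 100.0 * i + 10, 100.0 * i + 40) for i in range(10)]
        patient = Patient("P1", [rec], events)
        (plan,) = make_split([patient], "first-seizures")
        assert len(plan.train_events) == 8
        trained = sorted(e.onset for e in plan.train_events)
        assert trained == sorted(e.onset for e in events[:8])

    def test_single_seizure_patient_excluded_from_training(self):
        from seizfcn.core import Patient, Recording

        sig = np.zeros((1, 256 * 100))
        rec = Recording("P1", "P1_r01", ["A"], ["scalp"], sig, 256.0)
        patient = Patient("P1", [rec], [SeizureEvent("P1_r01", 10.0, 30.0)])
        (plan,) = make_split([patient], "first-seizures")
        assert plan.train_recordings == set()
        assert plan.test_recordings == {("P1", "P1_r01")}


class TestAssembleDataset:
    def _single_patient(self):
        from seizfcn.core import Patient

        rec = noise_recording(duration=600.0, n_channels=4)
        events = [ev(200.0, 230.0)]
        return [Patient("PX", [rec], events)]

    def test_one_to_one_ratio_counts(self):
        from seizfcn.sampling import SplitPlan

        cohort = self._single_patient()
        plan = SplitPlan("LOO", "train-all", {("PX", "PX_r01")}, set())
        cfg = SamplingConfig(ictal_shift=1 / 8, interictal_per_ictal=1.0, seed=2)
        ds = assemble_dataset(cohort, plan, cfg, RepresentationConfig(montage=None))
        assert ds.n_ictal == 209
        assert ds.n_interictal == 209
        labels = {w.label for w in ds.train_windows}
        assert labels == {"ictal", "interictal"}

    def test_label_purity(self):
        from seizfcn.sampling import SplitPlan

        cohort = self._single_patient()
        plan = SplitPlan("LOO", "train-all", {("PX", "PX_r01")}, set())
        ds = assemble_dataset(
            cohort, plan, SamplingConfig(seed=2), RepresentationConfig(montage=None)
        )
        for w in ds.train_windows:
            inside = 200.0 <= w.t0 and w.t0 + 4.0 <= 230.0
            intersects = w.t0 < 230.0 and 200.0 < w.t0 + 4.0
            if w.label == "ictal":
                assert inside
            else:
                assert not intersects

    def test_no_leakage_under_loo(self, small_cohort):
        plans = make_split(small_cohort, "LOO")
        cfg = SamplingConfig(ictal_shift=1.0, seed=4)
        rep = RepresentationConfig(montage=None)
        ds = assemble_dataset(small_cohort, plans[0], cfg, rep)
        held = small_cohort[0].patient_id
        assert all(w.patient_id != held for w in ds.train_windows)
        test_pids = {p.patient_id for p, _, _ in ds.test_recordings}
        assert test_pids == {held}

    def test_test_side_never_subsampled(self, small_cohort):
        plans = make_split(small_cohort, "LOO")
        rep = RepresentationConfig(montage=None)
        a = assemble_dataset(small_cohort, plans[0], SamplingConfig(ictal_shift=1.0, seed=1), rep)
        b = assemble_dataset(
            small_cohort, plans[0],
            SamplingConfig(ictal_shift=2.0, interictal_per_ictal=0.5, seed=99), rep,
        )
        assert len(a.test_recordings) == len(b.test_recordings)

    def test_deterministic_composition(self, small_cohort):
        plans = make_split(small_cohort, "LOO")
        cfg = SamplingConfig(ictal_shift=1.0, seed=8)
        rep = RepresentationConfig(montage=None)
        a = assemble_dataset(small_cohort, plans[0], cfg, rep)
        b = assemble_dataset(small_cohort, plans[0], cfg, rep)
        assert [(w.recording_id, w.t0, w.label) for w in a.train_windows] == [
            (w.recording_id, w.t0, w.label) for w in b.train_windows
        ]

    def test_single_class_train_set_rejected(self):
        from seizfcn.core import Patient
        from seizfcn.sampling import SplitPlan

        rec = noise_recording(duration=200.0)
        cohort = [Patient("PX", [rec], [])]  # no seizures at all
        plan = SplitPlan("LOO", "train-all", {("PX", "PX_r01")}, set())
        with pytest.raises(DataError, match="single class"):
            assemble_dataset(cohort, plan, SamplingConfig(seed=1), RepresentationConfig(montage=None))
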