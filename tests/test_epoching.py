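"""Epoch extraction, jitter augmentation, balancing, and splitting."""

import numpy as np
import pytest

from focalspike.epoching import (
    NON_IED,
    EpochSet,
    EpochingConfig,
    balance_classes,
    build_balanced_dataset,
    extract_ied_epochs,
    jitter_augment,
    sample_non_ied_epochs,
    split_dataset,
)
from focalspike.errors import CapacityError, ContractError
from focalspike.recording import AnnotationSet, IEDAnnotation, Recording
from focalspike.synth import make_background, inject_ieds


@pytest.fixture(scope="module")
def annotated_recording():
    rec = make_background(60, 200, seed=21, subject_id="P01")
    return inject_ieds(rec, "occipital", 8, min_gap_s=2.0, seed=21)


def _synthetic_epochset(n, label, subject="S", n_samples=300, seed=0):
    rng = np.random.default_rng(seed)
    return EpochSet(
        data=rng.normal(0, 1, (n, 19, n_samples)).astype(np.float32),
        labels=np.array([label] * n, dtype=object),
        subject_ids=np.array([subject] * n, dtype=object),
        source_event_indices=np.arange(n),
        centers_s=np.arange(n, dtype=float),
        uids=np.array([f"{subject}:{label}:{i}" for i in range(n)], dtype=object),
    )


class TestExtract:
    def test_window_arithmetic(self):
        sig = np.arange(19 * 4000, dtype=float).reshape(19, 4000)
        rec = Recording("W", sig, fs=200)
        ann = AnnotationSet("W", [IEDAnnotation("frontal", 9.8, 10.2)])
        out = extract_ied_epochs(rec, ann)
        assert len(out) == 1
        assert out.data.shape == (1, 19, 300)
        np.testing.assert_allclose(out.data[0], sig[:, 1850:2150])
        assert out.centers_s[0] == pytest.approx(10.0)

    def test_one_epoch_per_interior_event(self, annotated_recording):
        rec, ann = annotated_recording
        out = extract_ied_epochs(rec, ann)
        assert len(out) == len(ann)
        assert set(out.labels.tolist()) == {"occipital"}

    def test_boundary_event_skipped_with_warning(self):
        rec = Recording("B", np.zeros((19, 2000)) + 1.0, fs=200)
        ann = AnnotationSet("B", [IEDAnnotation("temporal", 0.3, 0.7)])
        with pytest.warns(UserWarning, match="skipped"):
            out = extract_ied_epochs(rec, ann)
        assert len(out) == 0

    def test_wrong_fs_rejected(self):
        rec = Recording("F", np.zeros((19, 2560)) + 1.0, fs=256)
        ann = AnnotationSet("F", [])
        with pytest.raises(ContractError):
            extract_ied_epochs(rec, ann)


class TestJitter:
    def test_count_is_events_times_factor(self, annotated_recording):
        rec, ann = annotated_recording
        cfg = EpochingConfig(augment_factor=10)
        out = jitter_augment(rec, ann, cfg, seed=1)
        assert len(out) == len(ann) * 10

    def test_shifts_bounded_by_50ms(self, annotated_recording):
        rec, ann = annotated_recording
        cfg = EpochingConfig(augment_factor=10)
        out = jitter_augment(rec, ann, cfg, seed=2)
        true_centers = {i: ev.center_s for i, ev in enumerate(ann)}
        for src, c in zip(out.source_event_indices, out.centers_s):
            assert abs(c - true_centers[src]) <= 0.05 + 1e-9

    def test_unjittered_copy_retained(self, annotated_recording):
        rec, ann = annotated_recording
        cfg1 = EpochingConfig(augment_factor=1)
        base = extract_ied_epochs(rec, ann, cfg1)
        aug = jitter_augment(rec, ann, cfg1, seed=3)
        np.testing.assert_array_equal(base.data, aug.data)

    def test_deterministic(self, annotated_recording):
        rec, ann = annotated_recording
        cfg = EpochingConfig(augment_factor=5)
        a = jitter_augment(rec, ann, cfg, seed=9)
        b = jitter_augment(rec, ann, cfg, seed=9)
        np.testing.assert_array_equal(a.data, b.data)


class TestNonIed:
    def test_control_sampling(self):
        rec = make_background(60, 200, seed=30, subject_id="C01", group="control")
        out = sample_non_ied_epochs(rec, 100, None, seed=4)
        assert len(out) == 100
        assert set(out.labels.tolist()) == {NON_IED}
        assert np.all(out.source_event_indices == -1)

    def test_exclusion_windows_never_intersected(self, annotated_recording):
        rec, ann = annotated_recording
        cfg = EpochingConfig()
        out = sample_non_ied_epochs(rec, 50, ann, cfg, seed=5)
        fs, half = cfg.fs, cfg.half_span_s
        for c in out.centers_s:
            s0 = round((c - half) * fs)
            for ev in ann:
                w0 = round((ev.center_s - half) * fs)
                assert abs(s0 - w0) >= cfg.n_samples  # disjoint 300-sample windows

    def test_deterministic_starts(self):
        rec = make_background(30, 200, seed=31)
        a = sample_non_ied_epochs(rec, 20, None, seed=6)
        b = sample_non_ied_epochs(rec, 20, None, seed=6)
        np.testing.assert_array_equal(a.centers_s, b.centers_s)

    def test_capacity_error(self):
        rec = make_background(15, 200, seed=32)
        with pytest.raises(CapacityError):
            sample_non_ied_epochs(rec, 10**6, None, seed=7)


class TestBalance:
    def test_one_to_one_undersampling(self):
        ied = _synthetic_epochset(650, "temporal", seed=1)
        pool = _synthetic_epochset(2000, NON_IED, seed=2)
        out = build_balanced_dataset(ied, pool)
        counts = out.label_counts()
        assert counts == {"temporal": 650, NON_IED: 650}

    def test_multiclass_min_match(self):
        parts = [
            _synthetic_epochset(1100, "temporal", seed=3),
            _synthetic_epochset(1000, "occipital", seed=4),
            _synthetic_epochset(1050, NON_IED, seed=5),
        ]
        out = balance_classes(EpochSet.concat(parts), seed=0)
        assert set(out.label_counts().values()) == {1000}

    def test_insufficient_pool_reports_shortfall(self):
        ied = _synthetic_epochset(650, "frontal", seed=6)
        pool = _synthetic_epochset(100, NON_IED, seed=7)
        with pytest.raises(CapacityError, match="shortfall"):
            build_balanced_dataset(ied, pool)


class TestSplit:
    def test_epoch_unit_sizes(self):
        epochs = _synthetic_epochset(100, "occipital", seed=8)
        cfg = EpochingConfig(split_unit="epoch")
        splits = split_dataset(epochs, cfg, seed=1)
        assert (len(splits.train), len(splits.val), len(splits.test)) == (60, 20, 20)

    def test_event_unit_no_source_leakage(self, annotated_recording):
        rec, ann = annotated_recording
        cfg = EpochingConfig(augment_factor=10)
        aug = jitter_augment(rec, ann, cfg, seed=10)
        splits = split_dataset(aug, cfg, seed=11)
        seen = {}
        for name, part in (("train", splits.train), ("val", splits.val),
                           ("test", splits.test)):
            for src in set(part.source_event_indices.tolist()):
                assert src not in seen, f"event {src} in {seen[src]} and {name}"
                seen[src] = name

    def test_stratified_and_near_ratio(self):
        both = EpochSet.concat([
            _synthetic_epochset(200, "temporal", subject="A", seed=12),
            _synthetic_epochset(200, NON_IED, subject="B", seed=13),
        ])
        cfg = EpochingConfig(split_unit="epoch")
        splits = split_dataset(both, cfg, seed=3)
        for part, expect in ((splits.train, 120), (splits.val, 40), (splits.test, 40)):
            counts = part.label_counts()
            assert counts["temporal"] == expect
            assert counts[NON_IED] == expect

    def test_deterministic_partition(self):
        epochs = _synthetic_epochset(90, "frontal", seed=14)
        splits_a = split_dataset(epochs, seed=5)
        splits_b = split_dataset(epochs, seed=5)
        assert splits_a.train.uids.tolist() == splits_b.train.uids.tolist()
        assert splits_a.test.uids.tolist() == splits_b.test.uids.tolist()

    def test_too_few_epochs_rejected(self):
        epochs = _synthetic_epochset(2, "frontal", seed=15)
        with pytest.raises(ValueError):
            split_dataset(epochs)

    def test_disjoint_uids(self):
        epochs = _synthetic_epochset(100, "temporal", seed=16)
        splits = split_dataset(epochs, seed=7)
        tr = set(splits.train.uids.tolist())
        va = set(splits.val.uids.tolist())
        te = set(splits.test.uids.tolist())
        assert not (tr & va) and not (tr & te) and not (va & te)
        assert len(tr | va | te) == 100


class TestConfigInvariants:
    def test_epoch_length_consistency(self):
        with pytest.raises(ValueError):
            EpochingConfig(epoch_len_s=2.0, half_span_s=0.75)

    def test_ratio_sum(self):
        with pytest.raises(ValueError):
            EpochingConfig(split_ratios=(0.5, 0.2, 0.2))

    def test_n_samples_is_300_at_200hz(self):
        assert EpochingConfig().n_samples == 300
        assert EpochingConfig().jitter_max_samples == 10
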