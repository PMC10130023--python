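"""Metrics against independent oracles; detection rates; LOPO harness; t-SNE."""

import numpy as np
import pytest

from focalspike.cnn import ModelSpec, TrainSpec
from focalspike.cohort_reference import lopo_reference_frame
from focalspike.epoching import NON_IED, EpochSet
from focalspike.errors import ContractError
from focalspike.evaluation import (
    PatientEpochs,
    TSNEParams,
    binary_metrics,
    detection_rate,
    lopo_cross_validation,
    multiclass_metrics,
    subsample_per_class,
    summarize_detection_rates,
    tsne_embed,
)


def pairwise_auc(y, s):
    """Oracle: exhaustive positive-negative pair concordance, ties counted 1/2."""
    pos = s[y == 1]
    neg = s[y == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return 100.0 * wins / (len(pos) * len(neg))


def confusion_by_hand(true, pred, order):
    k = len(order)
    conf = np.zeros((k, k), int)
    for t, p in zip(true, pred):
        conf[order.index(t), order.index(p)] += 1
    return conf


class TestBinary:
    def test_perfect_scores(self):
        y = np.array([1, 1, 0, 0])
        rep = binary_metrics(y, np.array([1.0, 1.0, 0.0, 0.0]))
        assert (rep.sensitivity, rep.specificity, rep.accuracy, rep.auc) == (
            100.0, 100.0, 100.0, 100.0,
        )

    def test_half_concordant_example(self):
        y = np.array([1, 1, 0, 0])
        s = np.array([0.9, 0.4, 0.6, 0.1])
        rep = binary_metrics(y, s)
        assert rep.sensitivity == 50.0
        assert rep.specificity == 50.0
        assert rep.accuracy == 50.0
        assert rep.auc == pytest.approx(75.0)  # 3 of 4 pairs ordered correctly

    def test_all_tied_scores_give_chance_auc(self):
        y = np.array([1, 0, 1, 0, 1])
        rep = binary_metrics(y, np.full(5, 0.5))
        assert rep.auc == pytest.approx(50.0)

    def test_trapezoid_equals_pairwise_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(4, 51)
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            s = np.round(rng.uniform(0, 1, n), 2)  # rounding forces ties
            rep = binary_metrics(y, s)
            assert rep.auc == pytest.approx(pairwise_auc(y, s), abs=1e-9)

    def test_roc_monotone(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        rep = binary_metrics(y, rng.uniform(0, 1, 60))
        fpr, tpr = np.array(rep.roc_points).T
        assert np.all(np.diff(fpr) >= 0)
        assert np.all(np.diff(tpr) >= 0)

    def test_single_class_auc_undefined(self):
        with pytest.warns(UserWarning, match="AUC undefined"):
            rep = binary_metrics(np.ones(5, int), np.full(5, 0.9))
        assert rep.auc is None
        assert rep.sensitivity == 100.0


class TestMulticlass:
    ORDER = ("temporal", "occipital", NON_IED)

    def test_all_correct(self):
        true = ["temporal"] * 5 + ["occipital"] * 5 + [NON_IED] * 5
        rep = multiclass_metrics(true, true, self.ORDER)
        assert rep.accuracy == 100.0
        assert all(v == 100.0 for v in rep.f1.values())
        assert np.all(np.diag(rep.confusion) == 5)
        assert rep.confusion.sum() == 15

    def test_known_recall_from_count_pattern(self):
        # 650 true temporal epochs: 223 called temporal, 184 occipital, 243 non
        true = ["temporal"] * 650
        pred = ["temporal"] * 223 + ["occipital"] * 184 + [NON_IED] * 243
        rep = multiclass_metrics(true, pred, self.ORDER)
        assert round(rep.recall["temporal"], 1) == 34.3

    def test_matches_hand_computation(self):
        rng = np.random.default_rng(2)
        order = self.ORDER
        for _ in range(20):
            n = rng.integers(6, 40)
            true = [order[i] for i in rng.integers(0, 3, n)]
            pred = [order[i] for i in rng.integers(0, 3, n)]
            rep = multiclass_metrics(true, pred, order)
            conf = confusion_by_hand(true, pred, list(order))
            np.testing.assert_array_equal(rep.confusion, conf)
            for k, cls in enumerate(order):
                col, row = conf[:, k].sum(), conf[k].sum()
                p = conf[k, k] / col if col else 0.0
                r = conf[k, k] / row if row else 0.0
                assert rep.precision[cls] == pytest.approx(100 * p)
                assert rep.recall[cls] == pytest.approx(100 * r)
                f1 = 2 * p * r / (p + r) if p + r else 0.0
                assert rep.f1[cls] == pytest.approx(100 * f1)
            assert rep.accuracy == pytest.approx(100 * np.trace(conf) / n)

    def test_never_predicted_class_flagged(self):
        true = ["temporal", "occipital", NON_IED]
        pred = ["temporal", "temporal", "temporal"]
        rep = multiclass_metrics(true, pred, self.ORDER)
        assert rep.precision["occipital"] == 0.0
        assert "occipital" in rep.undefined_precision

    def test_label_outside_order_rejected(self):
        with pytest.raises(ContractError):
            multiclass_metrics(["frontal"], ["frontal"], self.ORDER)


class TestDetectionRate:
    def test_reference_count_patterns(self):
        # occipital patient: 1580 epochs, 1576 classified occipital
        pred = ["occipital"] * 1576 + [NON_IED] * 4
        res = detection_rate("occipital", pred, "occ-6")
        assert round(res.detection_rate, 1) == 99.7
        # temporal patient: 223 of 650 correct
        pred = ["temporal"] * 223 + ["occipital"] * 184 + [NON_IED] * 243
        assert round(detection_rate("temporal", pred).detection_rate, 1) == 34.3

    def test_all_correct_is_100(self):
        assert detection_rate("frontal", ["frontal"] * 7).detection_rate == 100.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            detection_rate("frontal", [])

    def test_equals_restricted_multiclass_recall(self):
        rng = np.random.default_rng(3)
        order = ("temporal", "occipital", NON_IED)
        pred = [order[i] for i in rng.integers(0, 3, 200)]
        res = detection_rate("occipital", pred)
        rep = multiclass_metrics(["occipital"] * 200, pred, order)
        assert res.detection_rate == pytest.approx(rep.recall["occipital"])

    def test_group_summary_reproduces_reference_means(self):
        """Mean/SD over the reference patient table's recomputed rates."""
        df = lopo_reference_frame()
        for region, mean, sd in (("temporal", 82.8, 22.6), ("occipital", 87.6, 15.2)):
            rows = df[df.region == region]
            results = [
                detection_rate(
                    region,
                    [region] * int(getattr(r, f"n_pred_{region}"))
                    + ["x"] * int(r.n_epochs - getattr(r, f"n_pred_{region}")),
                )
                for r in rows.itertuples()
            ]
            summary = summarize_detection_rates(results)
            assert round(summary["mean"], 1) == mean
            assert round(summary["sd"], 1) == sd


def _toy_patient(subject, region, n, seed, scale=40.0):
    """Epochs with a class-coded amplitude pattern so the task is learnable."""
    rng = np.random.default_rng(seed)
    offsets = {"temporal": 12, "occipital": 8}
    t = np.arange(300) / 200.0
    x = rng.normal(0, 10, (n, 19, 300))
    x += scale * np.sin(2 * np.pi * offsets[region] * t)
    return PatientEpochs(
        subject_id=subject,
        region=region,
        epochs=EpochSet(
            data=x.astype(np.float32),
            labels=np.array([region] * n, dtype=object),
            subject_ids=np.array([subject] * n, dtype=object),
            source_event_indices=np.arange(n),
            centers_s=np.zeros(n),
            uids=np.array([f"{subject}:e{i}" for i in range(n)], dtype=object),
        ),
    )


class TestLopo:
    def test_fold_structure_and_leakage(self):
        patients = [
            _toy_patient("T1", "temporal", 24, 1),
            _toy_patient("T2", "temporal", 24, 2),
            _toy_patient("O1", "occipital", 24, 3),
            _toy_patient("O2", "occipital", 24, 4),
        ]
        rng = np.random.default_rng(9)
        controls = EpochSet(
            data=rng.normal(0, 10, (48, 19, 300)).astype(np.float32),
            labels=np.array([NON_IED] * 48, dtype=object),
            subject_ids=np.array(["C"] * 48, dtype=object),
            source_event_indices=np.full(48, -1),
            centers_s=np.zeros(48),
            uids=np.array([f"C:n{i}" for i in range(48)], dtype=object),
        )
        folds, summary = lopo_cross_validation(
            patients,
            controls,
            ModelSpec(variant="cnn1d", n_classes=3, seed=0),
            TrainSpec(learning_rate=1e-3, max_epochs=2, seed=0),
            seed=0,
        )
        assert [f.subject_id for f in folds] == ["T1", "T2", "O1", "O2"]
        assert all(f.n_leaked_uids == 0 for f in folds)
        assert set(summary) == {"temporal", "occipital"}
        for region in summary:
            rates = [f.result.detection_rate for f in folds if f.region == region]
            assert summary[region]["mean"] == pytest.approx(np.mean(rates))
            assert summary[region]["n_patients"] == 2

    def test_single_patient_class_rejected(self):
        patients = [
            _toy_patient("T1", "temporal", 8, 1),
            _toy_patient("O1", "occipital", 8, 2),
            _toy_patient("O2", "occipital", 8, 3),
        ]
        controls = _toy_patient("C", "temporal", 8, 4).epochs
        with pytest.raises(ValueError, match="temporal"):
            lopo_cross_validation(
                patients, controls,
                ModelSpec(n_classes=3), TrainSpec(max_epochs=1),
            )


class TestTsne:
    def test_shape_and_determinism(self, rng):
        feats = rng.normal(0, 1, (120, 30))
        params = TSNEParams(perplexity=15.0, seed=3)
        a = tsne_embed(feats, params)
        b = tsne_embed(feats, params)
        assert a.shape == (120, 2)
        assert np.isfinite(a).all()
        np.testing.assert_array_equal(a, b)

    def test_separated_clusters_stay_separated(self, rng):
        a = rng.normal(0, 1, (100, 20))
        b = rng.normal(8, 1, (100, 20))
        feats = np.vstack([a, b])
        labels = np.array([0] * 100 + [1] * 100)
        coords = tsne_embed(feats, TSNEParams(perplexity=30.0, seed=0))
        from sklearn.metrics import silhouette_score

        assert silhouette_score(coords, labels) > 0.5

    def test_perplexity_bound(self, rng):
        with pytest.raises(ValueError):
            tsne_embed(rng.normal(0, 1, (10, 5)), TSNEParams(perplexity=30.0))

    def test_subsample_caps_classes(self, rng):
        feats = rng.normal(0, 1, (300, 4))
        labels = np.array(["a"] * 200 + ["b"] * 100, dtype=object)
        sub_f, sub_l = subsample_per_class(feats, labels, max_per_class=50, seed=1)
        assert (sub_l == "a").sum() == 50
        assert (sub_l == "b").sum() == 50
        assert sub_f.shape == (100, 4)
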