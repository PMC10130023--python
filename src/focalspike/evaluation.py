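"""Performance metrics, patient-level evaluation, and feature embedding.

Binary detectors are scored by sensitivity, specificity, accuracy (at a
decision threshold) and the threshold-free area under the ROC curve;
multiclass models by per-class precision/recall/F1 with a confusion matrix in
the fixed (frontal, temporal, occipital, non-IED) order; and patient-level
generalization by leave-one-patient-out cross-validation with a per-patient
*detection rate*: the fraction of a patient's discharge epochs classified as
that patient's true region.

All percentages are computed in double precision and reported on a 0-100
scale; rounding to one decimal is display-only.  AUC ties are counted 1/2
(Mann-Whitney convention), which the trapezoidal ROC area implements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.manifold import TSNE
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve

from .cnn import ModelSpec, TrainSpec, build_model, predict_labels, train
from .epoching import (
    CLASS_ORDER,
    NON_IED,
    DatasetSplits,
    EpochSet,
    EpochingConfig,
    split_dataset,
)
from .errors import ContractError


@dataclass
class BinaryReport:
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float | None
    roc_points: list[tuple[float, float]]
    threshold: float

    def __post_init__(self) -> None:
        for v in (self.sensitivity, self.specificity, self.accuracy):
            if not 0 <= v <= 100:
                raise ValueError("metrics must lie in [0, 100]")


@dataclass
class MulticlassReport:
    class_order: tuple[str, ...]
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    accuracy: float
    confusion: np.ndarray
    undefined_precision: tuple[str, ...] = ()

    def macro_f1(self) -> float:
        return float(np.mean([self.f1[c] for c in self.class_order]))


@dataclass
class PatientDetectionResult:
    subject_id: str
    n_epochs: int
    n_correct: int

    @property
    def detection_rate(self) -> float:
        return 100.0 * self.n_correct / self.n_epochs


def binary_metrics(
    true_labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> BinaryReport:
    """Threshold metrics plus trapezoidal ROC AUC for a binary detector.

    ``true_labels`` is 0/1 (1 = discharge present); ``scores`` in [0, 1] is the
    model's probability of the discharge class.  If only one class is present
    the AUC is undefined: a warning is emitted and ``auc`` is None while the
    threshold metrics are still returned.
    """
    y = np.asarray(true_labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.size == 0:
        raise ValueError("labels and scores must be equal-length and nonempty")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("true_labels must be binary 0/1")
    if s.min() < 0 or s.max() > 1:
        raise ValueError("scores must lie in [0, 1]")
    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    n_pos, n_neg = tp + fn, tn + fp
    sens = 100.0 * tp / n_pos if n_pos else 0.0
    spec = 100.0 * tn / n_neg if n_neg else 0.0
    acc = 100.0 * (tp + tn) / y.size
    if n_pos == 0 or n_neg == 0:
        warnings.warn("AUC undefined: only one class present in true_labels")
        return BinaryReport(sens, spec, acc, None, [], threshold)
    fpr, tpr, _ = _sk_roc_curve(y, s)
    auc = 100.0 * float(np.trapezoid(tpr, fpr))
    return BinaryReport(
        sens, spec, acc, auc, list(zip(fpr.tolist(), tpr.tolist())), threshold
    )


def multiclass_metrics(
    true_labels, predicted_labels, class_order: tuple[str, ...]
) -> MulticlassReport:
    """Per-class one-vs-rest precision/recall/F1 plus the confusion matrix.

    The confusion matrix has rows = true class, columns = predicted class, in
    ``class_order``.  Precision of a never-predicted class is reported as 0
    and flagged in ``undefined_precision`` so F1 stays defined.
    """
    true_labels = np.asarray(true_labels, dtype=object)
    predicted_labels = np.asarray(predicted_labels, dtype=object)
    for name, arr in (("true", true_labels), ("predicted", predicted_labels)):
        outside = set(arr.tolist()) - set(class_order)
        if outside:
            raise ContractError(f"{name} labels {outside} outside class order")
    conf = _sk_confusion(true_labels, predicted_labels, labels=list(class_order))
    diag = np.diag(conf).astype(float)
    row_sums = conf.sum(axis=1).astype(float)
    col_sums = conf.sum(axis=0).astype(float)
    precision, recall, f1 = {}, {}, {}
    undefined = []
    for k, cls in enumerate(class_order):
        p = diag[k] / col_sums[k] if col_sums[k] else 0.0
        if col_sums[k] == 0:
            undefined.append(cls)
        r = diag[k] / row_sums[k] if row_sums[k] else 0.0
        precision[cls] = 100.0 * p
        recall[cls] = 100.0 * r
        f1[cls] = 100.0 * (2 * p * r / (p + r) if p + r else 0.0)
    accuracy = 100.0 * diag.sum() / conf.sum()
    return MulticlassReport(
        class_order=tuple(class_order),
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=float(accuracy),
        confusion=conf,
        undefined_precision=tuple(undefined),
    )


def detection_rate(
    true_region: str, predicted_labels, subject_id: str = ""
) -> PatientDetectionResult:
    """Per-patient detection rate: correctly-labeled discharge epochs over all.

    Equivalent to the recall of the patient's true class restricted to that
    patient's epochs.
    """
    predicted_labels = np.asarray(predicted_labels, dtype=object)
    if predicted_labels.size == 0:
        raise ValueError("detection rate of zero epochs is undefined")
    n_correct = int(np.sum(predicted_labels == true_region))
    return PatientDetectionResult(
        subject_id=subject_id, n_epochs=predicted_labels.size, n_correct=n_correct
    )


def summarize_detection_rates(
    results: list[PatientDetectionResult],
) -> dict[str, float]:
    """Mean and (sample) SD of per-patient detection rates."""
    rates = np.array([r.detection_rate for r in results], dtype=float)
    return {
        "n_patients": len(results),
        "mean": float(rates.mean()),
        "sd": float(rates.std(ddof=1)) if len(rates) > 1 else 0.0,
    }


@dataclass
class PatientEpochs:
    """One patient's augmented discharge epochs for patient-level evaluation."""

    subject_id: str
    region: str
    epochs: EpochSet


@dataclass
class LopoFold:
    subject_id: str
    region: str
    result: PatientDetectionResult
    n_leaked_uids: int
    best_epoch: int


def lopo_cross_validation(
    patients: list[PatientEpochs],
    control_epochs: EpochSet,
    model_spec: ModelSpec,
    train_spec: TrainSpec,
    val_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[list[LopoFold], dict[str, dict[str, float]]]:
    """Leave-one-patient-out cross-validation of a multiclass model.

    One fold per patient: the held-out patient contributes no epochs (original
    or jittered) to that fold's training or validation data; the remaining
    patients' discharge epochs plus the control-derived non-IED epochs are
    split into train/validation, a fresh model is trained, and the held-out
    patient's epochs are scored by detection rate.  Each fold also records the
    size of the intersection between held-out and training epoch identifiers,
    which must be zero.

    Returns the folds and per-region summaries (mean/SD of detection rates).
    """
    regions = {}
    for p in patients:
        regions.setdefault(p.region, []).append(p)
    for region, members in regions.items():
        if len(members) < 2:
            raise ValueError(
                f"region {region!r} has {len(members)} patient(s); "
                "leave-one-patient-out needs >= 2 per included class"
            )
    if len(control_epochs) == 0:
        raise ValueError("control (non-IED) epochs are required in every fold")
    split_cfg = EpochingConfig(
        split_ratios=(1 - val_fraction, val_fraction, 0.0), split_unit="event", seed=seed
    )
    folds: list[LopoFold] = []
    for held_out in patients:
        train_sets = [p.epochs for p in patients if p is not held_out]
        pool = EpochSet.concat(train_sets + [control_epochs])
        parts = split_dataset(pool, split_cfg)
        splits = DatasetSplits(train=parts.train, val=parts.val, test=parts.test)
        held_uids = set(held_out.epochs.uids.tolist())
        leaked = len(held_uids & set(parts.train.uids.tolist())) + len(
            held_uids & set(parts.val.uids.tolist())
        )
        model = train(build_model(model_spec), splits, train_spec)
        preds = predict_labels(model, held_out.epochs)
        result = detection_rate(held_out.region, preds, held_out.subject_id)
        folds.append(
            LopoFold(
                subject_id=held_out.subject_id,
                region=held_out.region,
                result=result,
                n_leaked_uids=leaked,
                best_epoch=model.best_epoch,
            )
        )
    summary = {
        region: summarize_detection_rates(
            [f.result for f in folds if f.region == region]
        )
        for region in regions
    }
    return folds, summary


@dataclass(frozen=True)
class TSNEParams:
    n_components: int = 2
    perplexity: float = 30.0
    early_exaggeration: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components != 2:
            raise ValueError("embedding is 2-dimensional by contract")
        if self.perplexity <= 0:
            raise ValueError("perplexity must be positive")


def tsne_embed(features: np.ndarray, params: TSNEParams | None = None) -> np.ndarray:
    """t-SNE embedding of flattened-layer features to 2 coordinates per epoch."""
    params = params or TSNEParams()
    features = np.asarray(features, dtype=float)
    if features.ndim != 2:
        raise ValueError("features must be (n_points, n_features)")
    if not np.isfinite(features).all():
        raise ValueError("features must be finite")
    if params.perplexity >= features.shape[0]:
        raise ValueError(
            f"perplexity {params.perplexity} must be < n_points {features.shape[0]}"
        )
    tsne = TSNE(
        n_components=params.n_components,
        perplexity=params.perplexity,
        early_exaggeration=params.early_exaggeration,
        random_state=params.seed,
        init="pca",
    )
    return tsne.fit_transform(features)


def subsample_per_class(
    features: np.ndarray,
    labels: np.ndarray,
    max_per_class: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly keep at most ``max_per_class`` points of each class."""
    labels = np.asarray(labels, dtype=object)
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for cls in sorted(set(labels.tolist()), key=str):
        idx = np.flatnonzero(labels == cls)
        if idx.size > max_per_class:
            idx = np.sort(rng.choice(idx, size=max_per_class, replace=False))
        keep.append(idx)
    order = np.sort(np.concatenate(keep))
    return features[order], labels[order]
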