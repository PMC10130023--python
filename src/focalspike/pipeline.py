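"""Config-driven orchestration: simulate -> preprocess -> epoch -> train -> evaluate.

A whole experiment is reproducible from a single integer: the run seed is
expanded through ``numpy.random.SeedSequence`` into per-stage seeds (cohort
simulation; jitter augmentation; non-IED sampling; class balancing; dataset
splitting; weight initialization; minibatch shuffling), in that fixed spawn
order.  Configs are plain dataclasses, so unknown keys in a YAML config raise
immediately instead of being silently ignored.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cnn import (
    ModelSpec,
    TrainSpec,
    build_model,
    extract_features,
    predict_labels,
    predict_proba,
    save_model,
    train,
)
from .epoching import (
    CLASS_ORDER,
    NON_IED,
    EpochSet,
    EpochingConfig,
    balance_classes,
    build_balanced_dataset,
    jitter_augment,
    sample_non_ied_epochs,
    split_dataset,
)
from .errors import FocalspikeError
from .evaluation import (
    TSNEParams,
    binary_metrics,
    multiclass_metrics,
    subsample_per_class,
    tsne_embed,
)
from .io import read_annotations, read_manifest, read_recording, save_cohort
from .preprocess import PreprocessConfig, preprocess
from .recording import AnnotationSet
from .synth import SubjectRecord, SynthCohortConfig, simulate_cohort

logger = logging.getLogger("focalspike")

#: Regions whose discharges constitute the positive class(es) of each task.
TASK_REGIONS: dict[str, tuple[str, ...]] = {
    "frontal": ("frontal",),
    "temporal": ("temporal",),
    "occipital": ("occipital",),
    "3class": ("temporal", "occipital"),
    "4class": ("frontal", "temporal", "occipital"),
}


def task_n_classes(task: str) -> int:
    return len(TASK_REGIONS[task]) + 1


def stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Derive ``n`` independent stage seeds (< 2**31) from one run seed."""
    return [
        int(child.generate_state(1)[0] % (2**31))
        for child in np.random.SeedSequence(seed).spawn(n)
    ]


def load_cohort_from_manifest(manifest_path: str | Path) -> list[SubjectRecord]:
    """Load a cohort written by :func:`focalspike.io.save_cohort`."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    subjects = []
    for entry in read_manifest(manifest_path):
        rec = read_recording(
            root / entry["edf"], subject_id=entry["subject_id"], group=entry["group"]
        )
        if entry.get("annotations"):
            ann = read_annotations(root / entry["annotations"])
        else:
            ann = AnnotationSet(recording_id=entry["subject_id"], events=[])
        subjects.append(
            SubjectRecord(
                recording=rec,
                annotations=ann,
                metadata={
                    "subject_id": entry["subject_id"],
                    "group": entry["group"],
                    "region": entry.get("region"),
                    "n_ieds": len(ann),
                },
            )
        )
    return subjects


def assemble_task_dataset(
    subjects: list[SubjectRecord],
    task: str,
    epoch_config: EpochingConfig | None = None,
    non_ied_source: str = "controls",
    seed: int = 0,
    pre_config: PreprocessConfig | None = None,
    already_preprocessed: bool = False,
):
    """Build balanced, split epoch data for one classification task.

    Discharge epochs come jitter-augmented from the task's patients; non-IED
    epochs come from control recordings (default) or from the patients' own
    recordings outside every discharge's epoch window
    (``non_ied_source='patients'``).  Binary tasks are balanced 1:1 against
    the augmented discharge count; multiclass tasks are balanced to the
    smallest class.  Returns ``(splits, class_order)``.
    """
    if task not in TASK_REGIONS:
        raise ValueError(f"unknown task {task!r}; expected one of {list(TASK_REGIONS)}")
    if non_ied_source not in ("controls", "patients"):
        raise ValueError("non_ied_source must be 'controls' or 'patients'")
    epoch_config = epoch_config or EpochingConfig()
    jit_seed, non_seed, bal_seed, split_seed = stage_seeds(seed, 4)
    regions = TASK_REGIONS[task]

    def prep(rec):
        return rec if already_preprocessed else preprocess(rec, pre_config)

    patients = [s for s in subjects if s.metadata["region"] in regions]
    controls = [s for s in subjects if s.metadata["group"] == "control"]
    if not patients:
        raise FocalspikeError(f"cohort has no patients for task {task!r}")

    ied_sets = []
    prepped_patients = []
    for i, s in enumerate(patients):
        rec = prep(s.recording)
        prepped_patients.append((rec, s.annotations))
        ied_sets.append(
            jitter_augment(rec, s.annotations, epoch_config, seed=jit_seed + i)
        )
    ied = EpochSet.concat(ied_sets)
    logger.info("task %s: %d augmented discharge epochs from %d patients",
                task, len(ied), len(patients))

    if non_ied_source == "controls":
        if not controls:
            raise FocalspikeError("non_ied_source='controls' but cohort has none")
        sources = [(prep(s.recording), None) for s in controls]
    else:
        sources = [(rec, ann) for rec, ann in prepped_patients]
    n_needed = math.ceil(len(ied) * 1.2)  # headroom for undersampling
    per_source = math.ceil(n_needed / len(sources))
    pool = EpochSet.concat(
        [
            sample_non_ied_epochs(rec, per_source, excl, epoch_config, seed=non_seed + i)
            for i, (rec, excl) in enumerate(sources)
        ]
    )
    logger.info("task %s: non-IED pool of %d epochs from %d %s recordings",
                task, len(pool), len(sources), non_ied_source)

    if len(regions) == 1:
        balanced = build_balanced_dataset(ied, pool, epoch_config, seed=bal_seed)
    else:
        balanced = balance_classes(EpochSet.concat([ied, pool]), seed=bal_seed)
    splits = split_dataset(balanced, epoch_config, seed=split_seed)
    class_order = tuple(c for c in CLASS_ORDER
                        if c in set(balanced.labels.astype(str).tolist()))
    logger.info("task %s: balanced dataset %s -> train/val/test %d/%d/%d",
                task, balanced.label_counts(),
                len(splits.train), len(splits.val), len(splits.test))
    return splits, class_order


@dataclass
class RunConfig:
    """One reproducible experiment: cohort, task, epoching, model, training."""

    out_dir: str
    task: str = "occipital"
    variant: str = "cnn1d"
    non_ied_source: str = "controls"
    seed: int = 0
    manifest: str | None = None
    cohort: SynthCohortConfig = field(default_factory=SynthCohortConfig)
    epoching: EpochingConfig = field(default_factory=EpochingConfig)
    train: TrainSpec = field(default_factory=TrainSpec)
    tsne: TSNEParams = field(default_factory=TSNEParams)
    embed_features: bool = False

    def __post_init__(self) -> None:
        if self.task not in TASK_REGIONS:
            raise ValueError(f"unknown task {self.task!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        kwargs = dict(doc)
        for key, typ in (
            ("cohort", SynthCohortConfig),
            ("epoching", EpochingConfig),
            ("train", TrainSpec),
            ("tsne", TSNEParams),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = typ(**kwargs[key])  # unknown keys raise TypeError
        return cls(**kwargs)

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        return plain(asdict(self))

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _report_to_dict(report) -> dict:
    doc = dataclasses.asdict(report)
    if "confusion" in doc:
        doc["confusion"] = np.asarray(doc["confusion"]).tolist()
    if "roc_points" in doc and len(doc["roc_points"]) > 200:
        doc["roc_points"] = doc["roc_points"][:: len(doc["roc_points"]) // 200 + 1]
    return doc


def run_pipeline(config: RunConfig) -> Path:
    """Execute one full experiment; returns the populated run directory.

    The run directory holds the resolved config snapshot (with hash), the
    model checkpoint, the training history, the metric report, and optionally
    the t-SNE embedding of test-epoch features.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        cohort_seed, data_seed, model_seed, shuffle_seed = stage_seeds(config.seed, 4)
        snapshot = config.to_dict()
        snapshot["config_hash"] = config.config_hash()
        with open(out / "config_snapshot.yaml", "w") as fh:
            yaml.safe_dump(snapshot, fh, sort_keys=False)

        if config.manifest:
            logger.info("stage cohort: loading manifest %s", config.manifest)
            subjects = load_cohort_from_manifest(config.manifest)
        else:
            cohort_cfg = dataclasses.replace(config.cohort, seed=cohort_seed)
            logger.info("stage cohort: simulating (seed %d)", cohort_seed)
            subjects = simulate_cohort(cohort_cfg)

        splits, class_order = assemble_task_dataset(
            subjects,
            config.task,
            config.epoching,
            non_ied_source=config.non_ied_source,
            seed=data_seed,
        )

        spec = ModelSpec(
            variant=config.variant,
            n_classes=task_n_classes(config.task),
            seed=model_seed,
        )
        train_spec = dataclasses.replace(config.train, seed=shuffle_seed)
        logger.info("stage train: %s, %d classes, %d train epochs",
                    spec.variant, spec.n_classes, train_spec.max_epochs)
        model = train(build_model(spec), splits, train_spec)
        save_model(model, out / "model")

        metrics: dict = {"task": config.task, "variant": config.variant,
                         "class_order": list(class_order),
                         "best_epoch": model.best_epoch}
        if len(class_order) == 2:
            probs = predict_proba(model, splits.test)
            ied_col = 1 - class_order.index(NON_IED)
            y_true = (splits.test.labels.astype(str) != NON_IED).astype(int)
            report = binary_metrics(y_true, probs[:, ied_col])
            metrics["binary"] = _report_to_dict(report)
        else:
            preds = predict_labels(model, splits.test)
            report = multiclass_metrics(
                splits.test.labels.astype(str), preds, class_order
            )
            metrics["multiclass"] = _report_to_dict(report)
        if config.embed_features:
            feats = extract_features(model, splits.test)
            feats, labels = subsample_per_class(
                feats, splits.test.labels, max_per_class=1000, seed=config.seed
            )
            coords = tsne_embed(feats, config.tsne)
            np.savetxt(
                out / "embedding.tsv",
                np.column_stack([coords, labels]).astype(object),
                fmt="%s",
                delimiter="\t",
                header="x\ty\tlabel",
                comments="",
            )
        with open(out / "metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=2)
        logger.info("run complete: %s", out)
        return out
    except Exception as err:  # surface the failing stage and config identity
        raise FocalspikeError(
            f"pipeline run {config.config_hash()} failed: {err}"
        ) from err
    finally:
        logger.removeHandler(handler)
        handler.close()
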