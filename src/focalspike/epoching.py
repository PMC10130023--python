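"""Labeled 1.5-s epoch construction.

An epoch is a 19 x 300 segment (1.5 s at 200 Hz) — the unit of classification.
Discharge epochs are centered on the annotation midpoint and span -0.75 s to
+0.75 s; augmentation jitters the center by up to +-50 ms (+-10 samples, with
the unjittered copy always retained); non-IED epochs are cut at random time
points, optionally excluding every discharge's epoch window; classes are
balanced 1:1 by undersampling; and datasets are split 6:2:2 into
train/validation/test, by default at the source-event level so jittered
near-duplicates of one discharge can never straddle a split boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import CapacityError, ContractError
from .montage import N_CHANNELS
from .recording import AnnotationSet, Recording

#: Fixed report/class order shared with the evaluation module.
CLASS_ORDER: tuple[str, ...] = ("frontal", "temporal", "occipital", "non_ied")
NON_IED = "non_ied"


@dataclass(frozen=True)
class EpochingConfig:
    epoch_len_s: float = 1.5
    half_span_s: float = 0.75
    jitter_max_s: float = 0.05
    augment_factor: int = 10
    balance_ratio: float = 1.0
    split_ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    split_unit: str = "event"
    fs: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.epoch_len_s - 2 * self.half_span_s) > 1e-9:
            raise ValueError("epoch_len_s must equal 2 * half_span_s")
        if self.jitter_max_s * self.fs < 1:
            raise ValueError("jitter_max_s must span at least one sample")
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValueError("split_ratios must sum to 1")
        if self.augment_factor < 1:
            raise ValueError("augment_factor must be >= 1")
        if self.split_unit not in ("event", "epoch"):
            raise ValueError("split_unit must be 'event' or 'epoch'")

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_len_s * self.fs))

    @property
    def jitter_max_samples(self) -> int:
        return int(round(self.jitter_max_s * self.fs))


@dataclass
class EpochSet:
    """A batch of labeled epochs with per-epoch provenance.

    ``data`` is ``(n, 19, n_samples)`` float32 in uV; ``source_event_indices``
    is -1 for non-IED epochs; ``uids`` identify epochs uniquely across a
    cohort (used for split-leakage checks).
    """

    data: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    source_event_indices: np.ndarray
    centers_s: np.ndarray
    uids: np.ndarray

    def __post_init__(self) -> None:
        n = self.data.shape[0]
        if self.data.ndim != 3 or self.data.shape[1] != N_CHANNELS:
            raise ValueError(f"epoch data must be (n, {N_CHANNELS}, L); got {self.data.shape}")
        for name in ("labels", "subject_ids", "source_event_indices", "centers_s", "uids"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")

    def __len__(self) -> int:
        return self.data.shape[0]

    @classmethod
    def empty(cls, n_samples: int) -> "EpochSet":
        return cls(
            data=np.empty((0, N_CHANNELS, n_samples), dtype=np.float32),
            labels=np.empty(0, dtype=object),
            subject_ids=np.empty(0, dtype=object),
            source_event_indices=np.empty(0, dtype=int),
            centers_s=np.empty(0, dtype=float),
            uids=np.empty(0, dtype=object),
        )

    @classmethod
    def concat(cls, sets: list["EpochSet"]) -> "EpochSet":
        sets = [s for s in sets if len(s)]
        if not sets:
            raise ValueError("cannot concatenate zero non-empty epoch sets")
        return cls(
            data=np.concatenate([s.data for s in sets]),
            labels=np.concatenate([s.labels for s in sets]),
            subject_ids=np.concatenate([s.subject_ids for s in sets]),
            source_event_indices=np.concatenate([s.source_event_indices for s in sets]),
            centers_s=np.concatenate([s.centers_s for s in sets]),
            uids=np.concatenate([s.uids for s in sets]),
        )

    def subset(self, idx) -> "EpochSet":
        idx = np.asarray(idx)
        return EpochSet(
            data=self.data[idx],
            labels=self.labels[idx],
            subject_ids=self.subject_ids[idx],
            source_event_indices=self.source_event_indices[idx],
            centers_s=self.centers_s[idx],
            uids=self.uids[idx],
        )

    def label_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def to_xy(self, class_order: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
        """Data tensor and integer labels in the given class order."""
        index = {c: i for i, c in enumerate(class_order)}
        unknown = set(self.labels.astype(str)) - set(class_order)
        if unknown:
            raise ContractError(f"labels {unknown} not in class order {class_order}")
        y = np.array([index[l] for l in self.labels], dtype=int)
        return self.data.astype(np.float32, copy=False), y


def _make_set(data, labels, subjects, sources, centers, uids, n_samples) -> EpochSet:
    if not data:
        return EpochSet.empty(n_samples)
    return EpochSet(
        data=np.stack(data).astype(np.float32),
        labels=np.array(labels, dtype=object),
        subject_ids=np.array(subjects, dtype=object),
        source_event_indices=np.array(sources, dtype=int),
        centers_s=np.array(centers, dtype=float),
        uids=np.array(uids, dtype=object),
    )


def _check_fs(recording: Recording, config: EpochingConfig) -> None:
    if abs(recording.fs - config.fs) > 1e-9:
        raise ContractError(
            f"epoching expects fs {config.fs}, got {recording.fs}; resample first"
        )


def extract_ied_epochs(
    recording: Recording,
    annotations: AnnotationSet,
    config: EpochingConfig | None = None,
) -> EpochSet:
    """One epoch per annotation, centered on the annotation midpoint.

    Events whose full window does not fit inside the recording are skipped
    with a warning.
    """
    config = config or EpochingConfig()
    _check_fs(recording, config)
    n_len = config.n_samples
    fs = config.fs
    data, labels, subjects, sources, centers, uids = [], [], [], [], [], []
    for idx, ev in enumerate(annotations):
        start = int(round((ev.center_s - config.half_span_s) * fs))
        if start < 0 or start + n_len > recording.n_samples:
            warnings.warn(
                f"{recording.subject_id}: event {idx} at {ev.center_s:.2f}s "
                "has no full epoch window; skipped"
            )
            continue
        data.append(recording.signal[:, start:start + n_len])
        labels.append(ev.region)
        subjects.append(recording.subject_id)
        sources.append(idx)
        centers.append(ev.center_s)
        uids.append(f"{recording.subject_id}:e{idx}:j0")
    return _make_set(data, labels, subjects, sources, centers, uids, n_len)


def jitter_augment(
    recording: Recording,
    annotations: AnnotationSet,
    config: EpochingConfig | None = None,
    seed: int | None = None,
) -> EpochSet:
    """``augment_factor`` epochs per annotation, jittered by <= +-50 ms.

    Jitter offsets are integer samples drawn uniformly from
    ``[-jitter_max, +jitter_max]``; the first copy is always unjittered, so
    ``augment_factor=1`` reproduces :func:`extract_ied_epochs`.  Shifts that
    would push the window outside the recording are clamped (with a warning).
    """
    config = config or EpochingConfig()
    _check_fs(recording, config)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_len, fs, jmax = config.n_samples, config.fs, config.jitter_max_samples
    data, labels, subjects, sources, centers, uids = [], [], [], [], [], []
    for idx, ev in enumerate(annotations):
        base = int(round((ev.center_s - config.half_span_s) * fs))
        if base < 0 or base + n_len > recording.n_samples:
            warnings.warn(
                f"{recording.subject_id}: event {idx} at {ev.center_s:.2f}s "
                "has no full epoch window; skipped"
            )
            continue
        shifts = rng.integers(-jmax, jmax + 1, size=config.augment_factor)
        shifts[0] = 0
        for k, delta in enumerate(shifts):
            start = base + int(delta)
            clamped = min(max(start, 0), recording.n_samples - n_len)
            if clamped != start:
                warnings.warn(
                    f"{recording.subject_id}: event {idx} jitter {delta:+d} "
                    "clamped at recording edge"
                )
                delta = clamped - base
                start = clamped
            data.append(recording.signal[:, start:start + n_len])
            labels.append(ev.region)
            subjects.append(recording.subject_id)
            sources.append(idx)
            centers.append(ev.center_s + delta / fs)
            uids.append(f"{recording.subject_id}:e{idx}:j{k}")
    return _make_set(data, labels, subjects, sources, centers, uids, n_len)


def sample_non_ied_epochs(
    recording: Recording,
    n: int,
    exclusion: AnnotationSet | None = None,
    config: EpochingConfig | None = None,
    seed: int | None = None,
) -> EpochSet:
    """``n`` epochs at random time points, labeled non-IED.

    With an exclusion set, no sampled window overlaps any excluded event's
    1.5-s epoch window (window starts are drawn without replacement from the
    allowed sample positions).
    """
    config = config or EpochingConfig()
    _check_fs(recording, config)
    if n < 0:
        raise ValueError("n must be >= 0")
    n_len, fs = config.n_samples, config.fs
    n_starts = recording.n_samples - n_len + 1
    if n_starts <= 0:
        raise CapacityError("recording shorter than one epoch")
    allowed = np.ones(n_starts, dtype=bool)
    if exclusion is not None:
        for ev in exclusion:
            w = int(round((ev.center_s - config.half_span_s) * fs))
            lo = max(w - n_len + 1, 0)
            hi = min(w + n_len, n_starts)
            if hi > lo:
                allowed[lo:hi] = False
    candidates = np.flatnonzero(allowed)
    if candidates.size < n:
        raise CapacityError(
            f"requested {n} non-IED epochs but only {candidates.size} "
            f"window positions are available in {recording.subject_id}"
        )
    rng = np.random.default_rng(config.seed if seed is None else seed)
    starts = np.sort(rng.choice(candidates, size=n, replace=False))
    data = [recording.signal[:, s:s + n_len] for s in starts]
    centers = [(s + n_len / 2) / fs for s in starts]
    uids = [f"{recording.subject_id}:n{s}" for s in starts]
    return _make_set(
        data,
        [NON_IED] * n,
        [recording.subject_id] * n,
        [-1] * n,
        centers,
        uids,
        n_len,
    )


def build_balanced_dataset(
    ied_epochs: EpochSet,
    non_ied_pool: EpochSet,
    config: EpochingConfig | None = None,
    seed: int | None = None,
) -> EpochSet:
    """IED epochs plus an equal number of undersampled non-IED epochs (1:1)."""
    config = config or EpochingConfig()
    n_needed = int(round(len(ied_epochs) * config.balance_ratio))
    if len(non_ied_pool) < n_needed:
        raise CapacityError(
            f"non-IED pool has {len(non_ied_pool)} epochs; "
            f"{n_needed} needed (shortfall {n_needed - len(non_ied_pool)})"
        )
    rng = np.random.default_rng(config.seed if seed is None else seed)
    keep = np.sort(rng.choice(len(non_ied_pool), size=n_needed, replace=False))
    return EpochSet.concat([ied_epochs, non_ied_pool.subset(keep)])


def balance_classes(epochs: EpochSet, seed: int = 0) -> EpochSet:
    """Undersample every class to the size of the smallest class."""
    counts = epochs.label_counts()
    target = min(counts.values())
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for label in counts:
        idx = np.flatnonzero(epochs.labels.astype(str) == label)
        keep.append(np.sort(rng.choice(idx, size=target, replace=False)))
    return epochs.subset(np.sort(np.concatenate(keep)))


@dataclass
class DatasetSplits:
    train: EpochSet
    val: EpochSet
    test: EpochSet


def _split_counts(n: int, ratios: tuple[float, float, float]) -> tuple[int, int, int]:
    n_train = int(round(n * ratios[0]))
    n_val = int(round(n * ratios[1]))
    n_val = min(n_val, n - n_train)
    return n_train, n_val, n - n_train - n_val


def split_dataset(
    epochs: EpochSet, config: EpochingConfig | None = None, seed: int | None = None
) -> DatasetSplits:
    """Random stratified 6:2:2 split into train/validation/test.

    With ``split_unit='event'`` (default) all augmented copies of one source
    event are kept in a single split, which prevents jittered near-duplicates
    from leaking across the train/test boundary; ``split_unit='epoch'`` splits
    at the individual-epoch level.
    """
    config = config or EpochingConfig()
    if len(epochs) < 3:
        raise ValueError("need at least 3 epochs to split")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    assign = np.full(len(epochs), -1, dtype=int)
    labels = epochs.labels.astype(str)
    for label in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == label)
        if config.split_unit == "epoch":
            perm = rng.permutation(idx)
            n_tr, n_va, _ = _split_counts(idx.size, config.split_ratios)
            assign[perm[:n_tr]] = 0
            assign[perm[n_tr:n_tr + n_va]] = 1
            assign[perm[n_tr + n_va:]] = 2
        else:
            # group epochs by source event (non-IED epochs are singleton groups)
            keys = [
                (epochs.subject_ids[i], int(epochs.source_event_indices[i]), i)
                for i in idx
            ]
            groups: dict[tuple, list[int]] = {}
            for sid, src, i in keys:
                gk = (sid, src) if src >= 0 else (sid, src, i)
                groups.setdefault(gk, []).append(i)
            order = rng.permutation(len(groups))
            group_list = [groups[k] for k in sorted(groups, key=str)]
            targets = np.array(config.split_ratios) * idx.size
            filled = np.zeros(3)
            for gi in order:
                members = group_list[gi]
                # put the group where the relative deficit is largest;
                # zero-ratio splits never receive epochs
                deficit = np.where(
                    targets > 0, (targets - filled) / np.maximum(targets, 1e-9), -np.inf
                )
                split = int(np.argmax(deficit))
                assign[members] = split
                filled[split] += len(members)
    return DatasetSplits(
        train=epochs.subset(np.flatnonzero(assign == 0)),
        val=epochs.subset(np.flatnonzero(assign == 1)),
        test=epochs.subset(np.flatnonzero(assign == 2)),
    )
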