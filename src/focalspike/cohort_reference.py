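"""Published summary statistics of the reference clinical cohort.

The pipeline's defaults and its validation arithmetic are anchored to a
single-center cohort of 38 patients with focal epilepsy (15 frontal, 13
temporal, 10 occipital) and 232 controls, recorded on 19-channel 200 Hz
scalp EEG.  The clinical recordings themselves are not distributable; what
is distributable are the printed summary tables: per-region annotated IED
totals, per-class epoch counts of the multiclass experiments, and the
patient-level leave-one-patient-out table of epoch counts and per-class
classification counts.  Those counts are stored here verbatim and every
derived quantity (rates, means, SDs) is recomputed from them by the
evaluation code.
"""

from __future__ import annotations

import pandas as pd

#: Number of patients contributing IEDs to each region.
PATIENTS_PER_REGION: dict[str, int] = {"frontal": 15, "temporal": 13, "occipital": 10}

N_CONTROLS = 232

#: Total annotated IEDs per region across all patients.
IEDS_PER_REGION: dict[str, int] = {"frontal": 2112, "temporal": 1176, "occipital": 1269}

#: Reported per-recording IED count mean +- SD per region.
IED_COUNT_MEAN_SD: dict[str, tuple[float, float]] = {
    "frontal": (141.0, 129.0),
    "temporal": (90.0, 99.0),
    "occipital": (127.0, 68.0),
}

#: Reported mean discharge durations (seconds) per region.
MEAN_IED_DURATION_S: dict[str, float] = {
    "frontal": 0.45,
    "temporal": 0.52,
    "occipital": 0.48,
}

#: Epoch counts per class entering the three- and four-class experiments.
MULTICLASS_EPOCH_COUNTS: dict[str, int] = {
    "frontal": 10560,
    "temporal": 11439,
    "occipital": 10575,
    "non_ied": 10695,
}

THREE_CLASS_CLASSES = ("temporal", "occipital", "non_ied")
FOUR_CLASS_CLASSES = ("frontal", "temporal", "occipital", "non_ied")

#: Patient-level leave-one-patient-out table for the 2D three-class model:
#: per subject, total focal IED epochs and how many the model classified as
#: temporal / occipital / non-IED.  Detection rates are *not* stored; they
#: are recomputed from these counts.
_LOPO_COLUMNS = [
    "region", "subject_no", "age_years", "sex",
    "n_ieds", "n_epochs", "n_pred_temporal", "n_pred_occipital", "n_pred_non_ied",
]

_LOPO_ROWS = [
    ("temporal", 1, 17, "F", 189, 1890, 1827, 9, 54),
    ("temporal", 2, 11, "M", 65, 650, 223, 184, 243),
    ("temporal", 3, 7, "M", 15, 150, 61, 32, 57),
    ("temporal", 4, 18, "M", 20, 200, 194, 0, 6),
    ("temporal", 5, 63, "M", 345, 3440, 2394, 6, 1040),
    ("temporal", 6, 39, "M", 108, 1080, 943, 1, 136),
    ("temporal", 7, 31, "M", 210, 2100, 1867, 209, 24),
    ("temporal", 8, 63, "F", 39, 390, 390, 0, 0),
    ("temporal", 9, 51, "F", 40, 400, 363, 26, 11),
    ("temporal", 10, 63, "F", 11, 110, 110, 0, 0),
    ("temporal", 11, 45, "F", 52, 520, 520, 0, 0),
    ("temporal", 12, 25, "F", 50, 500, 358, 142, 0),
    ("temporal", 13, 26, "F", 32, 320, 320, 0, 0),
    ("occipital", 1, 14, "F", 86, 860, 46, 421, 393),
    ("occipital", 2, 13, "F", 90, 900, 43, 726, 131),
    ("occipital", 3, 9, "F", 281, 2810, 12, 2661, 137),
    ("occipital", 4, 16, "F", 167, 1670, 172, 1411, 87),
    ("occipital", 5, 17, "F", 159, 1600, 89, 1448, 63),
    ("occipital", 6, 12, "M", 158, 1580, 0, 1576, 4),
    ("occipital", 7, 11, "M", 127, 1280, 0, 1280, 0),
    ("occipital", 8, 10, "M", 57, 570, 7, 563, 0),
    ("occipital", 9, 16, "M", 89, 890, 56, 834, 0),
    ("occipital", 10, 14, "M", 55, 550, 0, 465, 85),
]


def lopo_reference_frame() -> pd.DataFrame:
    """The patient-level evaluation table as a DataFrame (counts only)."""
    return pd.DataFrame(_LOPO_ROWS, columns=_LOPO_COLUMNS)


def total_ied_count() -> int:
    """Total annotated IEDs summed over the three regions."""
    return sum(IEDS_PER_REGION.values())


def mean_ieds_per_recording(region: str) -> float:
    """Mean IED count per recording: region total over region patient count."""
    return IEDS_PER_REGION[region] / PATIENTS_PER_REGION[region]


def multiclass_epoch_total(classes: tuple[str, ...]) -> int:
    """Total epochs entering a multiclass experiment over the given classes."""
    return sum(MULTICLASS_EPOCH_COUNTS[c] for c in classes)
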