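"""EDF and annotation-table I/O.

Signals travel as EDF (European Data Format, 16-bit, physical units uV);
annotations as TSV with columns ``subject_id, region, onset_s, offset_s``;
cohorts as a YAML manifest mapping subject ids to files and group labels.

Reading EDF goes through :mod:`mne`; writing uses a small format-level writer
(one-second data records, per-channel physical scaling).  Because EDF stores
whole data records, recordings whose length is not a multiple of the record
length are zero-padded on write; the true sample count is stored in the
recording-id header field and used to trim on read, making the round trip
lossless up to 16-bit quantization.
"""

from __future__ import annotations

import datetime as _dt
import re
from pathlib import Path
from typing import Sequence

import mne
import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .montage import CANONICAL_CHANNELS, normalize_channel_name
from .recording import AnnotationSet, IEDAnnotation, Recording

_EDF_DIG_MAX = 32767
_NS_TAG = re.compile(r"ns=(\d+)")


def _edf_field(value, width: int) -> bytes:
    s = f"{value:.8g}" if isinstance(value, float) else str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(
    signals: np.ndarray,
    labels: Sequence[str],
    fs: float,
    path: str | Path,
    recording_id: str = "",
    physical_dim: str = "uV",
) -> None:
    """Low-level EDF writer for an arbitrary channel set.

    ``signals`` is ``(n_channels, n_samples)`` in ``physical_dim`` units; the
    sampling rate must be a positive integer (one-second data records).
    """
    signals = np.asarray(signals, dtype=float)
    if signals.ndim != 2 or signals.shape[1] == 0:
        raise ValueError("signals must be (n_channels, n_samples) with samples")
    if fs <= 0 or abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    fs_i = int(round(fs))
    n_ch, n_samples = signals.shape
    n_records = -(-n_samples // fs_i)  # ceil
    padded = np.zeros((n_ch, n_records * fs_i))
    padded[:, :n_samples] = signals

    phys_max = np.maximum(np.abs(padded).max(axis=1), 1e-6)
    scale = phys_max / _EDF_DIG_MAX
    digital = np.round(padded / scale[:, None]).astype("<i2")

    rid = f"{recording_id} ns={n_samples}".strip()
    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("X X X X", 80),
            _edf_field(rid, 80),
            _edf_field(now.strftime("%d.%m.%y"), 8),
            _edf_field(now.strftime("%H.%M.%S"), 8),
            _edf_field(256 * (n_ch + 1), 8),
            _edf_field("", 44),
            _edf_field(n_records, 8),
            _edf_field(1, 8),
            _edf_field(n_ch, 4),
        ]
    )
    sig_headers = b"".join(
        [
            b"".join(_edf_field(lbl, 16) for lbl in labels),
            b"".join(_edf_field("", 80) for _ in labels),
            b"".join(_edf_field(physical_dim, 8) for _ in labels),
            b"".join(_edf_field(float(-m), 8) for m in phys_max),
            b"".join(_edf_field(float(m), 8) for m in phys_max),
            b"".join(_edf_field(-_EDF_DIG_MAX, 8) for _ in labels),
            b"".join(_edf_field(_EDF_DIG_MAX, 8) for _ in labels),
            b"".join(_edf_field("", 80) for _ in labels),
            b"".join(_edf_field(fs_i, 8) for _ in labels),
            b"".join(_edf_field("", 32) for _ in labels),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_headers)
        # records: per record, all samples of ch0, then ch1, ...
        recs = digital.reshape(n_ch, n_records, fs_i).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(recs).tobytes())


def write_recording(recording: Recording, path: str | Path) -> None:
    """Write a canonical 19-channel Recording as a standard EDF file in uV."""
    write_edf(
        recording.signal,
        recording.channel_names,
        recording.fs,
        path,
        recording_id=recording.subject_id,
    )


def _read_true_n_samples(path: Path) -> int | None:
    with open(path, "rb") as fh:
        fh.seek(88)
        rid = fh.read(80).decode("ascii", errors="replace")
    m = _NS_TAG.search(rid)
    return int(m.group(1)) if m else None


def read_recording(
    path: str | Path,
    subject_id: str | None = None,
    group: str = "patient",
) -> Recording:
    """Read an EDF file and normalize it to the canonical 19-channel montage.

    Channel labels are matched case-insensitively, 'EEG ' prefixes and
    reference suffixes are stripped, and the modern temporal-row aliases
    (T7/T8/P7/P8) are mapped to T3/T4/T5/T6.  Extra channels (ECG, EOG, ...)
    are dropped; a missing canonical channel raises :class:`SchemaError`
    naming the absent channels.
    """
    path = Path(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    found: dict[str, int] = {}
    for i, ch in enumerate(raw.ch_names):
        canon = normalize_channel_name(ch)
        if canon is not None and canon not in found:
            found[canon] = i
    missing = [c for c in CANONICAL_CHANNELS if c not in found]
    if missing:
        raise SchemaError(f"EDF {path.name} lacks canonical channels: {missing}")
    data = raw.get_data() * 1e6  # mne returns volts for uV-dimensioned signals
    sig = np.stack([data[found[c]] for c in CANONICAL_CHANNELS])
    n_true = _read_true_n_samples(path)
    if n_true is not None and n_true <= sig.shape[1]:
        sig = sig[:, :n_true]
    return Recording(
        subject_id=subject_id or path.stem,
        signal=sig,
        fs=float(raw.info["sfreq"]),
        group=group,
    )


_ANNOTATION_COLUMNS = ["subject_id", "region", "onset_s", "offset_s"]


def write_annotations(annotations: AnnotationSet, path: str | Path) -> None:
    """Write an AnnotationSet as a TSV with the canonical four-column schema."""
    rows = [
        {
            "subject_id": annotations.recording_id,
            "region": ev.region,
            "onset_s": ev.onset_s,
            "offset_s": ev.offset_s,
        }
        for ev in annotations
    ]
    pd.DataFrame(rows, columns=_ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read and validate an annotation TSV; events come back sorted by onset."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"annotation TSV lacks columns: {missing}")
    events = []
    recording_id = str(df["subject_id"].iloc[0]) if len(df) else Path(path).stem
    for row_no, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        if row.region not in ("frontal", "temporal", "occipital"):
            raise SchemaError(
                f"row {row_no}: unknown region {row.region!r} "
                "(only frontal/temporal/occipital are modeled)"
            )
        if not row.offset_s > row.onset_s:
            raise ValueError(
                f"row {row_no}: offset_s ({row.offset_s}) must exceed "
                f"onset_s ({row.onset_s})"
            )
        events.append(
            IEDAnnotation(
                region=row.region,
                onset_s=float(row.onset_s),
                offset_s=float(row.offset_s),
            )
        )
    return AnnotationSet(recording_id=recording_id, events=events)


def write_manifest(entries: list[dict], path: str | Path) -> None:
    """Write a cohort manifest YAML (subject_id -> edf/annotations/group)."""
    with open(path, "w") as fh:
        yaml.safe_dump({"subjects": entries}, fh, sort_keys=False)


def read_manifest(path: str | Path) -> list[dict]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "subjects" not in doc:
        raise SchemaError("manifest must contain a top-level 'subjects' list")
    entries = doc["subjects"]
    for e in entries:
        for key in ("subject_id", "edf", "group"):
            if key not in e:
                raise SchemaError(f"manifest entry missing key {key!r}: {e}")
    return entries


def save_cohort(subjects, out_dir: str | Path) -> Path:
    """Write a simulated cohort (EDF + TSV per subject) and its manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for s in subjects:
        sid = s.metadata["subject_id"]
        edf_path = out / f"{sid}.edf"
        write_recording(s.recording, edf_path)
        entry = {
            "subject_id": sid,
            "edf": edf_path.name,
            "group": s.metadata["group"],
            "region": s.metadata["region"],
        }
        if len(s.annotations):
            tsv_path = out / f"{sid}_annotations.tsv"
            write_annotations(s.annotations, tsv_path)
            entry["annotations"] = tsv_path.name
        entries.append(entry)
    write_manifest(entries, out / "manifest.yaml")
    return out / "manifest.yaml"
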