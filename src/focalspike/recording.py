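"""In-memory containers: multichannel recordings and IED annotations."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .montage import CANONICAL_CHANNELS, N_CHANNELS, REGIONS

#: Envelope of plausible single-discharge durations (seconds); annotations
#: outside it are accepted with a warning.
DURATION_ENVELOPE_S = (0.1, 3.0)


@dataclass
class Recording:
    """One subject's 19-channel scalp EEG in microvolts.

    Channels are always in the canonical 10-20 order of
    :data:`focalspike.montage.CANONICAL_CHANNELS`; ``signal`` has shape
    ``(19, n_samples)``.
    """

    subject_id: str
    signal: np.ndarray
    fs: float
    channel_names: tuple[str, ...] = CANONICAL_CHANNELS
    group: str = "patient"
    age_years: float | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        if sig.ndim != 2 or sig.shape[0] != N_CHANNELS:
            raise ValueError(f"signal must be ({N_CHANNELS}, n_samples); got {sig.shape}")
        if sig.shape[1] == 0:
            raise ValueError("signal must contain at least one sample")
        if not np.isfinite(sig).all():
            raise ValueError("signal contains non-finite samples")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if tuple(self.channel_names) != CANONICAL_CHANNELS:
            raise ValueError("channel_names must be the canonical 10-20 order")
        if self.group not in ("patient", "control"):
            raise ValueError(f"group must be 'patient' or 'control', got {self.group!r}")
        self.signal = sig
        self.channel_names = tuple(self.channel_names)

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "Recording":
        return replace(self, signal=self.signal.copy())

    def channel(self, name: str) -> np.ndarray:
        return self.signal[self.channel_names.index(name)]


@dataclass(frozen=True)
class IEDAnnotation:
    """One annotated interictal discharge: region label plus [onset, offset) seconds."""

    region: str
    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}; expected one of {REGIONS}")
        if not 0 <= self.onset_s < self.offset_s:
            raise ValueError(
                f"need 0 <= onset < offset, got [{self.onset_s}, {self.offset_s})"
            )
        dur = self.offset_s - self.onset_s
        lo, hi = DURATION_ENVELOPE_S
        if not lo <= dur <= hi:
            warnings.warn(
                f"IED duration {dur:.3f}s outside the typical [{lo}, {hi}]s envelope",
                stacklevel=3,
            )

    @property
    def center_s(self) -> float:
        return 0.5 * (self.onset_s + self.offset_s)

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class AnnotationSet:
    """All annotated IEDs of one recording, sorted by onset."""

    recording_id: str
    events: list[IEDAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.onset_s, e.offset_s))

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __getitem__(self, i: int) -> IEDAnnotation:
        return self.events[i]

    def regions(self) -> set[str]:
        return {e.region for e in self.events}

    def validate_against(self, recording: Recording) -> None:
        """Check every event lies inside the recording."""
        for i, ev in enumerate(self.events):
            if ev.offset_s > recording.duration_s + 1e-9:
                raise ValueError(
                    f"event {i} offset {ev.offset_s:.3f}s exceeds recording "
                    f"duration {recording.duration_s:.3f}s"
                )
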