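"""Canonical 19-channel 10-20 montage shared by every module.

The channel order below is the package-wide single source of truth: the
simulator writes it, the EDF reader normalizes to it, and the 2D network's
row semantics depend on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical order of the 19 scalp electrodes of the international 10-20 system.
CANONICAL_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
)

N_CHANNELS = len(CANONICAL_CHANNELS)

#: Modern 10-10 names mapped back to the classic temporal-row labels.
CHANNEL_ALIASES: dict[str, str] = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}

REGIONS: tuple[str, ...] = ("frontal", "temporal", "occipital")

#: Electrode groups over which each focal region expresses its discharges.
REGION_CHANNELS: dict[str, tuple[str, ...]] = {
    "frontal": ("Fp1", "Fp2", "F3", "F4", "F7", "F8"),
    "temporal": ("F7", "F8", "T3", "T4", "T5", "T6"),
    "occipital": ("O1", "O2", "T5", "T6", "P3", "P4"),
}

#: Channels where the discharge is strongest within each region group.
_REGION_PEAKS: dict[str, tuple[str, ...]] = {
    "frontal": ("Fp1", "Fp2"),
    "temporal": ("T3", "T4"),
    "occipital": ("O1", "O2"),
}

_LEAKAGE_WEIGHT = 0.1      # far-field weight outside the region group
_IN_GROUP_WEIGHT = 0.7     # non-peak members of the region group


def channel_index(name: str) -> int:
    """Index of a canonical channel name in :data:`CANONICAL_CHANNELS`."""
    return CANONICAL_CHANNELS.index(name)


def normalize_channel_name(raw: str) -> str | None:
    """Map a raw EDF label to its canonical channel name, or None.

    Accepts case differences, 'EEG ' prefixes, reference suffixes
    (``-REF``, ``-LE``, ``-AVG``) and the T7/T8/P7/P8 aliases.
    """
    name = raw.strip()
    for prefix in ("EEG ", "eeg "):
        if name.startswith(prefix):
            name = name[len(prefix):]
    for suffix in ("-REF", "-Ref", "-ref", "-LE", "-le", "-AVG", "-avg"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
    lowered = name.strip().lower()
    table = {c.lower(): c for c in CANONICAL_CHANNELS}
    table.update({a.lower(): c for a, c in CHANNEL_ALIASES.items()})
    return table.get(lowered)


@dataclass(frozen=True)
class RegionTopography:
    """Per-channel scalar weights in [0, 1] describing a focal scalp field.

    The peak channels of the region carry weight 1, the rest of the region's
    electrode group an intermediate weight, and channels outside the group a
    small far-field leakage weight (kept <= 0.3 so injected discharges remain
    focal).
    """

    region: str
    weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (N_CHANNELS,):
            raise ValueError(f"topography needs {N_CHANNELS} weights, got {w.shape}")
        if not np.isclose(w.max(), 1.0):
            raise ValueError("maximum topography weight must be 1")
        if w.min() < 0 or w.max() > 1:
            raise ValueError("topography weights must lie in [0, 1]")
        group = set(REGION_CHANNELS[self.region])
        for name, wi in zip(CANONICAL_CHANNELS, w):
            if name not in group and wi > 0.3:
                raise ValueError(
                    f"weight {wi:.2f} on {name} outside the {self.region} group exceeds 0.3"
                )
        object.__setattr__(self, "weights", w)


def region_topography(region: str) -> RegionTopography:
    """Default focal topography for one of the three modeled regions."""
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")
    w = np.full(N_CHANNELS, _LEAKAGE_WEIGHT)
    for name in REGION_CHANNELS[region]:
        w[channel_index(name)] = _IN_GROUP_WEIGHT
    for name in _REGION_PEAKS[region]:
        w[channel_index(name)] = 1.0
    return RegionTopography(region=region, weights=w)


def blink_topography() -> np.ndarray:
    """Scalp weights of an eye-blink artifact: maximal at Fp1/Fp2, frontal falloff."""
    w = np.full(N_CHANNELS, 0.05)
    for name, wi in (
        ("Fp1", 1.0), ("Fp2", 1.0), ("F3", 0.55), ("F4", 0.55),
        ("F7", 0.4), ("F8", 0.4), ("Fz", 0.45), ("C3", 0.15),
        ("C4", 0.15), ("Cz", 0.15),
    ):
        w[channel_index(name)] = wi
    return w


def alpha_topography() -> np.ndarray:
    """Scalp weights of the posterior dominant (alpha) rhythm."""
    w = np.full(N_CHANNELS, 0.05)
    for name, wi in (
        ("O1", 1.0), ("O2", 1.0), ("P3", 0.6), ("P4", 0.6),
        ("Pz", 0.45), ("T5", 0.3), ("T6", 0.3),
    ):
        w[channel_index(name)] = wi
    return w
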