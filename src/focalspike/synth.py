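"""Synthetic scalp-EEG cohort simulator.

Generates annotated 19-channel recordings that mimic the statistical structure
a focal-IED classifier is trained on: pink (1/f) background with a posterior
alpha rhythm, negative spike/slow-wave discharges injected with a focal
topography in exactly one of the frontal/temporal/occipital regions, optional
frontal eye-blink artifacts, and IED-free control recordings.  Every generator
is a pure function of its arguments and seed.

The morphology is phenomenological, not biophysical: a biphasic (Mexican-hat)
spike of 20-200 ms followed by an opposite-polarity half-sine slow wave, with
the discharge negative at the focus as is conventional for surface-negative
epileptiform potentials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import CapacityError
from .montage import (
    CANONICAL_CHANNELS,
    N_CHANNELS,
    REGIONS,
    RegionTopography,
    alpha_topography,
    blink_topography,
    channel_index,
    region_topography,
)
from .recording import AnnotationSet, IEDAnnotation, Recording

EPOCH_LEN_S = 1.5
HALF_SPAN_S = 0.75

#: Per-region defaults: mean IEDs per recording and mean discharge duration (s),
#: matching the clinical cohort profile in :mod:`focalspike.cohort_reference`.
DEFAULT_IEDS_PER_PATIENT = {"frontal": 141.0, "temporal": 90.0, "occipital": 127.0}
DEFAULT_IED_DURATION_MEAN_S = {"frontal": 0.45, "temporal": 0.52, "occipital": 0.48}


@dataclass
class SynthCohortConfig:
    """Study-scale defaults for a simulated focal-epilepsy cohort.

    The defaults reproduce the reference clinical cohort: 15/13/10 patients
    with frontal/temporal/occipital discharges plus 232 controls, >=30 min
    recordings at 200 Hz, and per-region mean IED counts of 141/90/127 with
    mean durations 0.45/0.52/0.48 s.  Tests and scaled experiments override
    counts and durations explicitly.
    """

    n_frontal: int = 15
    n_temporal: int = 13
    n_occipital: int = 10
    n_controls: int = 232
    recording_duration_s: float = 1800.0
    fs: float = 200.0
    ieds_per_patient_mean: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_IEDS_PER_PATIENT)
    )
    ied_duration_mean_s: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_IED_DURATION_MEAN_S)
    )
    ied_duration_sd_s: float = 0.1
    ied_amplitude_uV: float = 100.0
    background_rms_uV: float = 15.0
    alpha_amplitude_uV: float = 20.0
    blink_rate_per_min: float = 0.0
    min_gap_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_frontal", "n_temporal", "n_occipital", "n_controls"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.recording_duration_s < 10 * EPOCH_LEN_S:
            raise ValueError(
                f"recording_duration_s must be >= {10 * EPOCH_LEN_S}s "
                "(ten epoch lengths)"
            )
        for region, mean in self.ied_duration_mean_s.items():
            if not 0.1 <= mean <= 3.0:
                raise ValueError(
                    f"{region} mean IED duration {mean}s outside [0.1, 3.0]s"
                )
        if self.blink_rate_per_min < 0:
            raise ValueError("blink_rate_per_min must be >= 0")


def _pink_noise(rng: np.random.Generator, n_channels: int, n: int) -> np.ndarray:
    """Unit-RMS 1/f-shaped Gaussian noise, independent across channels."""
    freqs = np.fft.rfftfreq(n, d=1.0)  # d cancels in the shaping
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    # flat below the first bin's worth of very low frequencies, 1/f above
    shape[nz] = 1.0 / np.sqrt(np.maximum(freqs[nz], freqs[nz].min() * 4))
    spec = (rng.standard_normal((n_channels, freqs.size))
            + 1j * rng.standard_normal((n_channels, freqs.size))) * shape
    x = np.fft.irfft(spec, n=n, axis=1)
    rms = x.std(axis=1, keepdims=True)
    return x / np.where(rms > 0, rms, 1.0)


def make_background(
    duration_s: float,
    fs: float = 200.0,
    alpha_amplitude_uV: float = 20.0,
    background_rms_uV: float = 15.0,
    seed: int | np.random.SeedSequence | None = None,
    subject_id: str = "synthetic",
    group: str = "control",
    common_mode_frac: float = 0.4,
) -> Recording:
    """Awake-resting background: pink noise plus a posterior ~10 Hz rhythm.

    Each channel receives independent pink noise plus a shared common-mode
    pink-noise term (so average referencing is non-trivial), and a waxing-and-
    waning alpha rhythm weighted toward O1/O2/P3/P4.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    sig = _pink_noise(rng, N_CHANNELS, n) * background_rms_uV
    common = _pink_noise(rng, 1, n) * background_rms_uV * common_mode_frac
    sig = sig + common  # shared across all channels

    if alpha_amplitude_uV > 0:
        f_alpha = rng.normal(10.0, 0.3)
        phase = rng.uniform(0, 2 * np.pi)
        env_f = rng.uniform(0.1, 0.3)
        env_phase = rng.uniform(0, 2 * np.pi)
        envelope = 0.5 * (1 + np.sin(2 * np.pi * env_f * t + env_phase))
        alpha = alpha_amplitude_uV * envelope * np.sin(2 * np.pi * f_alpha * t + phase)
        sig = sig + np.outer(alpha_topography(), alpha)

    return Recording(subject_id=subject_id, signal=sig, fs=fs, group=group)


def make_spike_wave(
    fs: float,
    spike_dur_s: float,
    wave_dur_s: float,
    amplitude_uV: float,
    wave_amplitude_frac: float = 0.4,
    polarity: int = -1,
) -> np.ndarray:
    """Single-channel spike-and-slow-wave template.

    A biphasic Mexican-hat transient (the spike or sharp wave, 20-200 ms)
    followed by an opposite-polarity half-sine slow wave.  The template's
    peak absolute value equals ``amplitude_uV``; with the default negative
    polarity the spike deflects downward, as at a surface-negative focus.
    Total length is ``round((spike_dur_s + wave_dur_s) * fs)`` samples.
    """
    if not 0.02 <= spike_dur_s <= 0.2:
        raise ValueError(f"spike_dur_s must be in [0.02, 0.2]s, got {spike_dur_s}")
    if wave_dur_s < 0:
        raise ValueError("wave_dur_s must be >= 0")
    if polarity not in (-1, 1):
        raise ValueError("polarity must be +1 or -1")
    n_total = int(round((spike_dur_s + wave_dur_s) * fs))
    n_spike = min(int(round(spike_dur_s * fs)), n_total)
    n_wave = n_total - n_spike

    # Mexican-hat spike, main lobe of unit amplitude with small side lobes.
    ts = np.arange(n_spike) - (n_spike - 1) / 2
    a = max(n_spike / 5.0, 1.0)
    spike = (1 - (ts / a) ** 2) * np.exp(-(ts**2) / (2 * a**2))

    # Half-sine slow wave, opposite sign to the spike's main lobe.
    wave = -wave_amplitude_frac * np.sin(np.pi * np.arange(n_wave) / max(n_wave, 1))

    # With polarity -1 the spike lobe is negative and the slow wave positive.
    template = polarity * np.concatenate([spike, wave])
    peak = np.abs(template).max()
    return template * (amplitude_uV / peak)


DurationSampler = Callable[[np.random.Generator], tuple[float, float]]


def default_duration_sampler(
    mean_total_s: float = 0.48, sd_total_s: float = 0.1
) -> DurationSampler:
    """Sampler of (spike, wave) durations with a clipped-normal total length."""

    def sample(rng: np.random.Generator) -> tuple[float, float]:
        total = float(np.clip(rng.normal(mean_total_s, sd_total_s), 0.2, 1.2))
        spike = float(rng.uniform(0.04, min(0.12, total - 0.05)))
        return spike, total - spike

    return sample


def inject_ieds(
    recording: Recording,
    region: str,
    n_events: int,
    duration_sampler: DurationSampler | None = None,
    min_gap_s: float = 1.0,
    seed: int | np.random.SeedSequence | None = None,
    amplitude_uV: float = 100.0,
    topography: RegionTopography | None = None,
) -> tuple[Recording, AnnotationSet]:
    """Add ``n_events`` focal discharges of one region to a copy of the recording.

    Events are placed by uniform rejection sampling with a minimum inter-event
    gap, and each event lies fully inside ``[0.75 s, T - 0.75 s]`` so that every
    discharge can center a complete 1.5-s epoch.  Returns the modified copy and
    the ground-truth annotations.
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}")
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    out = recording.copy()
    if n_events == 0:
        return out, AnnotationSet(recording_id=recording.subject_id, events=[])

    rng = np.random.default_rng(seed)
    sampler = duration_sampler or default_duration_sampler(
        DEFAULT_IED_DURATION_MEAN_S[region]
    )
    topo = topography or region_topography(region)
    fs, T = recording.fs, recording.duration_s
    margin = HALF_SPAN_S

    placed: list[tuple[float, float, np.ndarray]] = []  # (onset, offset, template)
    max_attempts = 2000 * n_events
    attempts = 0
    while len(placed) < n_events:
        attempts += 1
        if attempts > max_attempts:
            mean_dur = np.mean([b - a for a, b, _ in placed]) if placed else 0.5
            feasible = int((T - 2 * margin + min_gap_s) / (mean_dur + min_gap_s))
            raise CapacityError(
                f"could not place {n_events} events of ~{mean_dur:.2f}s with "
                f"gap {min_gap_s}s in {T:.0f}s; at most ~{feasible} fit"
            )
        spike_dur, wave_dur = sampler(rng)
        dur = spike_dur + wave_dur
        # one-sample inner margin so the onset stays >= margin after rounding
        lo, hi = margin + 1.0 / fs, T - margin - dur - 1.0 / fs
        if hi <= lo:
            continue
        onset = rng.uniform(lo, hi)
        offset = onset + dur
        if all(onset - b >= min_gap_s or a - offset >= min_gap_s for a, b, _ in placed):
            template = make_spike_wave(fs, spike_dur, wave_dur, amplitude_uV)
            placed.append((onset, offset, template))

    events = []
    for onset, offset, template in placed:
        start = int(round(onset * fs))
        stop = start + template.size
        out.signal[:, start:stop] += np.outer(topo.weights, template)
        events.append(
            IEDAnnotation(region=region, onset_s=start / fs, offset_s=stop / fs)
        )
    return out, AnnotationSet(recording_id=recording.subject_id, events=events)


def inject_eye_blinks(
    recording: Recording,
    rate_per_min: float,
    amplitude_uV: float = 150.0,
    seed: int | np.random.SeedSequence | None = None,
) -> Recording:
    """Add positive-polarity blink transients, maximal at Fp1/Fp2.

    The number of blinks is Poisson with mean ``rate_per_min * duration / 60``;
    each blink is a 0.2-0.4 s raised-cosine pulse.  ``rate_per_min = 0``
    returns a bitwise-identical copy.
    """
    if rate_per_min < 0:
        raise ValueError("rate_per_min must be >= 0")
    out = recording.copy()
    if rate_per_min == 0:
        return out
    rng = np.random.default_rng(seed)
    fs, n = recording.fs, recording.n_samples
    n_blinks = rng.poisson(rate_per_min * recording.duration_s / 60.0)
    topo = blink_topography()
    for _ in range(n_blinks):
        width_s = rng.uniform(0.2, 0.4)
        w = int(round(width_s * fs))
        start = rng.integers(0, max(n - w, 1))
        pulse = amplitude_uV * np.hanning(w)
        out.signal[:, start:start + w] += np.outer(topo, pulse)
    return out


def draw_ied_count(rng: np.random.Generator, mean: float) -> int:
    """Per-patient IED count: Poisson around the configured mean, clipped >= 1."""
    return max(1, int(rng.poisson(mean)))


@dataclass
class SubjectRecord:
    """One simulated subject: recording, ground-truth annotations, metadata."""

    recording: Recording
    annotations: AnnotationSet
    metadata: dict


def simulate_cohort(config: SynthCohortConfig) -> list[SubjectRecord]:
    """Simulate a full annotated cohort from one seed.

    Patients receive discharges of exactly one region (count Poisson around the
    region's configured mean, clipped >= 1); controls receive none.  Eye blinks
    are added to every subject at ``blink_rate_per_min``.  Fully reproducible
    from ``config.seed``.
    """
    roster: list[tuple[str, str | None]] = []
    for region, count in (
        ("frontal", config.n_frontal),
        ("temporal", config.n_temporal),
        ("occipital", config.n_occipital),
    ):
        roster += [(region, f"{region[0].upper()}{i + 1:02d}") for i in range(count)]
    roster += [(None, f"C{i + 1:02d}") for i in range(config.n_controls)]

    ss = np.random.SeedSequence(config.seed)
    child_seeds = ss.spawn(len(roster))

    subjects: list[SubjectRecord] = []
    for idx, ((region, subject_id), child) in enumerate(zip(roster, child_seeds)):
        bg_seed, count_seed, ied_seed, blink_seed = child.spawn(4)
        group = "control" if region is None else "patient"
        rec = make_background(
            config.recording_duration_s,
            config.fs,
            alpha_amplitude_uV=config.alpha_amplitude_uV,
            background_rms_uV=config.background_rms_uV,
            seed=bg_seed,
            subject_id=subject_id,
            group=group,
        )
        if region is None:
            ann = AnnotationSet(recording_id=subject_id, events=[])
            n_ieds = 0
        else:
            n_ieds = draw_ied_count(
                np.random.default_rng(count_seed), config.ieds_per_patient_mean[region]
            )
            sampler = default_duration_sampler(
                config.ied_duration_mean_s[region], config.ied_duration_sd_s
            )
            try:
                rec, ann = inject_ieds(
                    rec,
                    region,
                    n_ieds,
                    duration_sampler=sampler,
                    min_gap_s=config.min_gap_s,
                    seed=ied_seed,
                    amplitude_uV=config.ied_amplitude_uV,
                )
            except CapacityError as err:
                raise CapacityError(f"subject {idx} ({subject_id}): {err}") from err
        if config.blink_rate_per_min > 0:
            rec = inject_eye_blinks(
                rec, config.blink_rate_per_min, seed=blink_seed
            )
        subjects.append(
            SubjectRecord(
                recording=rec,
                annotations=ann,
                metadata={
                    "subject_id": subject_id,
                    "group": group,
                    "region": region,
                    "n_ieds": n_ieds,
                },
            )
        )
    return subjects
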