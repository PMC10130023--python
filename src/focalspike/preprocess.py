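"""Signal conditioning: resample to 200 Hz, average reference, 1-70 Hz band-pass.

The pipeline order is resample -> average_reference -> bandpass; the output of
the full chain is what epoching consumes.  All operations are linear,
deterministic, and shape-preserving (resampling changes length only).

The band-pass is a 4th-order Butterworth applied forward-backward (zero
phase) so discharge peak latencies — and hence epoch centers — are not
shifted.  A 60 Hz notch is available but off by default: synthetic data has
no mains hum and clinical recorders typically notch at acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .errors import ContractError
from .montage import N_CHANNELS
from .recording import Recording


@dataclass(frozen=True)
class PreprocessConfig:
    target_fs: float = 200.0
    band_lo: float = 1.0
    band_hi: float = 70.0
    notch_hz: float | None = None
    filter_order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.band_lo < self.band_hi < self.target_fs / 2:
            raise ValueError(
                f"need 0 < band_lo < band_hi < target_fs/2; got "
                f"({self.band_lo}, {self.band_hi}) at fs {self.target_fs}"
            )
        if self.notch_hz is not None and not (
            self.band_lo < self.notch_hz < self.band_hi
        ):
            raise ValueError("notch frequency must lie inside the pass band")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")


def average_reference(recording: Recording) -> Recording:
    """Re-reference to the common average of all 19 channels.

    After this, the mean across channels is zero at every sample.  Idempotent.
    """
    if recording.signal.shape[0] != N_CHANNELS:
        raise ContractError(
            f"average reference requires {N_CHANNELS} channels, "
            f"got {recording.signal.shape[0]}"
        )
    out = recording.copy()
    out.signal -= out.signal.mean(axis=0, keepdims=True)
    return out


def bandpass(recording: Recording, config: PreprocessConfig | None = None) -> Recording:
    """Band-pass (and optionally notch) filter every channel."""
    config = config or PreprocessConfig()
    if abs(recording.fs - config.target_fs) > 1e-9:
        raise ContractError(
            f"bandpass expects fs {config.target_fs}, got {recording.fs}; "
            "resample first"
        )
    sos = sps.butter(
        config.filter_order,
        [config.band_lo, config.band_hi],
        btype="bandpass",
        fs=recording.fs,
        output="sos",
    )
    out = recording.copy()
    filt = sps.sosfiltfilt if config.zero_phase else sps.sosfilt
    out.signal = filt(sos, out.signal, axis=1)
    if config.notch_hz is not None:
        b, a = sps.iirnotch(config.notch_hz, Q=30.0, fs=recording.fs)
        if config.zero_phase:
            out.signal = sps.filtfilt(b, a, out.signal, axis=1)
        else:
            out.signal = sps.lfilter(b, a, out.signal, axis=1)
    return out


def resample(recording: Recording, target_fs: float = 200.0) -> Recording:
    """Polyphase resampling to ``target_fs``; identity when rates match.

    Output length is ``round(n_in * target_fs / fs)``.
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if abs(recording.fs - target_fs) < 1e-9:
        return recording.copy()
    ratio = Fraction(target_fs).limit_denominator(10**6) / Fraction(
        recording.fs
    ).limit_denominator(10**6)
    up, down = ratio.numerator, ratio.denominator
    sig = sps.resample_poly(recording.signal, up, down, axis=1)
    n_out = int(round(recording.n_samples * target_fs / recording.fs))
    if sig.shape[1] > n_out:
        sig = sig[:, :n_out]
    elif sig.shape[1] < n_out:
        pad = np.repeat(sig[:, -1:], n_out - sig.shape[1], axis=1)
        sig = np.concatenate([sig, pad], axis=1)
    return replace(recording, signal=sig, fs=target_fs)


def preprocess(
    recording: Recording, config: PreprocessConfig | None = None
) -> Recording:
    """Full conditioning chain: resample -> average reference -> band-pass."""
    config = config or PreprocessConfig()
    rec = resample(recording, config.target_fs)
    rec = average_reference(rec)
    return bandpass(rec, config)
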