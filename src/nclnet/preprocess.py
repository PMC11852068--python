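"""Signal conditioning for multichannel LFP recordings.

The chain mirrors standard LFP practice: a broadband 1–250 Hz zero-phase
Butterworth band-pass, a narrow 50 Hz notch for mains interference,
anti-aliased integer-factor downsampling (typically 30 kHz → 1 kHz), a
five-band decomposition (delta, theta, beta, slow gamma, fast gamma), and
event-centred epoching into ``trials × channels × samples`` arrays.

All filters are applied forward-backward (``sosfiltfilt``/``filtfilt``) so
the chain is zero-phase: band-limited features do not shift in time, which
matters because windows are later assigned to the pre/post condition by
their position relative to the event.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import ParameterError, SamplingError

log = logging.getLogger(__name__)

__all__ = [
    "BandSpec",
    "CANONICAL_BANDS",
    "EpochSet",
    "broadband_filter",
    "remove_line_noise",
    "downsample",
    "band_decompose",
    "extract_epochs",
]


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band ``[f_lo, f_hi]`` in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ParameterError(
                f"band {self.name!r}: need 0 < f_lo < f_hi, got ({self.f_lo}, {self.f_hi})"
            )


#: The canonical five-band set used throughout the analysis.
CANONICAL_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 1.0, 4.0),
    BandSpec("theta", 5.0, 12.0),
    BandSpec("beta", 13.0, 30.0),
    BandSpec("slow_gamma", 31.0, 45.0),
    BandSpec("fast_gamma", 55.0, 80.0),
)

BAND_BY_NAME: dict[str, BandSpec] = {b.name: b for b in CANONICAL_BANDS}


@dataclass
class EpochSet:
    """Event-centred epochs of one band-filtered signal.

    ``data`` has shape ``(trials, channels, samples)`` where ``samples``
    equals ``(epoch_pre + epoch_post) * fs`` and sample ``event_sample``
    (= ``epoch_pre * fs``) is the event trigger.
    """

    band: BandSpec
    fs: float
    data: np.ndarray
    event_sample: int
    subject_id: str
    kept_trials: list[int] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


def _as_2d(signal: np.ndarray) -> np.ndarray:
    arr = np.asarray(signal, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2:
        raise ParameterError(f"signal must be 1-D or channels x samples, got ndim={arr.ndim}")
    return arr


def broadband_filter(signal: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass, 1–250 Hz, per channel."""
    if fs <= 2 * 250.0:
        raise SamplingError(f"fs={fs} Hz too low for a 1-250 Hz band-pass (need fs > 500)")
    arr = _as_2d(signal)
    sos = sps.butter(4, [1.0, 250.0], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, arr, axis=-1)


def remove_line_noise(signal: np.ndarray, fs: float, line_freq: float = 50.0, q: float = 30.0) -> np.ndarray:
    """Zero-phase IIR notch at ``line_freq`` (quality factor ``q``), per channel."""
    if not line_freq < fs / 2:
        raise SamplingError(f"line_freq={line_freq} Hz must be below Nyquist ({fs / 2} Hz)")
    arr = _as_2d(signal)
    b, a = sps.iirnotch(line_freq, q, fs=fs)
    return sps.filtfilt(b, a, arr, axis=-1)


def downsample(signal: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Anti-aliased decimation by the integer factor ``fs_in / fs_out``.

    A zero-phase 8th-order Butterworth low-pass at ``0.4 * fs_out`` guards
    against aliasing before every ``factor``-th sample is kept; the output
    length is ``floor(n / factor)``.
    """
    arr = _as_2d(signal)
    factor_f = fs_in / fs_out
    factor = int(round(factor_f))
    if abs(factor_f - factor) > 1e-9 or factor < 1:
        raise ParameterError(f"fs_in/fs_out must be a positive integer, got {fs_in}/{fs_out}")
    n_out = arr.shape[-1] // factor
    if factor == 1:
        return arr[..., :n_out].copy()
    sos = sps.butter(8, 0.4 * fs_out, btype="lowpass", fs=fs_in, output="sos")
    filtered = sps.sosfiltfilt(sos, arr, axis=-1)
    return filtered[..., ::factor][..., :n_out]


def band_decompose(
    signal: np.ndarray, fs: float, bands: list[BandSpec] | tuple[BandSpec, ...] = CANONICAL_BANDS
) -> dict[str, np.ndarray]:
    """Zero-phase 4th-order band-pass per band; returns ``{band name: matrix}``."""
    arr = _as_2d(signal)
    out: dict[str, np.ndarray] = {}
    for band in bands:
        if band.f_hi >= fs / 2:
            raise ParameterError(
                f"band {band.name!r}: upper edge {band.f_hi} Hz is not below Nyquist ({fs / 2} Hz)"
            )
        sos = sps.butter(4, [band.f_lo, band.f_hi], btype="bandpass", fs=fs, output="sos")
        out[band.name] = sps.sosfiltfilt(sos, arr, axis=-1)
    return out


def extract_epochs(
    recording,
    band_signal: np.ndarray,
    pre_s: float,
    post_s: float,
    fs: float | None = None,
    band: BandSpec | None = None,
) -> EpochSet:
    """Slice ``band_signal`` into event-centred epochs.

    ``fs`` is the sampling rate of ``band_signal`` (defaults to the
    recording's rate; pass it explicitly after downsampling).  Each epoch
    covers the half-open sample range ``[event - pre_s*fs, event + post_s*fs)``
    so its length is exactly ``(pre_s + post_s) * fs`` samples.  Events too
    close to the recording edges are excluded with a warning.
    """
    arr = _as_2d(band_signal)
    fs = float(fs if fs is not None else recording.fs)
    n_pre = int(round(pre_s * fs))
    n_post = int(round(post_s * fs))
    n_samples = arr.shape[-1]
    epochs = []
    kept: list[int] = []
    for i, t in enumerate(recording.events):
        start = int(round(t * fs)) - n_pre
        stop = start + n_pre + n_post
        if start < 0 or stop > n_samples:
            warnings.warn(
                f"trial {i} at t={t:.3f}s lacks {pre_s}s history / {post_s}s future; excluded",
                stacklevel=2,
            )
            log.warning("subject %s: trial %d excluded (event too close to edge)", recording.subject_id, i)
            continue
        epochs.append(arr[:, start:stop])
        kept.append(i)
    data = (
        np.stack(epochs, axis=0)
        if epochs
        else np.empty((0, arr.shape[0], n_pre + n_post))
    )
    if band is None:
        band = BandSpec("broadband", 1.0, fs / 2 - 1e-9)
    return EpochSet(
        band=band,
        fs=fs,
        data=data,
        event_sample=n_pre,
        subject_id=recording.subject_id,
        kept_trials=kept,
    )
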