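"""Sliding-window multitaper coherence networks.

For two signals x(t), y(t) the magnitude-squared coherence at frequency f is

    C_xy(f) = |<S_xy(f)>|^2 / (<S_xx(f)> <S_yy(f)>)

where S are (cross-)eigenspectra and <.> averages over K Slepian tapers.
Within each sliding window (default 256 samples, step 128) the coherence of
every channel pair is averaged over the frequency bins falling inside the
analysis band, producing one ``channels x channels`` adjacency matrix per
window per trial.  Windows are assigned to the *pre* (target not yet
detected) or *post* (target detected) condition by whether their midpoint
falls before the event sample; for a 2 s epoch at 1 kHz this yields 14
windows, 7 per condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.signal.windows import dpss

from .errors import ParameterError
from .preprocess import BandSpec, EpochSet

__all__ = [
    "WindowPlan",
    "CoherenceTensor",
    "plan_windows",
    "mtm_coherence",
    "band_adjacency",
    "coherence_tensor",
    "global_mean_coherence",
]

DEFAULT_WIN_LEN = 256
DEFAULT_STEP = 128
DEFAULT_NW = 3.0
DEFAULT_K = 5


@dataclass(frozen=True)
class WindowPlan:
    """Sliding-window layout over one epoch, with pre/post condition labels."""

    win_len: int
    step: int
    starts: tuple[int, ...]
    condition_of_window: tuple[str, ...]
    event_sample: int

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    def midpoints(self) -> np.ndarray:
        return np.asarray(self.starts) + self.win_len / 2.0


@dataclass
class CoherenceTensor:
    """Band-averaged coherence, ``values[trial, window, i, j]`` in [0, 1]."""

    subject_id: str
    band: BandSpec
    values: np.ndarray  # trials x windows x channels x channels
    window_plan: WindowPlan

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[2]


def plan_windows(
    epoch_len: int,
    win_len: int = DEFAULT_WIN_LEN,
    step: int = DEFAULT_STEP,
    event_sample: int | None = None,
) -> WindowPlan:
    """Tile an epoch with windows; label each by its midpoint vs the event.

    ``n_windows = floor((epoch_len - win_len) / step) + 1``.  A window is
    *pre* iff its midpoint sample is strictly before ``event_sample``.
    """
    if win_len > epoch_len:
        raise ParameterError(f"win_len={win_len} exceeds epoch length {epoch_len}")
    if step < 1:
        raise ParameterError(f"step must be >= 1, got {step}")
    if event_sample is None:
        event_sample = epoch_len // 2
    n_windows = (epoch_len - win_len) // step + 1
    starts = tuple(i * step for i in range(n_windows))
    conditions = tuple(
        "pre" if s + win_len / 2.0 < event_sample else "post" for s in starts
    )
    return WindowPlan(
        win_len=win_len,
        step=step,
        starts=starts,
        condition_of_window=conditions,
        event_sample=event_sample,
    )


@lru_cache(maxsize=32)
def _tapers(win_len: int, nw: float, k: int) -> np.ndarray:
    if k > 2 * nw - 1:
        raise ParameterError(f"taper count k={k} exceeds 2*nw-1={2 * nw - 1}")
    return dpss(win_len, nw, Kmax=k)  # (k, win_len)


def mtm_coherence(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    nw: float = DEFAULT_NW,
    k: int = DEFAULT_K,
) -> tuple[np.ndarray, np.ndarray]:
    """Multitaper magnitude-squared coherence spectrum of two equal-length signals.

    Returns ``(freqs, coherence)`` with coherence clipped to [0, 1].  A
    zero-variance input makes coherence undefined; zeros are returned with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be equal-length 1-D sequences")
    n = x.size
    tapers = _tapers(n, nw, k)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    fx = np.fft.rfft(tapers * x[None, :], axis=-1)
    fy = np.fft.rfft(tapers * y[None, :], axis=-1)
    sxx = np.mean(np.abs(fx) ** 2, axis=0)
    syy = np.mean(np.abs(fy) ** 2, axis=0)
    sxy = np.mean(fx * np.conj(fy), axis=0)
    denom = sxx * syy
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero-variance input: coherence undefined, returning zeros", stacklevel=2)
        return freqs, np.zeros_like(freqs)
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(sxy) ** 2 / denom
    coh = np.nan_to_num(coh, nan=0.0)
    return freqs, np.clip(coh, 0.0, 1.0)


def _band_bins(win_len: int, fs: float, band: BandSpec) -> np.ndarray:
    freqs = np.fft.rfftfreq(win_len, d=1.0 / fs)
    mask = (freqs >= band.f_lo) & (freqs <= band.f_hi)
    if not mask.any():
        raise ParameterError(
            f"band {band.name!r} [{band.f_lo}, {band.f_hi}] Hz contains no frequency bin "
            f"at resolution {fs / win_len:.4g} Hz (win_len={win_len})"
        )
    return mask


def _batch_band_coherence(
    windows: np.ndarray, fs: float, band: BandSpec, nw: float, k: int
) -> np.ndarray:
    """Coherence adjacency for a batch of windows.

    ``windows``: (..., channels, win_len) → (..., channels, channels).
    """
    win_len = windows.shape[-1]
    tapers = _tapers(win_len, nw, k)
    mask = _band_bins(win_len, fs, band)
    # (..., channels, k, n_bins) — restrict to in-band bins immediately.
    f = np.fft.rfft(windows[..., None, :] * tapers, axis=-1)[..., mask]
    sxy = np.einsum("...ckf,...dkf->...cdf", f, np.conj(f)) / k
    auto = np.einsum("...ccf->...cf", sxy).real  # (..., channels, n_bins)
    denom = auto[..., :, None, :] * auto[..., None, :, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(sxy) ** 2 / denom
    bad = ~np.isfinite(coh)
    if bad.any():
        warnings.warn("zero-variance channel(s): undefined coherence entries set to 0", stacklevel=3)
        coh[bad] = 0.0
    adj = np.clip(coh.mean(axis=-1), 0.0, 1.0)
    adj = 0.5 * (adj + np.swapaxes(adj, -1, -2))
    idx = np.arange(adj.shape[-1])
    adj[..., idx, idx] = 1.0
    return adj


def band_adjacency(
    window_data: np.ndarray,
    fs: float,
    band: BandSpec,
    nw: float = DEFAULT_NW,
    k: int = DEFAULT_K,
) -> np.ndarray:
    """One window's ``channels x channels`` band-averaged coherence matrix.

    Entry (i, j) is the mean multitaper coherence of channels i and j over
    the frequency bins inside ``[f_lo, f_hi]``; symmetric with unit diagonal.
    """
    arr = np.asarray(window_data, dtype=float)
    if arr.ndim != 2:
        raise ParameterError("window_data must be channels x win_len")
    return _batch_band_coherence(arr[None], fs, band, nw, k)[0]


def coherence_tensor(
    epochs: EpochSet,
    plan: WindowPlan,
    nw: float = DEFAULT_NW,
    k: int = DEFAULT_K,
    trial_chunk: int = 16,
) -> CoherenceTensor:
    """Coherence adjacency for every (trial, window) of an epoch set.

    ``values[t, w]`` equals ``band_adjacency`` of trial ``t``, window ``w``;
    trials are processed in chunks to bound memory.
    """
    data = epochs.data
    n_trials, n_channels, epoch_len = data.shape
    starts = np.asarray(plan.starts)
    if plan.starts and starts[-1] + plan.win_len > epoch_len:
        raise ParameterError("window plan exceeds the epoch length")
    values = np.empty((n_trials, plan.n_windows, n_channels, n_channels))
    win_idx = starts[:, None] + np.arange(plan.win_len)[None, :]
    for lo in range(0, n_trials, trial_chunk):
        hi = min(lo + trial_chunk, n_trials)
        # (chunk, windows, channels, win_len)
        windows = data[lo:hi][:, :, win_idx].transpose(0, 2, 1, 3)
        values[lo:hi] = _batch_band_coherence(windows, epochs.fs, epochs.band, nw, k)
    return CoherenceTensor(
        subject_id=epochs.subject_id,
        band=epochs.band,
        values=values,
        window_plan=plan,
    )


def global_mean_coherence(tensor: CoherenceTensor) -> np.ndarray:
    """Per-window mean of strictly-upper-triangle coherence, averaged over trials."""
    if tensor.values.size == 0:
        raise ParameterError("empty coherence tensor")
    n = tensor.n_channels
    iu = np.triu_indices(n, k=1)
    per_trial_window = tensor.values[:, :, iu[0], iu[1]].mean(axis=-1)
    return per_trial_window.mean(axis=0)
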