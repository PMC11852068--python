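"""Synthetic multichannel LFP cohorts with a planted connectivity change.

Each channel is a mixture of shared band-limited latent oscillators (one per
frequency band, built by band-pass filtering white noise), private white
noise, and a common 50 Hz mains sinusoid.  The mixing weight of a band's
latent into every channel switches instantaneously from ``gain_pre`` to
``gain_post`` at each trial's event time, which plants a step change in
inter-channel coherence in that band — the structure the downstream network
analysis is designed to detect.

The default configuration emulates the study design this package targets:
4 subjects x 60 trials, 16 channels, 30 kHz acquisition later downsampled to
1 kHz, 2 s event-centred epochs, and a beta-band coupling increase
(0.3 -> 0.8) after the event.  ``noise_sd`` is defined as the private-noise
standard deviation within a 1 kHz-equivalent bandwidth; noise generated at a
higher rate is scaled by ``sqrt(fs_raw / 1000)`` so in-band signal-to-noise,
and therefore coherence, is invariant to the generation rate.  A fast mode
is obtained simply by setting ``fs_raw = 1000``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .errors import ConfigError
from .preprocess import BAND_BY_NAME, BandSpec

__all__ = [
    "CohortConfig",
    "Recording",
    "generate_recording",
    "generate_cohort",
    "write_recording",
    "read_recording",
]

#: Default band coupling: a planted beta increase, weak constant coupling elsewhere.
DEFAULT_BAND_COUPLING: dict[str, tuple[float, float]] = {
    "delta": (0.2, 0.2),
    "theta": (0.2, 0.2),
    "beta": (0.3, 0.8),
    "slow_gamma": (0.2, 0.2),
    "fast_gamma": (0.2, 0.2),
}

#: Quiet gap between consecutive epochs, seconds.
_TRIAL_GAP_S = 0.5
#: Padding before the first event's history and after the last event's future.
_EDGE_PAD_S = 0.25


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generation parameters (all rates in Hz, times in seconds)."""

    n_subjects: int = 4
    n_trials: int = 60
    n_channels: int = 16
    fs_raw: float = 30000.0
    epoch_pre: float = 1.0
    epoch_post: float = 1.0
    band_coupling: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BAND_COUPLING)
    )
    line_amp: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if self.n_trials < 1:
            raise ConfigError(f"n_trials must be >= 1, got {self.n_trials}")
        if self.n_channels < 2:
            raise ConfigError(f"n_channels must be >= 2, got {self.n_channels}")
        if self.epoch_pre <= 0 or self.epoch_post <= 0:
            raise ConfigError("epoch_pre and epoch_post must be positive")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.line_amp < 0:
            raise ConfigError(f"line_amp must be >= 0, got {self.line_amp}")
        f_hi_max = 0.0
        for name, gains in self.band_coupling.items():
            if name not in BAND_BY_NAME:
                raise ConfigError(
                    f"band_coupling: unknown band {name!r} (known: {sorted(BAND_BY_NAME)})"
                )
            gp, gq = gains
            if not (0.0 <= gp <= 1.0 and 0.0 <= gq <= 1.0):
                raise ConfigError(
                    f"band_coupling[{name!r}]: gains must lie in [0, 1], got {gains}"
                )
            f_hi_max = max(f_hi_max, BAND_BY_NAME[name].f_hi)
        if self.fs_raw <= 2 * f_hi_max:
            raise ConfigError(
                f"fs_raw={self.fs_raw} Hz must exceed twice the highest coupled band edge "
                f"({f_hi_max} Hz)"
            )

    def fast(self) -> "CohortConfig":
        """A 1 kHz variant of this config (test/fast mode, statistically equivalent)."""
        return replace(self, fs_raw=1000.0)


@dataclass
class Recording:
    """One subject's continuous multichannel recording with trial event times."""

    subject_id: str
    fs: float
    signal: np.ndarray  # channels x samples, float64
    events: list[float]  # event times, seconds

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def _band_limited_noise(rng: np.random.Generator, band: BandSpec, fs: float, n: int) -> np.ndarray:
    """Unit-variance band-limited Gaussian process: band-passed white noise."""
    white = rng.standard_normal(n)
    sos = sps.butter(4, [band.f_lo, band.f_hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def _event_times(config: CohortConfig) -> list[float]:
    span = config.epoch_pre + config.epoch_post + _TRIAL_GAP_S
    return [_EDGE_PAD_S + config.epoch_pre + i * span for i in range(config.n_trials)]


def generate_recording(config: CohortConfig, subject_index: int) -> Recording:
    """Generate one subject's recording; deterministic given ``(config, subject_index)``."""
    if not 0 <= subject_index < config.n_subjects:
        raise ConfigError(
            f"subject_index must be in [0, {config.n_subjects}), got {subject_index}"
        )
    fs = config.fs_raw
    events = _event_times(config)
    duration = events[-1] + config.epoch_post + _EDGE_PAD_S
    n = int(round(duration * fs))
    rng = np.random.default_rng(config.seed + subject_index)

    # Gain timeline per band: gain_pre everywhere except [event, event+epoch_post).
    post_mask = np.zeros(n, dtype=bool)
    for t in events:
        a = int(round(t * fs))
        b = min(n, a + int(round(config.epoch_post * fs)))
        post_mask[a:b] = True

    # Private noise first (one draw per channel, fixed order for determinism).
    noise_scale = config.noise_sd * np.sqrt(fs / 1000.0)
    signal = rng.standard_normal((config.n_channels, n))
    signal *= noise_scale

    # Shared latents, mixed with per-channel random sign and gain = coupling weight.
    for name in sorted(config.band_coupling):
        gain_pre, gain_post = config.band_coupling[name]
        latent = _band_limited_noise(rng, BAND_BY_NAME[name], fs, n)
        signs = rng.choice(np.array([-1.0, 1.0]), size=config.n_channels)
        gains = np.where(post_mask, gain_post, gain_pre)
        driven = gains * latent
        for c in range(config.n_channels):
            signal[c] += signs[c] * driven

    if config.line_amp > 0:
        t_axis = np.arange(n) / fs
        signal += config.line_amp * np.sin(2 * np.pi * 50.0 * t_axis)

    return Recording(
        subject_id=f"bird{subject_index}",
        fs=fs,
        signal=signal,
        events=events,
    )


def generate_cohort(config: CohortConfig) -> list[Recording]:
    """All subjects' recordings; per-subject seeds are ``config.seed + index``."""
    return [generate_recording(config, i) for i in range(config.n_subjects)]


def write_recording(recording: Recording, path_prefix: str | Path) -> tuple[Path, Path]:
    """Persist as flat little-endian float64 channel-major binary + JSON sidecar."""
    prefix = Path(path_prefix)
    bin_path = prefix.with_suffix(".bin")
    json_path = prefix.with_suffix(".json")
    recording.signal.astype("<f8").tofile(bin_path)
    sidecar = {
        "subject_id": recording.subject_id,
        "fs": recording.fs,
        "n_channels": recording.n_channels,
        "n_samples": recording.n_samples,
        "events": list(recording.events),
    }
    json_path.write_text(json.dumps(sidecar, indent=2))
    return bin_path, json_path


def read_recording(path_prefix: str | Path) -> Recording:
    """Inverse of :func:`write_recording`; round-trip is bit-exact."""
    prefix = Path(path_prefix)
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    signal = np.fromfile(prefix.with_suffix(".bin"), dtype="<f8").reshape(
        sidecar["n_channels"], sidecar["n_samples"]
    )
    return Recording(
        subject_id=sidecar["subject_id"],
        fs=sidecar["fs"],
        signal=signal,
        events=list(sidecar["events"]),
    )
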