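"""Synthetic EEG cohort generator.

The generator emulates the statistical structure the downstream classifier
relies on: per-channel oscillatory power in the five canonical bands with a
class-dependent amplitude profile (elevated alpha and theta in the MDD
class), a pink (1/f) broadband background, and optional frontal blink
transients. Each subject's signal is drawn from an independent random
stream derived by stable hashing of ``(seed, subject_id)``, so adding or
removing subjects from a cohort never reshuffles the others.

The signal model per channel is deliberately simple — one sinusoid per band
at a frequency drawn uniformly inside the band, with a random phase — which
makes its band-power statistics analytically checkable (a sinusoid of
amplitude A carries power A**2/2 concentrated at its frequency).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .montage import (
    BAND_ORDER,
    FRONTAL_CHANNELS,
    ChannelMontage,
    band_limits,
    default_montage,
)
from .recording import EEGRecording

#: (healthy, mdd) sinusoid amplitudes per band, microvolts. The MDD profile
#: doubles alpha and raises theta by 50%, reflecting the elevated alpha/theta
#: resting power reported for depression; other bands are class-neutral.
DEFAULT_BAND_AMPLITUDES: dict[str, tuple[float, float]] = {
    "delta": (10.0, 10.0),
    "theta": (6.0, 9.0),
    "alpha": (8.0, 16.0),
    "beta": (4.0, 4.0),
    "gamma": (1.5, 1.5),
}


@dataclass
class GeneratorConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults mirror the reference cohort: 30 healthy controls and 33 MDD
    patients, 19-channel 10-20 montage, 256 Hz, 5-minute recordings.
    """

    n_healthy: int = 30
    n_mdd: int = 33
    fs: float = 256.0
    duration_s: float = 300.0
    band_amplitudes: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDES)
    )
    noise_scale: float = 5.0
    blink_rate: float = 0.0  # events per minute, frontal channels only
    montage: ChannelMontage = field(default_factory=default_montage)
    seed: int = 0

    def validate(self) -> None:
        if self.n_healthy + self.n_mdd < 1:
            raise InputError("cohort must contain at least one subject")
        if self.n_healthy < 0 or self.n_mdd < 0:
            raise InputError("subject counts must be nonnegative")
        if self.noise_scale < 0:
            raise InputError("noise_scale must be nonnegative")
        if self.blink_rate < 0:
            raise InputError("blink_rate must be nonnegative")
        for band in BAND_ORDER:
            if band not in self.band_amplitudes:
                raise InputError(f"band_amplitudes missing band {band!r}")
            h, m = self.band_amplitudes[band]
            if h < 0 or m < 0:
                raise InputError(f"amplitudes for band {band!r} must be nonnegative")
        n = self.fs * self.duration_s
        if abs(n - round(n)) > 1e-9:
            raise InputError(
                f"duration_s x fs = {n} is not an integer number of samples"
            )


def subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    """Random stream for one subject, stable under cohort recomposition.

    The stream key is derived from a SHA-256 hash of the subject id, so it
    depends only on ``(seed, subject_id)`` — never on how many other
    subjects exist or in which order they are generated.
    """
    digest = hashlib.sha256(subject_id.encode("utf-8")).digest()
    key = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _pink_noise(rng: np.random.Generator, n: int, scale: float) -> np.ndarray:
    """1/f-amplitude noise of RMS ``scale`` (zero mean)."""
    if scale == 0 or n == 0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, d=1.0)  # d cancels in the normalization
    spectrum = rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size)
    shaping = np.zeros_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])  # power ~ 1/f, DC removed
    x = np.fft.irfft(spectrum * shaping, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x * (scale / rms) if rms > 0 else x


def _blink_template(fs: float) -> np.ndarray:
    """A 0.5-s raised-cosine bump, the stylized ocular transient."""
    n = max(int(round(0.5 * fs)), 2)
    return np.hanning(n)


def generate_recording(
    config: GeneratorConfig,
    subject_id: str,
    label: int,
    rng: np.random.Generator | None = None,
) -> EEGRecording:
    """Generate one subject's recording.

    Each channel is the sum of one sinusoid per canonical band (frequency
    uniform in the band, uniform phase, amplitude set by the subject's
    class), pink noise of RMS ``noise_scale``, and — on frontal channels —
    blink bumps arriving as a Poisson process at ``blink_rate`` per minute.

    Fully determined by ``(config, seed, subject_id, label)`` when ``rng``
    is not supplied.
    """
    config.validate()
    if label not in (0, 1):
        raise InputError(f"label must be 0 or 1, got {label!r}")
    if rng is None:
        rng = subject_rng(config.seed, subject_id)

    n = int(round(config.fs * config.duration_s))
    t = np.arange(n) / config.fs
    nyq = config.fs / 2.0
    samples = np.zeros((config.montage.size, n))

    for ch in range(config.montage.size):
        x = np.zeros(n)
        for band in BAND_ORDER:
            low, high = band_limits(band, config.fs)
            high = min(high, nyq)
            if high <= low:
                continue
            amp = config.band_amplitudes[band][label]
            # keep the tone clear of the band edges so finite-window
            # spectral leakage cannot push its peak into a neighbor band
            margin = min(0.5, 0.1 * (high - low))
            f = rng.uniform(low + margin, high - margin)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            x += amp * np.sin(2.0 * np.pi * f * t + phase)
        x += _pink_noise(rng, n, config.noise_scale)
        samples[ch] = x

    if config.blink_rate > 0:
        template = _blink_template(config.fs)
        n_blinks = rng.poisson(config.blink_rate * config.duration_s / 60.0)
        starts = rng.integers(0, max(n - template.size, 1), size=n_blinks)
        frontal_idx = [
            config.montage.index(c)
            for c in FRONTAL_CHANNELS
            if c in config.montage.names
        ]
        for s in starts:
            amp = rng.uniform(60.0, 100.0)
            for ci in frontal_idx:
                samples[ci, s : s + template.size] += amp * template

    return EEGRecording(
        samples=samples,
        fs=config.fs,
        montage=config.montage,
        subject_id=subject_id,
        label=int(label),
    )


def generate_cohort(config: GeneratorConfig) -> list[EEGRecording]:
    """Generate the full cohort: healthy subjects first, then MDD.

    Subject ids are ``H001..`` and ``M001..``; per-subject streams are
    split deterministically from ``config.seed``.
    """
    config.validate()
    if config.n_healthy + config.n_mdd < 1:
        raise InputError("cohort must contain at least one subject")
    cohort: list[EEGRecording] = []
    for i in range(config.n_healthy):
        cohort.append(generate_recording(config, f"H{i + 1:03d}", 0))
    for i in range(config.n_mdd):
        cohort.append(generate_recording(config, f"M{i + 1:03d}", 1))
    return cohort


def iter_cohort(config: GeneratorConfig):
    """Lazily yield the cohort's recordings (memory-friendly for long runs)."""
    config.validate()
    if config.n_healthy + config.n_mdd < 1:
        raise InputError("cohort must contain at least one subject")
    for i in range(config.n_healthy):
        yield generate_recording(config, f"H{i + 1:03d}", 0)
    for i in range(config.n_mdd):
        yield generate_recording(config, f"M{i + 1:03d}", 1)
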