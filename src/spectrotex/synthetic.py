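"""Synthetic labeled multi-channel EEG with class-specific band power.

The generator emulates the one property of clinical resting-state EEG this
pipeline exploits: classes that differ by where their oscillatory power
sits in the spectrum.  Each class is a set of narrow-band sinusoids; each
subject of a class gets a small frequency jitter (<= 0.5 Hz) around the
class band centers; each channel gets an independent random phase and a
mild amplitude jitter, plus independent 1/f^alpha pink noise scaled to the
requested SNR.  The per-channel random phases matter: a sinusoid with a
common phase across channels is common-mode and would be cancelled by the
average-reference step.

The default study has five classes (mimicking an ASD / EP / PD / SZ /
healthy-control cohort), 4 subjects per class, 60 s per subject, 16
channels at 256 Hz, SNR 10 dB — well separated band centers inside the
40 Hz analysis passband.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .io import STANDARD_16_CHANNELS, RawRecording


@dataclass(frozen=True)
class ClassSpec:
    """Spectral signature of one class."""

    name: str
    band_centers_hz: tuple[float, ...]
    band_powers: tuple[float, ...]
    n_subjects: int = 4
    seconds_per_subject: float = 60.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic labeled EEG cohort."""

    classes: tuple[ClassSpec, ...]
    fs: float = 256.0
    n_channels: int = 16
    pink_exponent: float = 1.0
    snr_db: float = 10.0
    freq_jitter_hz: float = 0.5
    amplitude_jitter: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if not self.classes:
            raise ConfigurationError("at least one class is required")
        for cls in self.classes:
            if len(cls.band_centers_hz) != len(cls.band_powers):
                raise ConfigurationError(
                    f"class {cls.name}: band centers and powers differ in length"
                )
            for f in cls.band_centers_hz:
                if not 0 < f < self.fs / 2:
                    raise ConfigurationError(
                        f"class {cls.name}: band center {f} Hz outside "
                        f"(0, Nyquist={self.fs / 2})"
                    )
            if cls.n_subjects < 1:
                raise ConfigurationError("n_subjects must be >= 1")


def default_spec(seed: int = 0) -> SyntheticSpec:
    """The default five-class study with well-separated band centers."""
    bands = {"ASD": 6.0, "EP": 11.0, "PD": 16.0, "SZ": 24.0, "HC": 32.0}
    return SyntheticSpec(
        classes=tuple(ClassSpec(name, (f,), (1.0,)) for name, f in bands.items()),
        seed=seed,
    )


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                alpha: float) -> np.ndarray:
    """Unit-variance 1/f^alpha noise via spectral shaping of white noise."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-alpha / 2.0)
    noise = np.fft.irfft(spec * shape, n=n_samples, axis=1)
    sd = noise.std(axis=1, keepdims=True)
    return noise / np.where(sd > 0, sd, 1.0)


def generate_recording(spec: SyntheticSpec, cls: ClassSpec, subject_index: int,
                       rng: np.random.Generator) -> RawRecording:
    """One subject's recording: class sinusoids + pink noise at the SNR."""
    n = int(round(cls.seconds_per_subject * spec.fs))
    t = np.arange(n) / spec.fs
    signal = np.zeros((spec.n_channels, n))
    for f0, power in zip(cls.band_centers_hz, cls.band_powers):
        if power <= 0:
            continue
        f_subj = f0 + rng.uniform(-spec.freq_jitter_hz, spec.freq_jitter_hz)
        amp = np.sqrt(2.0 * power) * (
            1.0 + spec.amplitude_jitter * rng.standard_normal(spec.n_channels)
        )
        phase = rng.uniform(0, 2 * np.pi, spec.n_channels)
        signal += amp[:, None] * np.sin(2 * np.pi * f_subj * t[None, :]
                                        + phase[:, None])
    sig_power = float(np.mean(signal ** 2))
    if sig_power > 0:
        noise_power = sig_power / (10.0 ** (spec.snr_db / 10.0))
    else:  # noise-only cohort (all band powers zero)
        noise_power = 1.0
    noise = _pink_noise(rng, spec.n_channels, n, spec.pink_exponent)
    data = signal + np.sqrt(noise_power) * noise
    names = (list(STANDARD_16_CHANNELS[:spec.n_channels])
             if spec.n_channels <= len(STANDARD_16_CHANNELS)
             else [f"ch{i}" for i in range(spec.n_channels)])
    return RawRecording(data=data, fs=spec.fs, channel_names=names,
                        label=cls.name,
                        subject_id=f"{cls.name}_S{subject_index:02d}")


def generate_dataset(spec: SyntheticSpec) -> list[RawRecording]:
    """All recordings of the cohort; fully determined by ``spec.seed``."""
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    streams = root.spawn(sum(c.n_subjects for c in spec.classes))
    recordings: list[RawRecording] = []
    i = 0
    for cls in spec.classes:
        for s in range(cls.n_subjects):
            rng = np.random.default_rng(streams[i])
            recordings.append(generate_recording(spec, cls, s, rng))
            i += 1
    return recordings
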