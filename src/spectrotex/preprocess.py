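"""Signal conditioning and segmentation.

The conditioning chain follows standard resting-state EEG practice:
common average referencing (CAR) to cancel common-mode noise, a 40 Hz
low-pass IIR filter against muscle/ocular/line artifacts, per-channel
z-normalization to remove amplitude scale, then cutting into fixed-length
windows (3 s by default) that each inherit the recording's label and
subject id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfilt, sosfiltfilt

from .errors import ConfigurationError, ValidationError
from .io import RawRecording


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass IIR filter description.

    ``zero_phase`` applies the filter forward and backward (filtfilt), which
    doubles the effective order of the magnitude response but leaves event
    timing intact — preferable when the output feeds time-frequency images.
    """

    cutoff_hz: float = 40.0
    order: int = 4
    design: str = "butterworth"
    kind: str = "lowpass"
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if self.design != "butterworth" or self.kind != "lowpass":
            raise ConfigurationError(
                f"unsupported filter design {self.design}/{self.kind}"
            )
        if not 0 < self.cutoff_hz < fs / 2:
            raise ConfigurationError(
                f"cutoff {self.cutoff_hz} Hz must lie in (0, fs/2) = (0, {fs / 2})"
            )
        if self.order < 1:
            raise ConfigurationError("filter order must be >= 1")

    def sos(self, fs: float) -> np.ndarray:
        """Second-order-section coefficients of the designed filter."""
        self.validate(fs)
        return butter(self.order, self.cutoff_hz, btype="low", fs=fs, output="sos")


@dataclass
class Segment:
    """A fixed-length window cut from a (possibly single-channel) recording."""

    data: np.ndarray  # (n_channels, window_samples)
    fs: float
    label: str
    subject_id: str
    segment_index: int
    channel_name: str | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def common_average_reference(rec: RawRecording) -> RawRecording:
    """Subtract the across-channel mean at every sample (CAR).

    After CAR the across-channel mean signal is identically zero.
    """
    if rec.n_channels < 2:
        raise ValidationError(
            "common average referencing needs >= 2 channels "
            f"(got {rec.n_channels})"
        )
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return RawRecording(data=data, fs=rec.fs, channel_names=list(rec.channel_names),
                        label=rec.label, subject_id=rec.subject_id)


def lowpass_filter(rec: RawRecording, spec: FilterSpec = FilterSpec()) -> RawRecording:
    """Apply the low-pass IIR filter channel-wise (unit DC gain)."""
    sos = spec.sos(rec.fs)
    apply = sosfiltfilt if spec.zero_phase else sosfilt
    data = apply(sos, rec.data, axis=1)
    return RawRecording(data=np.ascontiguousarray(data), fs=rec.fs,
                        channel_names=list(rec.channel_names),
                        label=rec.label, subject_id=rec.subject_id)


def znormalize(rec: RawRecording) -> RawRecording:
    """Scale each channel to zero mean, unit variance.

    Constant channels (zero variance) are mapped to all-zeros rather than
    NaN so a flat electrode cannot poison downstream features.
    """
    mean = rec.data.mean(axis=1, keepdims=True)
    std = rec.data.std(axis=1, keepdims=True)
    centered = rec.data - mean
    data = np.divide(centered, std, out=np.zeros_like(centered), where=std > 0)
    return RawRecording(data=data, fs=rec.fs, channel_names=list(rec.channel_names),
                        label=rec.label, subject_id=rec.subject_id)


def segment_recording(
    rec: RawRecording,
    window_seconds: float = 3.0,
    per_channel: bool = True,
    overlap: float = 0.0,
) -> list[Segment]:
    """Cut a recording into consecutive windows of ``window_seconds``.

    The trailing remainder shorter than one window is discarded.  With
    ``per_channel`` (the default) each window is additionally split into
    single-channel segments tagged with their channel name — one segment
    per channel per window, matching one spectrogram image per segment
    downstream.  ``overlap`` is the fraction of a window shared by
    consecutive windows (0 = non-overlapping).
    """
    if window_seconds <= 0:
        raise ConfigurationError("window_seconds must be > 0")
    if not 0 <= overlap < 1:
        raise ConfigurationError("overlap must be in [0, 1)")
    win = int(round(window_seconds * rec.fs))
    hop = max(1, int(round(win * (1 - overlap))))
    if rec.n_samples < win:
        warnings.warn(
            f"recording {rec.subject_id!r} shorter than one window; no segments",
            stacklevel=2,
        )
        return []
    starts = range(0, rec.n_samples - win + 1, hop)
    segments: list[Segment] = []
    for si, t0 in enumerate(starts):
        block = rec.data[:, t0:t0 + win]
        if per_channel:
            for ch, name in enumerate(rec.channel_names):
                segments.append(Segment(block[ch:ch + 1].copy(), rec.fs,
                                        rec.label, rec.subject_id, si, name))
        else:
            segments.append(Segment(block.copy(), rec.fs,
                                    rec.label, rec.subject_id, si))
    return segments


def preprocess_recording(rec: RawRecording,
                         filter_spec: FilterSpec = FilterSpec()) -> RawRecording:
    """The full conditioning chain: CAR -> low-pass -> z-normalize."""
    return znormalize(lowpass_filter(common_average_reference(rec), filter_spec))
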