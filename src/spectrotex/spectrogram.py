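"""Short-time Fourier transform and grayscale spectrogram rendering.

A segment x[n] is cut into Hamming-windowed blocks of ``window_samples``
advanced by ``hop_samples``; each block's one-sided DFT magnitude forms one
column of the time-frequency matrix

    |X(tau, omega)| = |sum_n x[n] w[n - tau] exp(-i omega n)|.

Frames are taken only where a full window fits (no edge padding), so the
frame count is ``floor((n - window) / hop) + 1``.  The magnitude matrix is
then rendered as an 8-bit grayscale image: optional log compression,
frequency crop to the filter passband, per-image min-max scaling to
[0, 255] and bilinear resize to a fixed size (block partitioning downstream
requires every image in a run to share one size).  Row order follows image
convention with low frequencies at the bottom row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import get_window
from skimage.transform import resize as _sk_resize

from .errors import ConfigurationError
from .preprocess import Segment


@dataclass
class STFTMatrix:
    """One-sided STFT magnitude with its frequency/time axes."""

    magnitude: np.ndarray  # (n_freq_bins, n_frames), >= 0
    freqs: np.ndarray      # Hz, ascending from 0 to fs/2
    times: np.ndarray      # window-center times, seconds
    window_samples: int
    hop_samples: int

    @property
    def n_frames(self) -> int:
        return self.magnitude.shape[1]


@dataclass
class SpectrogramImage:
    """8-bit grayscale spectrogram with provenance metadata."""

    pixels: np.ndarray  # (H, W) uint8
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def stft(
    segment: Segment | np.ndarray,
    window_samples: int | None = None,
    hop_samples: int | None = None,
    fs: float | None = None,
) -> STFTMatrix:
    """Compute the Hamming-windowed one-sided STFT magnitude of one channel.

    ``segment`` is a single-channel :class:`Segment` or a 1-D array (then
    ``fs`` is required).  Defaults: window = fs/2 samples, hop = window/2
    (50% overlap) — about 11 frames on a 3 s segment at 256 Hz.
    """
    if isinstance(segment, Segment):
        if segment.data.shape[0] != 1:
            raise ConfigurationError(
                "stft expects a single-channel segment; use per_channel segmentation"
            )
        x = segment.data[0]
        fs = segment.fs
    else:
        x = np.asarray(segment, dtype=np.float64).ravel()
        if fs is None:
            raise ConfigurationError("fs is required for array input")
    n = x.size
    win = window_samples if window_samples is not None else int(fs) // 2
    hop = hop_samples if hop_samples is not None else max(1, win // 2)
    if win > n:
        raise ConfigurationError(f"window ({win}) longer than segment ({n})")
    if not 0 < hop <= win:
        raise ConfigurationError("hop must satisfy 0 < hop <= window")

    window = get_window("hamming", win)
    n_frames = (n - win) // hop + 1
    idx = np.arange(win)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * window
    mag = np.abs(np.fft.rfft(frames, axis=1)).T  # (bins, frames)
    freqs = np.fft.rfftfreq(win, d=1.0 / fs)
    times = (hop * np.arange(n_frames) + win / 2) / fs
    return STFTMatrix(mag, freqs, times, win, hop)


def render_image(
    S: STFTMatrix,
    height: int = 128,
    width: int = 128,
    log_scale: bool = True,
    freq_max_hz: float | None = 40.0,
    meta: dict | None = None,
) -> SpectrogramImage:
    """Render an STFT magnitude matrix as an 8-bit grayscale image.

    Pipeline: crop to [0, freq_max_hz] -> optional log10(1+m) compression ->
    per-image min-max scale to [0, 255] -> bilinear resize to
    (height, width) -> flip so frequency 0 is the bottom row.  A constant
    (or all-zero) magnitude maps to an all-zero image.
    """
    if height <= 0 or width <= 0:
        raise ConfigurationError("image size must be positive")
    m = S.magnitude
    if freq_max_hz is not None:
        nyquist = S.freqs[-1]
        if freq_max_hz > nyquist + 1e-9:
            raise ConfigurationError(
                f"freq_max_hz {freq_max_hz} exceeds Nyquist {nyquist}"
            )
        m = m[S.freqs <= freq_max_hz + 1e-9]
    m = np.log10(1.0 + m) if log_scale else m.astype(np.float64)
    lo, hi = m.min(), m.max()
    scaled = np.zeros_like(m) if hi - lo < 1e-12 else (m - lo) * (255.0 / (hi - lo))
    img = _sk_resize(scaled, (height, width), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    img = np.flipud(img)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return SpectrogramImage(pixels=pixels, meta=dict(meta or {}))


def segment_to_image(
    segment: Segment,
    window_samples: int | None = None,
    hop_samples: int | None = None,
    height: int = 128,
    width: int = 128,
    log_scale: bool = True,
    freq_max_hz: float | None = 40.0,
) -> SpectrogramImage:
    """Convenience: STFT + render, carrying segment provenance into meta."""
    S = stft(segment, window_samples, hop_samples)
    meta = {
        "subject_id": segment.subject_id,
        "label": segment.label,
        "channel_name": segment.channel_name,
        "segment_index": segment.segment_index,
    }
    return render_image(S, height, width, log_scale, freq_max_hz, meta)


def image_filename(img: SpectrogramImage) -> str:
    m = img.meta
    return (f"{m.get('subject_id', 'x')}_{m.get('channel_name', 'x')}_"
            f"{m.get('segment_index', 0)}_{m.get('label', 'x')}.png")


def save_png(img: SpectrogramImage, path) -> None:
    """Write the image as an 8-bit grayscale PNG."""
    from PIL import Image

    Image.fromarray(img.pixels, mode="L").save(path)


def load_png(path) -> SpectrogramImage:
    from PIL import Image

    with Image.open(path) as im:
        return SpectrogramImage(pixels=np.asarray(im.convert("L")))
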