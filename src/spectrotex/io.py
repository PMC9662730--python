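"""Reading, writing and standardizing multi-channel EEG recordings.

A recording is a channels x samples matrix with a sampling rate, ordered
channel names, a class label and a subject id.  Amplitude units are treated
as arbitrary: the preprocessing stage z-normalizes every channel, so only
relative waveform shape matters downstream.

Supported on-disk formats:

* **EDF** (European Data Format), read through :mod:`mne`.  A minimal
  16-bit EDF writer is provided for fixtures and export.
* **CSV** dialect: first row = channel names, each following row = one
  channel's samples (one column per sample).
* **NPY**: a bare ``channels x samples`` array; the sampling rate must be
  supplied by the caller or a JSON sidecar.

A JSON sidecar ``<path>.json`` may carry ``fs``, ``label`` and
``subject_id`` for formats that do not store them.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.signal import resample_poly

from .errors import ConfigurationError, ValidationError

#: The 16-electrode subset shared by all source montages (10-20 system),
#: used as the common channel standard.
STANDARD_16_CHANNELS = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "C3", "C4",
    "P3", "P4", "T3", "T4", "T5", "T6", "O1", "O2",
)

#: Reference suffixes commonly appended to electrode labels by acquisition
#: software; stripped before channel-name matching.
_REFERENCE_SUFFIXES = ("-A1", "-A2", "-REF", "-LE", "-AVG")


@dataclass
class RawRecording:
    """One subject's multi-channel EEG.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal matrix, arbitrary amplitude units.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        One unique name per row of ``data``.
    label : str
        Class label of the recording (e.g. ``"SZ"``).
    subject_id : str
        Identifier shared by all recordings of one subject.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    label: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        self.channel_names = list(self.channel_names)
        self.validate()

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be > 0, got {self.fs}")
        if self.data.ndim != 2 or self.n_samples == 0:
            raise ValidationError("data must be a non-empty channels x samples matrix")
        if len(self.channel_names) != self.n_channels:
            raise ValidationError(
                f"{self.n_channels} data rows but {len(self.channel_names)} channel names"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValidationError("channel names must be unique")
        bad = ~np.isfinite(self.data)
        if bad.any():
            ch, samp = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite value in channel '{self.channel_names[ch]}' "
                f"(index {ch}) at sample {samp}"
            )


@dataclass(frozen=True)
class ChannelStandard:
    """Target montage: an ordered channel subset and a common sampling rate."""

    names: tuple[str, ...] = STANDARD_16_CHANNELS
    target_fs: float = 256.0


def _normalize_name(name: str) -> str:
    """Case-fold a channel label and strip common reference suffixes."""
    s = name.strip().upper()
    for suf in _REFERENCE_SUFFIXES:
        if s.endswith(suf):
            s = s[: -len(suf)]
            break
    return s


def _sidecar(path: Path) -> dict:
    side = path.with_name(path.name + ".json")
    if side.exists():
        with open(side) as fh:
            return json.load(fh)
    return {}


def read_recording(
    path: str | Path,
    format: str | None = None,
    label: str = "",
    subject_id: str = "",
    fs: float | None = None,
) -> RawRecording:
    """Load a recording from ``path``.

    ``format`` is one of ``"edf"``, ``"csv"``, ``"npy"``; when omitted it is
    inferred from the file suffix.  ``fs`` is required for formats that do
    not carry a sampling rate (CSV/NPY) unless a JSON sidecar supplies it.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    meta = _sidecar(path)
    fs = fs if fs is not None else meta.get("fs")
    label = label or meta.get("label", "")
    subject_id = subject_id or meta.get("subject_id", "")

    if fmt == "edf":
        data, rate, names = _read_edf(path)
    elif fmt == "csv":
        data, names = _read_csv_matrix(path)
        rate = fs
    elif fmt == "npy":
        data = np.load(path)
        names = meta.get("channel_names") or [f"ch{i}" for i in range(len(data))]
        rate = fs
    else:
        raise ConfigurationError(f"unknown recording format '{fmt}'")

    if rate is None:
        raise ConfigurationError(
            f"sampling rate for {path.name} not in file, sidecar or arguments"
        )
    return RawRecording(data=data, fs=float(rate), channel_names=names,
                        label=label, subject_id=subject_id)


def _read_csv_matrix(path: Path) -> tuple[np.ndarray, list[str]]:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise ValidationError(f"{path.name}: need a header row and >=1 channel row")
    names = [c.strip() for c in lines[0].split(",")]
    rows = []
    for i, ln in enumerate(lines[1:]):
        try:
            rows.append(np.array([float(v) for v in ln.split(",")]))
        except ValueError as exc:
            raise ValidationError(f"{path.name}: unparsable value in row {i}: {exc}")
    if len(rows) != len(names):
        raise ValidationError(
            f"{path.name}: {len(names)} header names but {len(rows)} channel rows"
        )
    if len({r.size for r in rows}) != 1:
        raise ValidationError(f"{path.name}: channel rows have unequal lengths")
    return np.vstack(rows), names


def write_recording_csv(rec: RawRecording, path: str | Path,
                        sidecar: bool = True) -> None:
    """Write the CSV dialect (header of names, one row per channel)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(",".join(rec.channel_names) + "\n")
        for row in rec.data:
            fh.write(",".join(f"{v:.10g}" for v in row) + "\n")
    if sidecar:
        with open(path.with_name(path.name + ".json"), "w") as fh:
            json.dump({"fs": rec.fs, "label": rec.label,
                       "subject_id": rec.subject_id}, fh)


def _read_edf(path: Path) -> tuple[np.ndarray, float, list[str]]:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    try:
        data = raw.get_data(units="uV")
    except (ValueError, KeyError):  # dimensionless channels
        data = raw.get_data()
    return np.asarray(data), float(raw.info["sfreq"]), list(raw.ch_names)


def write_edf(rec: RawRecording, path: str | Path) -> None:
    """Write a minimal single-session 16-bit EDF file.

    Covers the subset of EDF needed to round-trip our recordings (one data
    record per second, physical dimension microvolts).  Requires an integer
    sampling rate and a whole number of seconds; trailing samples beyond the
    last full second are dropped, mirroring EDF's record structure.
    """
    path = Path(path)
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9:
        raise ConfigurationError("EDF writer requires an integer sampling rate")
    spr = fs  # samples per record (1 s records)
    nrec = rec.n_samples // spr
    if nrec == 0:
        raise ValidationError("recording shorter than one EDF record (1 s)")
    data = rec.data[:, : nrec * spr]
    nch = rec.n_channels
    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    pmax = np.where(pmax - pmin < 1e-9, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767

    def fixed(s, n: int) -> bytes:
        b = str(s).encode("ascii")[:n]
        return b + b" " * (n - len(b))

    hdr = b"".join([
        fixed("0", 8),
        fixed(f"X X X {rec.subject_id or 'X'}", 80),
        fixed("Startdate 01-JAN-2000 X X X", 80),
        fixed("01.01.00", 8), fixed("00.00.00", 8),
        fixed(256 * (1 + nch), 8), fixed("", 44),
        fixed(nrec, 8), fixed("1", 8), fixed(nch, 4),
        b"".join(fixed(nm, 16) for nm in rec.channel_names),
        b" " * (80 * nch),                       # transducer type
        b"".join(fixed("uV", 8) for _ in range(nch)),
        b"".join(fixed(f"{v:.6g}"[:8], 8) for v in pmin),
        b"".join(fixed(f"{v:.6g}"[:8], 8) for v in pmax),
        b"".join(fixed(dmin, 8) for _ in range(nch)),
        b"".join(fixed(dmax, 8) for _ in range(nch)),
        b" " * (80 * nch),                       # prefiltering
        b"".join(fixed(spr, 8) for _ in range(nch)),
        b" " * (32 * nch),
    ])
    # re-read the 8-char ASCII physical limits so digital and physical
    # scales agree exactly with what a reader will parse
    pmin = np.array([float(f"{v:.6g}"[:8]) for v in pmin])
    pmax = np.array([float(f"{v:.6g}"[:8]) for v in pmax])
    scale = (pmax - pmin) / (dmax - dmin)
    dig = np.round((data - pmin[:, None]) / scale[:, None] + dmin)
    dig = np.clip(dig, dmin, dmax).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(nrec):
            fh.write(dig[:, r * spr:(r + 1) * spr].tobytes())


def standardize_channels(rec: RawRecording,
                         std: ChannelStandard = ChannelStandard()) -> RawRecording:
    """Reduce a recording to the standard channel subset, in standard order.

    Matching is case-insensitive and ignores reference suffixes like
    ``-A1``/``-REF``; every standard channel must be present.
    """
    lookup: dict[str, int] = {}
    for i, name in enumerate(rec.channel_names):
        lookup.setdefault(_normalize_name(name), i)
    missing = [n for n in std.names if _normalize_name(n) not in lookup]
    if missing:
        raise ValidationError(
            "recording is missing required channels: " + ", ".join(missing)
        )
    idx = [lookup[_normalize_name(n)] for n in std.names]
    return RawRecording(data=rec.data[idx].copy(), fs=rec.fs,
                        channel_names=list(std.names),
                        label=rec.label, subject_id=rec.subject_id)


def resample_recording(rec: RawRecording, target_fs: float) -> RawRecording:
    """Band-limited (polyphase) resampling to ``target_fs``.

    Output length is ``round(n_samples * target_fs / fs)``.  A no-op when
    the rates already match.
    """
    if target_fs <= 0:
        raise ConfigurationError(f"target_fs must be > 0, got {target_fs}")
    if math.isclose(target_fs, rec.fs):
        return replace(rec, data=rec.data.copy())
    frac = Fraction(target_fs / rec.fs).limit_denominator(10000)
    out = resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    n_out = int(round(rec.n_samples * target_fs / rec.fs))
    out = out[:, :n_out]
    return RawRecording(data=out, fs=float(target_fs),
                        channel_names=list(rec.channel_names),
                        label=rec.label, subject_id=rec.subject_id)
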