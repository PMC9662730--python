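"""Single-document pipeline configuration.

Every stage reads its knobs from one nested mapping that can round-trip
through YAML/JSON.  Unknown keys are rejected (typos should fail loudly,
not silently fall back to defaults), and every pipeline run writes its
fully resolved configuration next to its outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class ChannelsConfig:
    names: list[str] = field(default_factory=lambda: [
        "Fp1", "Fp2", "F3", "F4", "F7", "F8", "C3", "C4",
        "P3", "P4", "T3", "T4", "T5", "T6", "O1", "O2"])
    target_fs: float = 256.0
    standardize: bool = True


@dataclass
class PreprocessConfig:
    cutoff_hz: float = 40.0
    filter_order: int = 4
    zero_phase: bool = True
    window_seconds: float = 3.0
    overlap: float = 0.0
    per_channel: bool = True


@dataclass
class StftConfig:
    window_samples: int | None = None  # default: fs / 2
    hop_samples: int | None = None     # default: window / 2


@dataclass
class ImageConfig:
    height: int = 128
    width: int = 128
    log_scale: bool = True
    freq_max_hz: float | None = 40.0


@dataclass
class TextureConfig:
    extractor: str = "tcentrist"  # tcentrist | ccentrist | centrist
    mu: float = 5.0
    riu2: bool = True
    normalize: bool = True


@dataclass
class PyramidConfig:
    levels: list[int] = field(default_factory=lambda: [0, 1, 2])


@dataclass
class PcaConfig:
    m: float = 0.95  # fraction of variance (float in (0,1)) or component count (int)
    cap: int = 500


@dataclass
class ClfConfig:
    kind: str = "svm_linear"  # svm_linear | knn | rf | lda
    k: int = 9
    c: float = 1.0
    n_trees: int = 100


@dataclass
class CvConfig:
    n_folds: int = 5
    mode: str = "segment"  # segment | subject


@dataclass
class SynthConfig:
    """Overrides applied on top of the default five-class synthetic study."""

    n_subjects: int | None = None
    seconds_per_subject: float | None = None
    snr_db: float | None = None
    n_channels: int | None = None
    fs: float | None = None
    classes: list[dict] | None = None  # [{name, band_centers_hz, band_powers}]


@dataclass
class DataConfig:
    source: str = "synth"        # synth | manifest
    manifest: str | None = None  # CSV: path, format, label, subject_id[, fs]


@dataclass
class OutputConfig:
    save_images: bool = False
    save_descriptors: bool = False


@dataclass
class PipelineConfig:
    data: DataConfig = field(default_factory=DataConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    channels: ChannelsConfig = field(default_factory=ChannelsConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    stft: StftConfig = field(default_factory=StftConfig)
    image: ImageConfig = field(default_factory=ImageConfig)
    texture: TextureConfig = field(default_factory=TextureConfig)
    pyramid: PyramidConfig = field(default_factory=PyramidConfig)
    pca: PcaConfig = field(default_factory=PcaConfig)
    clf: ClfConfig = field(default_factory=ClfConfig)
    cv: CvConfig = field(default_factory=CvConfig)
    output: OutputConfig = field(default_factory=OutputConfig)
    seed: int = 0

    def validate(self) -> None:
        fs = self.channels.target_fs
        if not 0 < self.preprocess.cutoff_hz < fs / 2:
            raise ConfigurationError(
                f"preprocess.cutoff_hz={self.preprocess.cutoff_hz} must lie in "
                f"(0, target_fs/2 = {fs / 2})"
            )
        if self.image.freq_max_hz is not None and self.image.freq_max_hz > fs / 2:
            raise ConfigurationError("image.freq_max_hz exceeds Nyquist")
        if self.texture.extractor not in ("tcentrist", "ccentrist", "centrist"):
            raise ConfigurationError(
                f"unknown texture.extractor '{self.texture.extractor}'"
            )
        if self.cv.mode not in ("segment", "subject"):
            raise ConfigurationError(f"unknown cv.mode '{self.cv.mode}'")
        if self.data.source not in ("synth", "manifest"):
            raise ConfigurationError(f"unknown data.source '{self.data.source}'")
        if self.data.source == "manifest" and not self.data.manifest:
            raise ConfigurationError("data.manifest path required")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _from_mapping(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigurationError(
            f"unknown config key(s) under '{path}': {sorted(unknown)}"
        )
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        if dataclasses.is_dataclass(_SECTION_TYPES.get(name)) and isinstance(value, dict):
            kwargs[name] = _from_mapping(_SECTION_TYPES[name], value,
                                         f"{path}.{name}" if path else name)
        else:
            kwargs[name] = value
    return cls(**kwargs)


_SECTION_TYPES = {
    "data": DataConfig, "synth": SynthConfig, "channels": ChannelsConfig,
    "preprocess": PreprocessConfig, "stft": StftConfig, "image": ImageConfig,
    "texture": TextureConfig, "pyramid": PyramidConfig, "pca": PcaConfig,
    "clf": ClfConfig, "cv": CvConfig, "output": OutputConfig,
}


def config_from_dict(data: dict) -> PipelineConfig:
    """Build and validate a config from a nested mapping (strict keys)."""
    cfg = _from_mapping(PipelineConfig, data or {}, "")
    cfg.validate()
    return cfg


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML (or JSON) configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})
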