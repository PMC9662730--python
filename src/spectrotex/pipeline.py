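"""End-to-end orchestration: recordings -> images -> descriptors -> CV.

The stages are the library functions of the other modules; this module
wires them according to a :class:`~spectrotex.config.PipelineConfig`,
keeps per-stage counters (recordings, segments, images, features, folds)
and persists results.  Descriptors are cached in memory per extractor so
a sweep over classifiers pays the image and texture cost once.
"""

from __future__ import annotations

import csv
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluate, io, preprocess, spectrogram, synthetic, texture
from .classify import ClassifierSpec
from .config import PipelineConfig
from .errors import ConfigurationError

log = logging.getLogger("spectrotex")


@dataclass
class FeatureSet:
    """Descriptor matrix plus per-image provenance."""

    X: np.ndarray              # (n_images, L) float32
    labels: np.ndarray         # (n_images,) str
    subjects: np.ndarray       # (n_images,) str
    channels: np.ndarray       # (n_images,) str
    segment_index: np.ndarray  # (n_images,) int
    extractor: str

    def to_frame(self) -> pd.DataFrame:
        meta = pd.DataFrame({
            "subject_id": self.subjects, "label": self.labels,
            "channel": self.channels, "segment_index": self.segment_index,
            "extractor": self.extractor,
        })
        feats = pd.DataFrame(self.X,
                             columns=[f"f{i}" for i in range(self.X.shape[1])])
        return pd.concat([meta, feats], axis=1)


@dataclass
class PipelineResult:
    reports: dict[str, evaluate.MetricsReport]
    counters: dict[str, int]
    config: PipelineConfig
    features: FeatureSet | None = None


def load_recordings(config: PipelineConfig) -> list[io.RawRecording]:
    """Materialize the input cohort (synthetic study or a file manifest)."""
    if config.data.source == "synth":
        spec = build_synthetic_spec(config)
        return synthetic.generate_dataset(spec)
    recs = []
    with open(config.data.manifest) as fh:
        for row in csv.DictReader(fh):
            recs.append(io.read_recording(
                row["path"], format=row.get("format") or None,
                label=row.get("label", ""), subject_id=row.get("subject_id", ""),
                fs=float(row["fs"]) if row.get("fs") else None,
            ))
    if not recs:
        raise ConfigurationError("manifest lists no recordings")
    return recs


def build_synthetic_spec(config: PipelineConfig) -> synthetic.SyntheticSpec:
    """Default five-class study with any config overrides applied."""
    base = synthetic.default_spec(seed=config.seed)
    s = config.synth
    classes = base.classes
    if s.classes is not None:
        classes = tuple(
            synthetic.ClassSpec(
                name=c["name"],
                band_centers_hz=tuple(c["band_centers_hz"]),
                band_powers=tuple(c["band_powers"]),
                n_subjects=c.get("n_subjects", s.n_subjects or 4),
                seconds_per_subject=c.get("seconds_per_subject",
                                          s.seconds_per_subject or 60.0),
            ) for c in s.classes
        )
    elif s.n_subjects is not None or s.seconds_per_subject is not None:
        classes = tuple(
            synthetic.ClassSpec(
                c.name, c.band_centers_hz, c.band_powers,
                n_subjects=s.n_subjects or c.n_subjects,
                seconds_per_subject=s.seconds_per_subject or c.seconds_per_subject,
            ) for c in classes
        )
    return synthetic.SyntheticSpec(
        classes=classes,
        fs=s.fs or base.fs,
        n_channels=s.n_channels or base.n_channels,
        snr_db=base.snr_db if s.snr_db is None else s.snr_db,
        seed=config.seed,
    )


def recordings_to_images(recs: list[io.RawRecording], config: PipelineConfig,
                         counters: dict | None = None
                         ) -> list[spectrogram.SpectrogramImage]:
    """Standardize, condition, segment and render every recording."""
    cfg = config
    std = io.ChannelStandard(tuple(cfg.channels.names), cfg.channels.target_fs)
    fspec = preprocess.FilterSpec(cutoff_hz=cfg.preprocess.cutoff_hz,
                                  order=cfg.preprocess.filter_order,
                                  zero_phase=cfg.preprocess.zero_phase)
    images: list[spectrogram.SpectrogramImage] = []
    n_segments = 0
    for rec in recs:
        if cfg.channels.standardize:
            rec = io.standardize_channels(rec, std)
            rec = io.resample_recording(rec, std.target_fs)
        rec = preprocess.preprocess_recording(rec, fspec)
        segments = preprocess.segment_recording(
            rec, cfg.preprocess.window_seconds,
            per_channel=cfg.preprocess.per_channel,
            overlap=cfg.preprocess.overlap)
        n_segments += len(segments)
        for seg in segments:
            images.append(spectrogram.segment_to_image(
                seg, cfg.stft.window_samples, cfg.stft.hop_samples,
                cfg.image.height, cfg.image.width,
                cfg.image.log_scale, cfg.image.freq_max_hz))
    if counters is not None:
        counters["n_recordings"] = len(recs)
        counters["n_segments"] = n_segments
        counters["n_images"] = len(images)
    log.info("rendered %d images from %d recordings", len(images), len(recs))
    return images


def extract_features(images: list[spectrogram.SpectrogramImage],
                     config: PipelineConfig,
                     extractor: str | None = None) -> FeatureSet:
    """Texture descriptors for every image (one row per image)."""
    cfg = config
    extractor = extractor or cfg.texture.extractor
    layout = texture.pyramid_blocks(cfg.image.height, cfg.image.width,
                                    cfg.pyramid.levels)
    n = len(images)
    length = texture.descriptor_length(extractor, layout, riu2=cfg.texture.riu2)
    X = np.empty((n, length), dtype=np.float32)
    labels = np.empty(n, dtype=object)
    subjects = np.empty(n, dtype=object)
    channels = np.empty(n, dtype=object)
    seg_idx = np.empty(n, dtype=int)
    for i, img in enumerate(images):
        desc = texture.extract_descriptor(
            img, extractor, layout, riu2=cfg.texture.riu2,
            mu=cfg.texture.mu, normalize=cfg.texture.normalize)
        X[i] = desc.values
        labels[i] = img.meta.get("label", "")
        subjects[i] = img.meta.get("subject_id", "")
        channels[i] = img.meta.get("channel_name", "")
        seg_idx[i] = img.meta.get("segment_index", 0)
    return FeatureSet(X, labels.astype(str), subjects.astype(str),
                      channels.astype(str), seg_idx, extractor)


def _clf_spec(config: PipelineConfig, kind: str | None = None) -> ClassifierSpec:
    c = config.clf
    return ClassifierSpec(kind=kind or c.kind, k=c.k, c=c.c,
                          n_trees=c.n_trees, seed=config.seed)


def run_pipeline(config: PipelineConfig,
                 out_dir: str | Path | None = None,
                 classifiers: list[str] | None = None) -> PipelineResult:
    """Execute the full pipeline and (optionally) persist its artifacts.

    ``classifiers`` defaults to the single configured ``clf.kind``; pass
    several kinds to share the per-fold PCA across them.
    """
    config.validate()
    counters: dict[str, int] = {}
    t0 = time.time()
    recs = load_recordings(config)
    images = recordings_to_images(recs, config, counters)
    feats = extract_features(images, config)
    counters["descriptor_length"] = feats.X.shape[1]
    kinds = classifiers or [config.clf.kind]
    specs = {k: _clf_spec(config, k) for k in kinds}
    reports = evaluate.run_cv_multi(
        feats.X, feats.labels, feats.subjects, specs,
        n_folds=config.cv.n_folds, mode=config.cv.mode, seed=config.seed,
        pca_m=config.pca.m, pca_cap=config.pca.cap)
    counters["n_folds"] = config.cv.n_folds
    counters["elapsed_s"] = int(time.time() - t0)
    log.info("pipeline done: %s", counters)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "resolved_config.yaml")
        for name, report in reports.items():
            report.to_json(out / f"metrics_{feats.extractor}_{name}.json")
        if config.output.save_descriptors:
            feats.to_frame().to_csv(out / f"descriptors_{feats.extractor}.csv",
                                    index=False)
        if config.output.save_images:
            img_dir = out / "images"
            img_dir.mkdir(exist_ok=True)
            for img in images:
                spectrogram.save_png(img, img_dir / spectrogram.image_filename(img))
    return PipelineResult(reports=reports, counters=counters, config=config,
                          features=feats)


def sweep(config: PipelineConfig,
          extractors: list[str] = ("ccentrist", "tcentrist"),
          classifiers: list[str] = ("svm_linear", "knn", "rf", "lda"),
          knn_k_values: range | list[int] = range(1, 11),
          out_dir: str | Path | None = None) -> pd.DataFrame:
    """Cross every extractor with every classifier on shared images.

    kNN is swept over ``knn_k_values`` and reported at its best k.  Returns
    a comparison table (one row per extractor x classifier) with five-fold
    mean/SD accuracy and fold-averaged per-class metrics.
    """
    if not extractors or not classifiers:
        raise ConfigurationError("sweep grid must be nonempty")
    config.validate()
    counters: dict[str, int] = {}
    recs = load_recordings(config)
    images = recordings_to_images(recs, config, counters)

    rows = []
    for extractor in extractors:
        feats = extract_features(images, config, extractor)
        specs: dict[str, ClassifierSpec] = {}
        for kind in classifiers:
            if kind == "knn":
                for k in knn_k_values:
                    spec = _clf_spec(config, "knn")
                    specs[f"knn_k{k}"] = ClassifierSpec(
                        kind="knn", k=k, c=spec.c, n_trees=spec.n_trees,
                        seed=spec.seed)
            else:
                specs[kind] = _clf_spec(config, kind)
        reports = evaluate.run_cv_multi(
            feats.X, feats.labels, feats.subjects, specs,
            n_folds=config.cv.n_folds, mode=config.cv.mode, seed=config.seed,
            pca_m=config.pca.m, pca_cap=config.pca.cap)

        knn_names = [n for n in reports if n.startswith("knn_k")]
        if knn_names:
            best = max(knn_names, key=lambda n: reports[n].mean_accuracy)
            reports["knn"] = reports[best]
            reports["knn_best_k"] = int(best.split("knn_k")[1])  # type: ignore
        for kind in classifiers:
            report = reports[kind]
            row = {"extractor": extractor, "classifier": kind,
                   "accuracy_mean": report.mean_accuracy,
                   "accuracy_sd": report.sd_accuracy}
            if kind == "knn":
                row["best_k"] = reports["knn_best_k"]
            for cls, m in report.average_class_metrics().items():
                for key, v in m.items():
                    row[f"{cls}_{key}"] = v
            rows.append(row)
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "resolved_config.yaml")
        table.to_csv(out / "comparison.csv", index=False)
    return table
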