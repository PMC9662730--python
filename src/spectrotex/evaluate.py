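"""Cross-validated evaluation: folds, confusion accounting, metrics, ROC.

Five-fold cross-validation with two split modes:

* ``segment`` (default) — stratified by class label over individual
  spectrogram images, mirroring an image-wise protocol.  Note that one
  subject's images can then appear in both train and test folds, a known
  optimistic bias for subject-level claims.
* ``subject`` — whole subjects are kept in a single fold (no subject
  leakage), balanced by image count.

For a K-class confusion matrix (rows = actual, columns = predicted), the
per-class counts are TP = cm[c][c], FN = row c - TP, FP = column c - TP
and TN = total - TP - FN - FP, from which sensitivity, specificity and
precision (percent), F1 (unitless) and overall accuracy
(100 * trace / total) follow.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve

from .classify import ClassifierSpec, fit_pca, train_classifier
from .errors import ValidationError

# ---------------------------------------------------------------------------
# Fold assignment


@dataclass
class FoldAssignment:
    """Maps every item index to a fold id in {0..n_folds-1}."""

    fold_of: np.ndarray
    n_folds: int
    mode: str
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)


def make_folds(labels, subjects=None, n_folds: int = 5,
               mode: str = "segment", seed: int = 0) -> FoldAssignment:
    """Partition items into folds.

    ``segment`` mode is stratified by label with fold sizes differing by at
    most one: each class's shuffled items are dealt in floor shares, and
    the leftover items are handed out round-robin through a cursor shared
    across classes.  ``subject`` mode assigns whole subjects to the
    currently least-loaded fold (largest subjects first).  Both modes are
    deterministic given ``seed``.
    """
    labels = np.asarray(labels)
    n = labels.size
    if n < n_folds:
        raise ValidationError(f"{n} items cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)

    if mode == "segment":
        cursor = 0
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            rng.shuffle(idx)
            base, extra = divmod(idx.size, n_folds)
            sizes = np.full(n_folds, base)
            for _ in range(extra):
                sizes[cursor % n_folds] += 1
                cursor += 1
            bounds = np.concatenate([[0], np.cumsum(sizes)])
            for f in range(n_folds):
                fold_of[idx[bounds[f]:bounds[f + 1]]] = f
    elif mode == "subject":
        if subjects is None:
            raise ValidationError("subject mode requires subject ids")
        subjects = np.asarray(subjects)
        uniq, counts = np.unique(subjects, return_counts=True)
        if uniq.size < n_folds:
            raise ValidationError(
                f"{uniq.size} subjects cannot fill {n_folds} folds"
            )
        order = np.lexsort((uniq, -counts))  # largest first, name-stable
        loads = np.zeros(n_folds, dtype=int)
        for s in order:
            f = int(np.argmin(loads))
            fold_of[subjects == uniq[s]] = f
            loads[f] += counts[s]
    else:
        raise ValidationError(f"unknown CV mode '{mode}'")
    return FoldAssignment(fold_of, n_folds, mode, seed)


# ---------------------------------------------------------------------------
# Confusion matrix and metrics


@dataclass
class ConfusionMatrix:
    """K x K count matrix; rows = actual class, columns = predicted."""

    counts: np.ndarray
    class_names: list[str]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def class_index(self, c) -> int:
        if isinstance(c, (int, np.integer)):
            return int(c)
        return self.class_names.index(c)


def confusion_from_predictions(actual, predicted, class_names) -> ConfusionMatrix:
    actual = np.asarray(actual)
    predicted = np.asarray(predicted)
    if actual.size == 0:
        raise ValidationError("no predictions to score")
    if actual.shape != predicted.shape:
        raise ValidationError("actual and predicted lengths differ")
    class_names = [str(c) for c in class_names]
    index = {c: i for i, c in enumerate(class_names)}
    counts = np.zeros((len(class_names), len(class_names)), dtype=int)
    for a, p in zip(actual, predicted):
        if str(a) not in index or str(p) not in index:
            raise ValidationError(f"label {a!r}/{p!r} not in class list")
        counts[index[str(a)], index[str(p)]] += 1
    return ConfusionMatrix(counts, class_names)


def class_counts(cm: ConfusionMatrix, c) -> dict[str, int]:
    """TP/FN/FP/TN for one class under the one-vs-rest accounting."""
    i = cm.class_index(c)
    tp = int(cm.counts[i, i])
    fn = int(cm.counts[i].sum()) - tp
    fp = int(cm.counts[:, i].sum()) - tp
    tn = cm.total - tp - fn - fp
    return {"TP": tp, "FN": fn, "FP": fp, "TN": tn}


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator computing {what}; reporting 0",
                      stacklevel=3)
        return 0.0
    return num / den


def class_metrics(cm: ConfusionMatrix, c) -> dict[str, float]:
    """Sensitivity, specificity, precision (percent) and F1 for class ``c``."""
    k = class_counts(cm, c)
    tp, fn, fp, tn = k["TP"], k["FN"], k["FP"], k["TN"]
    return {
        "Sen": 100.0 * _safe_ratio(tp, tp + fn, "sensitivity"),
        "Spec": 100.0 * _safe_ratio(tn, tn + fp, "specificity"),
        "Prec": 100.0 * _safe_ratio(tp, tp + fp, "precision"),
        "F1": _safe_ratio(2 * tp, 2 * tp + fp + fn, "F1"),
    }


def accuracy(cm: ConfusionMatrix) -> float:
    """Overall accuracy in percent: 100 * trace / total."""
    if cm.total == 0:
        raise ValidationError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def roc_points(actual, scores, c, class_names) -> np.ndarray:
    """One-vs-rest ROC points (FPR, TPR) for class ``c``, sorted by FPR."""
    actual = np.asarray(actual).astype(str)
    class_names = [str(x) for x in class_names]
    i = class_names.index(str(c))
    y_true = actual == class_names[i]
    if not y_true.any():
        raise ValidationError(f"class {c!r} absent from the actual labels")
    fpr, tpr, _ = roc_curve(y_true, np.asarray(scores)[:, i])
    return np.column_stack([fpr, tpr])


def macro_roc(actual, scores, class_names,
              grid: np.ndarray | None = None) -> np.ndarray:
    """Macro-average ROC: mean per-class TPR on a common FPR grid."""
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    tprs = []
    for c in class_names:
        pts = roc_points(actual, scores, c, class_names)
        tprs.append(np.interp(grid, pts[:, 0], pts[:, 1]))
    return np.column_stack([grid, np.mean(tprs, axis=0)])


def binomial_chance_sd(n_items: int, n_classes: int) -> float:
    """Standard deviation (in percent) of chance-level accuracy.

    Under the permutation null, each of ``n_items`` predictions is correct
    with probability 1/K independently, so accuracy is Binomial(n, 1/K)/n.
    """
    p = 1.0 / n_classes
    return 100.0 * float(np.sqrt(p * (1 - p) / n_items))


# ---------------------------------------------------------------------------
# Cross-validated pipeline evaluation


@dataclass
class MetricsReport:
    """Per-fold and fold-averaged metrics for one classifier."""

    class_names: list[str]
    mode: str
    seed: int
    fold_confusions: list[ConfusionMatrix]
    pooled_actual: np.ndarray
    pooled_scores: np.ndarray
    pca_components_per_fold: list[int]

    @property
    def fold_accuracies(self) -> np.ndarray:
        return np.array([accuracy(cm) for cm in self.fold_confusions])

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracies.mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.fold_accuracies.std(ddof=0))

    def average_class_metrics(self) -> dict[str, dict[str, float]]:
        """Per-class metrics averaged over folds."""
        out: dict[str, dict[str, float]] = {}
        for c in self.class_names:
            per_fold = [class_metrics(cm, c) for cm in self.fold_confusions]
            out[c] = {k: float(np.mean([m[k] for m in per_fold]))
                      for k in ("Sen", "Spec", "Prec", "F1")}
        return out

    def pooled_confusion(self) -> ConfusionMatrix:
        counts = sum(cm.counts for cm in self.fold_confusions)
        return ConfusionMatrix(counts, self.class_names)

    def roc(self, c) -> np.ndarray:
        return roc_points(self.pooled_actual, self.pooled_scores, c,
                          self.class_names)

    def to_dict(self) -> dict:
        return {
            "class_names": self.class_names,
            "cv_mode": self.mode,
            "seed": self.seed,
            "n_folds": len(self.fold_confusions),
            "fold_accuracies": [round(a, 6) for a in self.fold_accuracies],
            "accuracy_mean": round(self.mean_accuracy, 6),
            "accuracy_sd": round(self.sd_accuracy, 6),
            "per_class_avg": {
                c: {k: round(v, 6) for k, v in m.items()}
                for c, m in self.average_class_metrics().items()
            },
            "pooled_confusion": self.pooled_confusion().counts.tolist(),
            "pca_components_per_fold": self.pca_components_per_fold,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def run_cv_multi(
    X: np.ndarray,
    labels,
    subjects=None,
    clf_specs: dict[str, ClassifierSpec] | None = None,
    n_folds: int = 5,
    mode: str = "segment",
    seed: int = 0,
    pca_m: int | float = 0.95,
    pca_cap: int = 500,
) -> dict[str, MetricsReport]:
    """Cross-validate several classifiers on one descriptor matrix.

    The PCA projection is fitted per fold on the training rows only and
    shared by every classifier, so multi-classifier comparisons pay the
    reduction cost once.
    """
    if clf_specs is None:
        clf_specs = {"svm_linear": ClassifierSpec()}
    X = np.atleast_2d(np.asarray(X))
    labels = np.asarray(labels).astype(str)
    class_names = [str(c) for c in np.unique(labels)]
    folds = make_folds(labels, subjects, n_folds=n_folds, mode=mode, seed=seed)

    confusions: dict[str, list[ConfusionMatrix]] = {k: [] for k in clf_specs}
    pooled_a: list[np.ndarray] = []
    pooled_s: dict[str, list[np.ndarray]] = {k: [] for k in clf_specs}
    components: list[int] = []

    for f in range(n_folds):
        tr, te = folds.train_indices(f), folds.test_indices(f)
        pca = fit_pca(X[tr], m=pca_m, cap=pca_cap)
        components.append(pca.n_components)
        Xtr, Xte = pca.transform(X[tr]), pca.transform(X[te])
        pooled_a.append(labels[te])
        for name, spec in clf_specs.items():
            model = train_classifier(spec, Xtr, labels[tr])
            pred = model.predict(Xte)
            scores = model.score_matrix(Xte)
            confusions[name].append(
                confusion_from_predictions(labels[te], pred, class_names)
            )
            pooled_s[name].append(scores)

    actual = np.concatenate(pooled_a)
    return {
        name: MetricsReport(
            class_names=class_names, mode=mode, seed=seed,
            fold_confusions=confusions[name],
            pooled_actual=actual,
            pooled_scores=np.vstack(pooled_s[name]),
            pca_components_per_fold=components,
        )
        for name in clf_specs
    }


def run_cv(X, labels, subjects=None, clf: ClassifierSpec = ClassifierSpec(),
           **kwargs) -> MetricsReport:
    """Cross-validate a single classifier (see :func:`run_cv_multi`)."""
    return run_cv_multi(X, labels, subjects, {clf.kind: clf}, **kwargs)[clf.kind]
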