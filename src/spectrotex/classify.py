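"""PCA reduction and the four classical classifiers.

The descriptor matrices are wide (up to ~10^4 columns), so PCA is fitted
on training rows only and the classifiers operate on the reduced
coordinates.  Classifiers share one interface: ``classes_`` (sorted label
array), ``predict`` and ``score_matrix`` (an n x K per-class score used
for ROC curves — decision values for the linear SVM, vote fractions for
kNN and the random forest, discriminant values y_c for LDA).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .errors import ConfigurationError, ValidationError

# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAModel:
    """Fitted principal-component projection (basis + center)."""

    mean: np.ndarray                # (d,)
    components: np.ndarray          # (d, M), orthonormal columns
    explained_variance: np.ndarray  # (M,), descending
    total_variance: float

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.explained_variance / self.total_variance

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        return (X - self.mean) @ self.components


# problems with min(n, d) at or below this size take the exact full-SVD path
_EXACT_SVD_LIMIT = 1500


def fit_pca(X: np.ndarray, m: int | float = 0.95, cap: int = 500) -> PCAModel:
    """Fit a principal-component basis on training rows only.

    ``m`` is either a fixed component count or a variance fraction in
    (0, 1); in fraction mode the smallest M whose components explain at
    least that fraction is chosen, capped at ``cap``.

    Small problems use an exact economy SVD.  Wide matrices (n << d) use
    the Gram-matrix route: the top eigenpairs of X_c X_c^T give the same
    components at a fraction of the cost, and the exact variance total
    comes from the Gram trace.
    """
    X = np.atleast_2d(np.asarray(X))
    n, d = X.shape
    if n < 2:
        raise ValidationError("PCA needs at least 2 training rows")
    rank_bound = min(n - 1, d)
    if isinstance(m, (int, np.integer)):
        if not 1 <= m <= rank_bound:
            raise ConfigurationError(
                f"M={m} infeasible for an {n}x{d} training matrix (max {rank_bound})"
            )
        k_needed = int(m)
    else:
        if not 0 < m < 1:
            raise ConfigurationError("variance fraction must lie in (0, 1)")
        k_needed = min(cap, rank_bound)

    mean = X.mean(axis=0)
    Xc = X - mean

    if min(n, d) <= _EXACT_SVD_LIMIT:
        Xc64 = Xc.astype(np.float64)
        _, s, Vt = np.linalg.svd(Xc64, full_matrices=False)
        ev = (s ** 2) / (n - 1)
        total = float(ev.sum())
        components = Vt.T
    else:
        G = (Xc @ Xc.T).astype(np.float64)
        total = float(np.trace(G)) / (n - 1)
        w, U = eigh(G, subset_by_index=[n - k_needed, n - 1])
        w = np.maximum(w[::-1], 0.0)       # descending
        U = U[:, ::-1]
        ev = w / (n - 1)
        keep = w > 1e-12 * max(w[0], 1.0)
        w, U, ev = w[keep], U[:, keep], ev[keep]
        if isinstance(m, (int, np.integer)) and ev.size < m:
            raise ConfigurationError(
                f"M={m} exceeds the effective rank {ev.size} of the data"
            )
        components = (Xc.T.astype(np.float64) @ U) / np.sqrt(w)

    if isinstance(m, (int, np.integer)):
        M = int(m)
    else:
        ratio = np.cumsum(ev) / max(total, 1e-300)
        M = int(np.searchsorted(ratio, m) + 1)
        M = min(M, cap, ev.size)
    return PCAModel(mean=mean.astype(np.float64),
                    components=components[:, :M],
                    explained_variance=ev[:M].astype(np.float64),
                    total_variance=total)


# ---------------------------------------------------------------------------
# Classifiers


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier to train and its (few) hyperparameters."""

    kind: str = "svm_linear"  # svm_linear | knn | rf | lda
    k: int = 9                # kNN neighbor count (sweeps cover 1..10)
    c: float = 1.0            # SVM penalty
    n_trees: int = 100        # random-forest size
    seed: int = 0


def _check_training(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise ValidationError("X and y lengths differ")
    if not np.isfinite(X).all():
        raise ValidationError("training features contain non-finite values")
    if np.unique(y).size < 2:
        raise ValidationError("training labels contain a single class")
    return X, y


class LinearSVM:
    """One-vs-one linear-kernel SVM (libsvm); scores are one-vs-rest
    aggregated decision values and predictions are their argmax."""

    def __init__(self, c: float = 1.0):
        self._svc = SVC(kernel="linear", C=c, decision_function_shape="ovr")

    def fit(self, X, y):
        X, y = _check_training(X, y)
        self._svc.fit(X, y)
        self.classes_ = self._svc.classes_
        return self

    def score_matrix(self, X) -> np.ndarray:
        s = self._svc.decision_function(np.atleast_2d(X))
        if s.ndim == 1:  # binary: decision value for classes_[1]
            s = np.column_stack([-s, s])
        return s

    def predict(self, X):
        return self.classes_[np.argmax(self.score_matrix(X), axis=1)]


class KNN:
    """k-nearest-neighbor classifier with Euclidean distance.

    Scores are neighbor vote fractions.  Vote ties are broken by the
    smallest mean distance to the tied class's voting neighbors, then by
    class index — fully deterministic.
    """

    def __init__(self, k: int = 9):
        if k < 1:
            raise ConfigurationError(f"k must be >= 1, got {k}")
        self.k = k

    def fit(self, X, y):
        X, y = _check_training(X, y)
        if self.k > X.shape[0]:
            raise ValidationError(f"k={self.k} exceeds {X.shape[0]} training rows")
        self.classes_, self._yi = np.unique(y, return_inverse=True)
        self._nn = NearestNeighbors(metric="euclidean").fit(X)
        return self

    def _votes(self, X) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        dist, idx = self._nn.kneighbors(np.atleast_2d(X), n_neighbors=self.k)
        return dist, idx, self._yi[idx]

    def score_matrix(self, X) -> np.ndarray:
        _, _, labels = self._votes(X)
        K = self.classes_.size
        counts = np.stack([(labels == c).sum(axis=1) for c in range(K)], axis=1)
        return counts / self.k

    def predict(self, X):
        dist, _, labels = self._votes(X)
        K = self.classes_.size
        out = np.empty(labels.shape[0], dtype=int)
        for i in range(labels.shape[0]):
            counts = np.bincount(labels[i], minlength=K)
            best = np.flatnonzero(counts == counts.max())
            if best.size > 1:
                mean_d = [dist[i][labels[i] == c].mean() for c in best]
                best = best[np.flatnonzero(mean_d == np.min(mean_d))]
            out[i] = best[0]
        return self.classes_[out]


class RandomForest:
    """Entropy-impurity random forest; scores are tree vote fractions."""

    def __init__(self, n_trees: int = 100, seed: int = 0):
        self._rf = RandomForestClassifier(
            n_estimators=n_trees, criterion="entropy", max_features="sqrt",
            random_state=seed, n_jobs=1,
        )

    def fit(self, X, y):
        X, y = _check_training(X, y)
        self._rf.fit(X, y)
        self.classes_ = self._rf.classes_
        return self

    def score_matrix(self, X) -> np.ndarray:
        return self._rf.predict_proba(np.atleast_2d(X))

    def predict(self, X):
        return self.classes_[np.argmax(self.score_matrix(X), axis=1)]


class LDA:
    """Linear discriminant analysis scored directly from the discriminant

        y_c = x^T S^-1 mu_c - (1/2) mu_c^T S^-1 mu_c + log(n_c / n)

    with class means mu_c, a pooled within-class covariance S (ridge
    1e-6 on the diagonal for invertibility) and empirical priors n_c/n.
    """

    def __init__(self, ridge: float = 1e-6):
        self.ridge = ridge

    def fit(self, X, y):
        X, y = _check_training(X, y)
        self.classes_, yi = np.unique(y, return_inverse=True)
        n, d = X.shape
        K = self.classes_.size
        self.means_ = np.stack([X[yi == c].mean(axis=0) for c in range(K)])
        self.priors_ = np.bincount(yi, minlength=K) / n
        scatter = np.zeros((d, d))
        for c in range(K):
            Z = X[yi == c] - self.means_[c]
            scatter += Z.T @ Z
        cov = scatter / max(n - K, 1) + self.ridge * np.eye(d)
        self._sigma_inv_means = np.linalg.solve(cov, self.means_.T)  # (d, K)
        return self

    def score_matrix(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        lin = X @ self._sigma_inv_means
        const = -0.5 * np.sum(self.means_.T * self._sigma_inv_means, axis=0)
        return lin + const + np.log(self.priors_)

    def predict(self, X):
        return self.classes_[np.argmax(self.score_matrix(X), axis=1)]


def train_classifier(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray):
    """Build and fit the classifier described by ``spec``."""
    if spec.kind == "svm_linear":
        model = LinearSVM(c=spec.c)
    elif spec.kind == "knn":
        model = KNN(k=spec.k)
    elif spec.kind == "rf":
        model = RandomForest(n_trees=spec.n_trees, seed=spec.seed)
    elif spec.kind == "lda":
        model = LDA()
    else:
        raise ConfigurationError(f"unknown classifier kind '{spec.kind}'")
    return model.fit(X, y)


def predict(model, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels and per-class scores for ``X`` (column count must match fit)."""
    scores = model.score_matrix(X)
    return model.predict(X), scores
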