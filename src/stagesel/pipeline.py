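"""Feature-table plumbing: patch geometry, extractors, dimensionality
reduction, classifiers, metrics and leakage-free stratified CV.

The evaluation unit is a :class:`FeatureTable` (samples x numeric
features with binary labels: 1 = malignant / PTC-like, 0 = benign).
Both study datasets are heavily imbalanced, so all cross-validation is
stratified; metrics are pooled over out-of-fold predictions so one
confusion matrix describes the whole run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Protocol, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.decomposition import PCA, FastICA, TruncatedSVD
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.manifold import Isomap, LocallyLinearEmbedding
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

__all__ = [
    "FeatureTable",
    "MetricTriplet",
    "FeatureExtractor",
    "IdentityExtractor",
    "RandomProjectionExtractor",
    "patch_grid",
    "fuse_patch_features",
    "make_reducer",
    "reduce_features",
    "make_classifier",
    "stratified_folds",
    "cross_val_proba",
    "f2_score",
    "metrics_from_predictions",
    "evaluate_cv",
    "plot_roc",
    "plot_confusion",
    "REDUCERS",
    "CLASSIFIERS",
]

REDUCERS = ("pca", "tsvd", "fastica", "isomap", "lle", "umap")
CLASSIFIERS = ("lr", "nb", "svc", "knn", "rf")


@dataclass
class FeatureTable:
    """Numeric sample-by-feature matrix with binary labels.

    ``group_id`` optionally records a grouping key (e.g. patient) for
    datasets with several images per subject; the default evaluation unit
    is the individual sample.
    """

    X: np.ndarray
    y: np.ndarray
    feature_ids: tuple[str, ...] = ()
    group_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.y.ndim != 1 or self.X.shape[0] != self.y.size:
            raise ValueError("X must be 2-D with one label per row")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature table contains missing/non-finite values")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if not self.feature_ids:
            self.feature_ids = tuple(f"f{i}" for i in range(self.X.shape[1]))
        if len(self.feature_ids) != self.X.shape[1]:
            raise ValueError("feature ids must match column count")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def select(self, mask: np.ndarray) -> "FeatureTable":
        """Column-subset view with labels carried along."""
        mask = np.asarray(mask, dtype=bool)
        ids = tuple(f for f, keep in zip(self.feature_ids, mask) if keep)
        return FeatureTable(self.X[:, mask], self.y, ids, self.group_id)

    def to_csv(self, path: str | Path) -> None:
        frame = pd.DataFrame(self.X, columns=list(self.feature_ids))
        frame["label"] = self.y
        if self.group_id is not None:
            frame["group"] = self.group_id
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        frame = pd.read_csv(path)
        group = frame.pop("group").to_numpy() if "group" in frame.columns else None
        y = frame.pop("label").to_numpy()
        return cls(frame.to_numpy(dtype=float), y, tuple(frame.columns), group)


@dataclass(frozen=True)
class MetricTriplet:
    """The three ranking criteria plus auxiliary recall/specificity."""

    accuracy: float
    f2: float
    auc_roc: float
    recall: float = float("nan")
    specificity: float = float("nan")

    def as_criteria(self) -> tuple[float, float, float]:
        return (self.accuracy, self.f2, self.auc_roc)


# ---------------------------------------------------------------------------
# Patch geometry and fusion
# ---------------------------------------------------------------------------


def patch_grid(height_px: int, width_px: int, window_px: int) -> tuple[int, int, int]:
    """Patch counts for a sliding, non-overlapping window after padding.

    The image is enlarged (by augmentation) to the next integer multiple
    of the window, so ``rows = ceil(height/window)`` and likewise for
    columns. A 1053 x 1916 px slide with a 224 px window yields the 45
    patches used for the histopathological data.
    """
    if height_px <= 0 or width_px <= 0 or window_px <= 0:
        raise ValueError("image and window dimensions must be positive")
    rows = math.ceil(height_px / window_px)
    cols = math.ceil(width_px / window_px)
    return rows, cols, rows * cols


def fuse_patch_features(per_patch_vectors: Sequence[np.ndarray]) -> np.ndarray:
    """Concatenate per-patch feature vectors in patch raster order."""
    vectors = [np.asarray(v, dtype=float).ravel() for v in per_patch_vectors]
    if not vectors:
        raise ValueError("no patch vectors to fuse")
    length = vectors[0].size
    if any(v.size != length for v in vectors):
        raise ValueError("ragged patch vectors: all patches must share one length")
    return np.concatenate(vectors)


# ---------------------------------------------------------------------------
# Feature extractors (plug-in interface; deep networks are external plug-ins)
# ---------------------------------------------------------------------------


class FeatureExtractor(Protocol):
    """Maps raw samples (e.g. image patches) to fixed-length vectors."""

    def extract(self, samples: np.ndarray) -> np.ndarray: ...


class IdentityExtractor:
    """Flattens each sample; the no-op extractor."""

    def extract(self, samples: np.ndarray) -> np.ndarray:
        arr = np.asarray(samples, dtype=float)
        return arr.reshape(arr.shape[0], -1)


class RandomProjectionExtractor:
    """Seeded Gaussian projection emulating a frozen deep embedding."""

    def __init__(self, n_features: int, seed: int = 0):
        self.n_features = n_features
        self.seed = seed

    def extract(self, samples: np.ndarray) -> np.ndarray:
        flat = IdentityExtractor().extract(samples)
        rng = np.random.default_rng(self.seed)
        proj = rng.standard_normal((flat.shape[1], self.n_features))
        return flat @ proj / np.sqrt(flat.shape[1])


# ---------------------------------------------------------------------------
# Dimensionality reduction
# ---------------------------------------------------------------------------


def make_reducer(method: str, n_components: int, seed: int = 0):
    """Instantiate one of the six supported reducers (sklearn/umap)."""
    method = method.lower()
    if method == "pca":
        return PCA(n_components=n_components, random_state=seed)
    if method == "tsvd":
        return TruncatedSVD(n_components=n_components, random_state=seed)
    if method == "fastica":
        return FastICA(n_components=n_components, random_state=seed, max_iter=500)
    if method == "isomap":
        return Isomap(n_components=n_components)
    if method == "lle":
        return LocallyLinearEmbedding(n_components=n_components, random_state=seed)
    if method == "umap":
        import umap  # deferred: numba-backed import is slow

        return umap.UMAP(n_components=n_components, random_state=seed)
    raise ValueError(f"unknown reduction method {method!r}; expected one of {REDUCERS}")


def reduce_features(
    table: FeatureTable, method: str, n_components: int, seed: int = 0
) -> FeatureTable:
    """Project the table to ``n_components`` columns (fit on all rows).

    Inside cross-validation use :func:`evaluate_cv`, which re-fits the
    reducer on each training fold instead.
    """
    if not 0 < n_components < table.n_features:
        raise ValueError("n_components must be in (0, n_features)")
    reducer = make_reducer(method, n_components, seed)
    Z = reducer.fit_transform(table.X)
    ids = tuple(f"{method}{i}" for i in range(n_components))
    return FeatureTable(np.asarray(Z, dtype=float), table.y, ids, table.group_id)


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------


def make_classifier(name: str, seed: int = 0, **params):
    """Library-default classifiers with a fixed seed where stochastic."""
    name = name.lower()
    if name == "lr":
        return LogisticRegression(max_iter=1000, random_state=seed, **params)
    if name == "nb":
        return GaussianNB(**params)
    if name == "svc":
        return SVC(probability=True, random_state=seed, **params)
    if name == "knn":
        return KNeighborsClassifier(**params)
    if name == "rf":
        return RandomForestClassifier(random_state=seed, **params)
    raise ValueError(f"unknown classifier {name!r}; expected one of {CLASSIFIERS}")


# ---------------------------------------------------------------------------
# Stratified cross-validation
# ---------------------------------------------------------------------------


def stratified_folds(
    y: np.ndarray, k: int = 5, seed: int = 0
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Shuffled stratified k-fold indices; class counts per fold differ by
    at most one sample."""
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"every class needs at least k={k} members for stratification")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    yield from skf.split(np.zeros_like(y), y)


def cross_val_proba(
    table: FeatureTable,
    classifier: str = "rf",
    reducer: tuple[str, int] | None = None,
    k: int = 5,
    seed: int = 0,
    classifier_params: dict | None = None,
    fit_reducer_on: str = "train",
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled out-of-fold positive-class probabilities.

    The reducer (if any) and the classifier are fit on each training fold
    only, so no test-fold information leaks into the model.
    ``fit_reducer_on="all"`` deliberately breaks that guard (fitting the
    reducer on the full table) and exists solely so tests can demonstrate
    that the guard matters; never use it for reported results.

    Returns ``(proba, y_pred)`` aligned to ``table.y``.
    """
    if fit_reducer_on not in ("train", "all"):
        raise ValueError("fit_reducer_on must be 'train' or 'all'")
    params = classifier_params or {}
    proba = np.empty(table.n_samples)

    leaked = None
    if reducer is not None and fit_reducer_on == "all":
        method, n_comp = reducer
        leaked = make_reducer(method, n_comp, seed).fit(table.X)

    for train_idx, test_idx in stratified_folds(table.y, k=k, seed=seed):
        X_train, X_test = table.X[train_idx], table.X[test_idx]
        if reducer is not None:
            if leaked is not None:
                X_train, X_test = leaked.transform(X_train), leaked.transform(X_test)
            else:
                method, n_comp = reducer
                red = make_reducer(method, n_comp, seed)
                X_train = red.fit_transform(X_train)
                X_test = red.transform(X_test)
        clf = clone(make_classifier(classifier, seed=seed, **params))
        clf.fit(X_train, table.y[train_idx])
        proba[test_idx] = clf.predict_proba(X_test)[:, list(clf.classes_).index(1)]
    return proba, (proba >= 0.5).astype(int)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def f2_score(tp: int, fp: int, fn: int) -> float:
    """F-beta with beta = 2: recall weighted four times precision.

    ``(1 + b^2) P R / (b^2 P + R)`` with P = tp/(tp+fp), R = tp/(tp+fn);
    0 when there are no true positives. Requires tp + fn > 0 (at least
    one actual positive).
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    if tp + fn == 0:
        raise ValueError("F2 undefined: no positive samples in the truth")
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    beta2 = 4.0
    return (1 + beta2) * precision * recall / (beta2 * precision + recall)


def metrics_from_predictions(
    y: np.ndarray, proba: np.ndarray, threshold: float = 0.5
) -> MetricTriplet:
    """Accuracy, F2 and AUC-ROC (plus recall/specificity) from pooled
    probabilities at the given decision threshold."""
    y = np.asarray(y, dtype=int)
    proba = np.asarray(proba, dtype=float)
    pred = (proba >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return MetricTriplet(
        accuracy=(tp + tn) / y.size,
        f2=f2_score(tp, fp, fn),
        auc_roc=float(roc_auc_score(y, proba)),
        recall=tp / (tp + fn),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
    )


def evaluate_cv(
    table: FeatureTable,
    classifier: str = "rf",
    reducer: tuple[str, int] | None = None,
    k: int = 5,
    seed: int = 0,
    classifier_params: dict | None = None,
    fit_reducer_on: str = "train",
) -> MetricTriplet:
    """Stratified k-fold evaluation with pooled out-of-fold metrics."""
    proba, _ = cross_val_proba(
        table,
        classifier=classifier,
        reducer=reducer,
        k=k,
        seed=seed,
        classifier_params=classifier_params,
        fit_reducer_on=fit_reducer_on,
    )
    return metrics_from_predictions(table.y, proba)


# ---------------------------------------------------------------------------
# Plotting (generic diagnostics; not part of the ranked criteria)
# ---------------------------------------------------------------------------


def plot_roc(y: np.ndarray, proba: np.ndarray, ax=None, label: str | None = None):
    """ROC curve from pooled out-of-fold probabilities."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(y, proba)
    if ax is None:
        _, ax = plt.subplots()
    auc = roc_auc_score(y, proba)
    ax.plot(fpr, tpr, label=f"{label or 'model'} (AUC={auc:.3f})")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend()
    return ax


def plot_confusion(y: np.ndarray, pred: np.ndarray, ax=None):
    """2x2 confusion-matrix heatmap (0 = benign, 1 = malignant)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from sklearn.metrics import confusion_matrix

    cm = confusion_matrix(y, pred, labels=[0, 1])
    if ax is None:
        _, ax = plt.subplots()
    ax.imshow(cm, cmap="Blues")
    for i in range(2):
        for j in range(2):
            ax.text(j, i, str(cm[i, j]), ha="center", va="center")
    ax.set_xlabel("predicted")
    ax.set_ylabel("actual")
    ax.set_xticks([0, 1])
    ax.set_yticks([0, 1])
    return ax
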