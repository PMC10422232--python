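"""Classifier harness: features, class balancing, models, evaluation.

The feature vector of a pixel is simply its reconstructed NDVI series — the
T (nominally 24) values in time order, unscaled.  Three model families share
one train/predict contract:

``random_forest``
    scikit-learn RandomForestClassifier (majority vote over decision trees).
``gradient_boosted_trees``
    XGBoost classifier (gradient-boosted CARTs).
``knn_dtw``
    k-nearest-neighbour classification under Dynamic Time Warping distance,
    implemented here: a lazy learner that stores the training series
    verbatim and votes over the k closest by DTW alignment cost.

A fourth family name, ``plugin``, is a registration slot for externally
supplied models (e.g. recurrent networks) behind the same contract; nothing
is registered by default.

Class imbalance is handled by random oversampling: minority classes are
duplicated with replacement until every class matches the majority count.
"""

from __future__ import annotations

import pickle
import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import train_test_split

from .datasets import LabeledDataset
from .series import NDVISeries

__all__ = [
    "ModelSpec",
    "EvalReport",
    "FittedModel",
    "oversample",
    "extract_features",
    "dtw_distance",
    "train",
    "predict",
    "evaluate",
    "split_dataset",
    "save_model",
    "load_model",
    "register_plugin",
    "MODEL_FAMILIES",
]

MODEL_FAMILIES = ("random_forest", "gradient_boosted_trees", "knn_dtw", "plugin")

_PLUGINS: dict[str, object] = {}

_MODEL_FORMAT = "phenocycle-model"
_MODEL_VERSION = 1


def register_plugin(name: str, factory) -> None:
    """Register a plugin model factory: ``factory(spec) -> estimator`` with
    sklearn-style ``fit(X, y)`` / ``predict(X)``."""
    _PLUGINS[name] = factory


@dataclass(frozen=True)
class ModelSpec:
    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(
                f"unknown model family {self.family!r}; choose from {MODEL_FAMILIES}"
            )
        if self.family == "knn_dtw" and self.hyperparameters.get("k", 1) < 1:
            raise ValueError("knn_dtw requires k >= 1")


@dataclass
class EvalReport:
    """Evaluation summary: overall accuracy, confusion counts, per-class recall."""

    overall_accuracy: float
    confusion_matrix: np.ndarray
    class_labels: np.ndarray
    per_class_recall: np.ndarray
    wall_time: float  # seconds, informational only

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": float(self.overall_accuracy),
            "confusion_matrix": self.confusion_matrix.tolist(),
            "class_labels": self.class_labels.tolist(),
            "per_class_recall": self.per_class_recall.tolist(),
            "wall_time": float(self.wall_time),
        }


def oversample(dataset: LabeledDataset, seed=None) -> LabeledDataset:
    """Random-oversample minority classes to the majority count.

    Every original sample is retained in its original order; duplicates (drawn
    with replacement) are appended.  An already balanced dataset is returned
    unchanged.
    """
    counts = dataset.class_counts()
    if not counts:
        raise ValueError("dataset has no classes")
    majority = max(counts.values())
    if all(c == majority for c in counts.values()):
        return dataset
    rng = np.random.default_rng(seed)
    extra: list[int] = []
    for label in sorted(counts):
        deficit = majority - counts[label]
        if deficit > 0:
            pool = np.flatnonzero(dataset.labels == label)
            extra.extend(rng.choice(pool, size=deficit, replace=True).tolist())
    keep = list(range(len(dataset))) + extra
    return dataset.subset(keep)


def extract_features(series: NDVISeries) -> np.ndarray:
    """Feature vector: the reconstructed NDVI values in time order, unscaled."""
    if not series.is_gap_free:
        raise ValueError("extract_features requires a reconstructed, gap-free series")
    return series.values.astype(float).copy()


def _feature_matrix(dataset: LabeledDataset) -> np.ndarray:
    return np.stack([extract_features(s) for s in dataset.series])


def dtw_distance(a, b) -> float:
    """Dynamic Time Warping alignment cost with absolute-difference local cost.

    Classic dynamic programme, unconstrained warping window, endpoints
    matched to endpoints.  Symmetric, non-negative, and zero iff the two
    sequences are identical up to repetition of values.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("dtw_distance requires non-empty sequences")
    n, m = len(a), len(b)
    prev = np.full(m + 1, np.inf)
    prev[0] = 0.0
    for i in range(1, n + 1):
        curr = np.full(m + 1, np.inf)
        ai = a[i - 1]
        for j in range(1, m + 1):
            cost = abs(ai - b[j - 1])
            curr[j] = cost + min(prev[j], curr[j - 1], prev[j - 1])
        prev = curr
    return float(prev[m])


class _KnnDtw:
    """Lazy KNN under DTW distance with deterministic tie-breaking."""

    def __init__(self, k: int = 1):
        self.k = k
        self._X: np.ndarray | None = None
        self._y: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_KnnDtw":
        self._X = np.asarray(X, dtype=float)
        self._y = np.asarray(y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self._X is None:
            raise ValueError("model not fitted")
        out = []
        for q in np.asarray(X, dtype=float):
            d = np.array([dtw_distance(q, x) for x in self._X])
            nearest = np.argsort(d, kind="stable")[: self.k]
            votes: dict[int, list[float]] = {}
            for idx in nearest:
                votes.setdefault(int(self._y[idx]), []).append(float(d[idx]))
            # majority vote; ties -> smaller mean distance -> lower class index
            best = min(
                votes.items(),
                key=lambda kv: (-len(kv[1]), float(np.mean(kv[1])), kv[0]),
            )[0]
            out.append(best)
        return np.asarray(out)


@dataclass
class FittedModel:
    """A fitted classifier plus the bookkeeping needed to apply it."""

    spec: ModelSpec
    estimator: object
    classes: np.ndarray
    n_features: int

    def predict_features(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"feature length {X.shape[-1]} does not match training "
                f"length {self.n_features}"
            )
        enc = self.estimator.predict(X)
        return self.classes[np.asarray(enc, dtype=int)]


def _build_estimator(spec: ModelSpec):
    hp = dict(spec.hyperparameters)
    if spec.family == "random_forest":
        return RandomForestClassifier(
            n_estimators=hp.pop("n_estimators", 100),
            max_depth=hp.pop("max_depth", None),
            random_state=spec.seed,
            **hp,
        )
    if spec.family == "gradient_boosted_trees":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=hp.pop("n_estimators", 100),
            max_depth=hp.pop("max_depth", 6),
            learning_rate=hp.pop("learning_rate", 0.1),
            random_state=spec.seed,
            verbosity=0,
            **hp,
        )
    if spec.family == "knn_dtw":
        return _KnnDtw(k=hp.pop("k", 1))
    factory = _PLUGINS.get(hp.pop("name", ""))
    if factory is None:
        raise ValueError("no plugin registered under the requested name")
    return factory(spec)


def train(dataset: LabeledDataset, spec: ModelSpec) -> FittedModel:
    """Fit a classifier on a labelled dataset of reconstructed series."""
    classes = np.unique(dataset.labels)
    if len(classes) < 2:
        raise ValueError("training requires at least two classes")
    X = _feature_matrix(dataset)
    # encode labels as 0..K-1 so every backend accepts them
    encoded = np.searchsorted(classes, dataset.labels)
    estimator = _build_estimator(spec)
    estimator.fit(X, encoded)
    return FittedModel(
        spec=spec, estimator=estimator, classes=classes, n_features=X.shape[1]
    )


def predict(model: FittedModel, series_batch) -> np.ndarray:
    """One label per series; series must be reconstructed (gap-free)."""
    if isinstance(series_batch, LabeledDataset):
        series_batch = series_batch.series
    X = np.stack([extract_features(s) for s in series_batch])
    return model.predict_features(X)


def evaluate(model: FittedModel, test: LabeledDataset) -> EvalReport:
    """Overall accuracy, confusion matrix and per-class recall on held-out data."""
    if len(test) == 0:
        raise ValueError("empty test set")
    t0 = time.perf_counter()
    pred = predict(model, test)
    wall = time.perf_counter() - t0
    labels = np.unique(np.concatenate([test.labels, pred]))
    cm = _sk_confusion(test.labels, pred, labels=labels)
    row_sums = cm.sum(axis=1)
    recall = np.divide(
        np.diag(cm), row_sums, out=np.zeros(len(labels)), where=row_sums > 0
    )
    return EvalReport(
        overall_accuracy=float(np.trace(cm)) / float(cm.sum()),
        confusion_matrix=cm,
        class_labels=labels,
        per_class_recall=recall,
        wall_time=wall,
    )


def split_dataset(
    dataset: LabeledDataset, test_fraction: float = 0.2, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified train/test split (default 80/20) with a fixed seed."""
    idx = np.arange(len(dataset))
    train_idx, test_idx = train_test_split(
        idx,
        test_size=test_fraction,
        random_state=seed,
        stratify=dataset.labels,
    )
    return dataset.subset(train_idx), dataset.subset(test_idx)


def save_model(model: FittedModel, path) -> None:
    payload = {
        "format": _MODEL_FORMAT,
        "version": _MODEL_VERSION,
        "model": model,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path) -> FittedModel:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if not isinstance(payload, dict) or payload.get("format") != _MODEL_FORMAT:
        raise ValueError(f"{path} is not a phenocycle model file")
    if payload.get("version") != _MODEL_VERSION:
        raise ValueError(f"unsupported model file version {payload.get('version')}")
    return payload["model"]
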