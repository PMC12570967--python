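"""Classifier-based verification of generated configurations and
surrogate model selection.

A trained single-channel image classifier assigns a *detected* class to
every generated sample; comparing against the *intended* conditioning
label yields per-class counts, a confusion matrix and a generation
accuracy. Uniformity of the generated class distribution is measured as
the KL divergence from the uniform distribution (natural log): values
near 0 mean the surrogate covers all classes evenly, large values flag
mode collapse. Candidate surrogates are ranked lexicographically —
smallest KL first, ties broken by greatest accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier

__all__ = [
    "SnapshotClassifier",
    "train_classifier",
    "classify_batch",
    "kl_from_uniform",
    "confusion_and_accuracy",
    "VerificationReport",
    "verify_surrogate",
    "select_best",
]


class SnapshotClassifier(BaseEstimator, ClassifierMixin):
    """ClassifierContract: single-channel binary snapshot → class
    probabilities.

    A multilayer perceptron over flattened pixels trained with Adam
    (lr 0.001, mirroring the verification training setup) on an 80/20
    train/validation split; per-epoch validation accuracy is recorded in
    ``validation_scores_``.
    """

    def __init__(self, hidden_sizes=(128,), split: float = 0.8,
                 learning_rate: float = 0.001, epochs: int = 30,
                 batch_size: int = 64, random_state: int | None = None):
        self.hidden_sizes = hidden_sizes
        self.split = split
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state

    def _flatten(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            X = X.reshape(len(X), -1)
        elif X.ndim == 2 and hasattr(self, "n_features_in_") \
                and X.shape[1] != self.n_features_in_:
            X = X.reshape(1, -1)
        return np.atleast_2d(X)

    def fit(self, X, y):
        if not 0 < self.split < 1:
            raise ValueError("split must be in (0, 1)")
        X = self._flatten(X)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("need at least 2 classes")
        X_tr, X_val, y_tr, y_val = train_test_split(
            X, y, train_size=self.split, stratify=y,
            random_state=self.random_state)
        self._mlp = MLPClassifier(
            hidden_layer_sizes=tuple(self.hidden_sizes), solver="adam",
            learning_rate_init=self.learning_rate,
            batch_size=min(self.batch_size, len(X_tr)),
            max_iter=1, warm_start=False, random_state=self.random_state)
        classes = np.unique(y)
        self.validation_scores_ = []
        # each partial_fit call runs one epoch over the training split, so
        # validation accuracy is reported per epoch
        for epoch in range(self.epochs):
            if epoch == 0:
                self._mlp.partial_fit(X_tr, y_tr, classes=classes)
            else:
                self._mlp.partial_fit(X_tr, y_tr)
            self.validation_scores_.append(float(self._mlp.score(X_val, y_val)))
        self.classes_ = self._mlp.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        return self._mlp.predict_proba(self._flatten(X))

    def predict(self, X) -> np.ndarray:
        X = self._flatten(X)
        if len(X) == 0:
            return np.array([], dtype=self.classes_.dtype)
        return self._mlp.predict(X)


def train_classifier(dataset, split: float = 0.8, lr: float = 0.001,
                     epochs: int = 30, seed: int | None = 0) -> SnapshotClassifier:
    """Train the verification classifier on a snapshot dataset."""
    images, labels = dataset.stacked()
    clf = SnapshotClassifier(split=split, learning_rate=lr, epochs=epochs,
                             random_state=seed)
    return clf.fit(images, labels)


def classify_batch(clf, images) -> np.ndarray:
    """Detected (argmax) class per image; deterministic for fixed weights."""
    images = np.asarray(images)
    if len(images) == 0:
        return np.array([], dtype=int)
    return np.asarray(clf.predict(images))


def kl_from_uniform(counts) -> float:
    """KL(empirical class distribution ‖ uniform), natural log.

    Σ p_i ln(p_i n) with p_i = counts_i / total and 0·ln 0 ≡ 0; zero iff
    the counts are exactly uniform, at most ln(n) (all mass on one class).
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1 or len(c) == 0:
        raise ValueError("counts must be a non-empty 1-D vector")
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("counts are all zero")
    p = c / total
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] * len(c))))


def confusion_and_accuracy(intended, detected, n_classes: int | None = None):
    """(n×n count matrix intended × detected, diagonal accuracy)."""
    intended = np.asarray(intended)
    detected = np.asarray(detected)
    if len(intended) == 0 or len(intended) != len(detected):
        raise ValueError("intended/detected must be equal non-zero length")
    if n_classes is None:
        n_classes = int(max(intended.max(), detected.max())) + 1
    cm = _sk_confusion(intended, detected, labels=np.arange(n_classes))
    acc = float(np.trace(cm) / cm.sum())
    return cm, acc


@dataclass
class VerificationReport:
    """Per-candidate verification summary used for model selection."""

    counts: np.ndarray
    kl_uniform: float
    confusion: np.ndarray
    accuracy: float
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_labels(cls, intended, detected, n_classes: int,
                    meta: dict | None = None) -> "VerificationReport":
        detected = np.asarray(detected)
        counts = np.bincount(detected, minlength=n_classes)
        cm, acc = confusion_and_accuracy(intended, detected, n_classes)
        return cls(counts=counts, kl_uniform=kl_from_uniform(counts),
                   confusion=cm, accuracy=acc, meta=meta or {})

    def to_dict(self) -> dict:
        return {
            "counts": self.counts.tolist(),
            "kl_uniform": self.kl_uniform,
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "meta": self.meta,
        }


def verify_surrogate(surrogate, clf, n_samples: int, seed0: int = 0,
                     meta: dict | None = None) -> VerificationReport:
    """Generate ``n_samples`` uniformly cycled over the classes, classify
    them, and summarise counts / KL / confusion / accuracy."""
    images, intended = surrogate.sample_uniform(n_samples, seed0=seed0)
    detected = classify_batch(clf, images)
    return VerificationReport.from_labels(
        intended, detected, n_classes=surrogate.n_classes_, meta=meta)


def select_best(candidates: list[VerificationReport]) -> int:
    """Index of the best candidate: minimal KL-from-uniform, ties broken
    by maximal generation accuracy (then by lowest index)."""
    if not candidates:
        raise ValueError("need at least one candidate")
    keys = [(r.kl_uniform, -r.accuracy, i) for i, r in enumerate(candidates)]
    return min(keys)[2]


def class_frequency_heatmap(report: VerificationReport, grid_shape,
                            path: str) -> None:
    """Class-count heatmap laid out on the (J, k) parameter grid
    (rows = J values, columns = k values)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    counts = report.counts.reshape(grid_shape)
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(counts, cmap="viridis")
    for (i, j), v in np.ndenumerate(counts):
        ax.text(j, i, str(int(v)), ha="center", va="center", color="w", fontsize=8)
    ax.set_xlabel("k index")
    ax.set_ylabel("J index")
    ax.set_title(f"KL from uniform = {report.kl_uniform:.4f}")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
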