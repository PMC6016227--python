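"""Four-class maximum-margin classifier: pairwise Gaussian-kernel SVMs.

The multiclass problem is decomposed one-vs-one: for k observed classes,
k(k-1)/2 binary soft-margin SVMs with a Gaussian (RBF) kernel are
trained, and a test point receives the class with the most pairwise
votes, ties broken by the lowest class index.  Features are
standardized (zero mean, unit variance, statistics fitted on the
training rows only) before the kernel, since sample-entropy components
of different IMF orders live on unequal scales.

The quadratic-programming solver is the standard maximum-margin
optimizer from scikit-learn; the pairwise decomposition and the voting
rule are explicit here so the tie-break is deterministic.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = ["SvmConfig", "TrainedModel", "train", "predict", "accuracy", "default_gamma"]


def default_gamma(X: np.ndarray) -> float:
    """Kernel width used when none is optimized: 1 / (n_features * var)."""
    var = float(X.var())
    if var == 0.0:
        var = 1.0
    return 1.0 / (X.shape[1] * var)


@dataclass(frozen=True)
class SvmConfig:
    """Gaussian-kernel soft-margin settings."""

    C: float = 1.0
    gamma: float | None = None  # None -> default_gamma of the training matrix
    class_weights: dict[int, float] | None = None

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass
class TrainedModel:
    """Pairwise binary separators plus the scaler fitted on training rows."""

    separators: dict[tuple[int, int], SVC]
    classes: list[int]
    config: SvmConfig
    scaler: StandardScaler
    gamma_used: float
    training_fingerprint: str = ""

    @property
    def n_separators(self) -> int:
        return len(self.separators)


def _fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


def train(X: np.ndarray, y: np.ndarray, config: SvmConfig | None = None) -> TrainedModel:
    """Fit the one-vs-one Gaussian SVM ensemble.

    Deterministic for identical inputs and config: the underlying solver
    is run with a fixed tolerance and no randomized components.

    Raises
    ------
    ValueError
        If fewer than 2 classes are present or any class has < 2 rows.
    """
    config = config or SvmConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train")
    for c in classes:
        if np.count_nonzero(y == c) < 2:
            raise ValueError(f"class {c} has fewer than 2 training rows")

    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    gamma = config.gamma if config.gamma is not None else default_gamma(Xs)

    separators: dict[tuple[int, int], SVC] = {}
    for a, b in combinations(classes, 2):
        mask = (y == a) | (y == b)
        weights = None
        if config.class_weights:
            weights = {c: config.class_weights.get(c, 1.0) for c in (a, b)}
        svc = SVC(kernel="rbf", C=config.C, gamma=gamma, class_weight=weights, tol=1e-3)
        svc.fit(Xs[mask], y[mask])
        separators[(a, b)] = svc

    return TrainedModel(
        separators=separators,
        classes=classes,
        config=config,
        scaler=scaler,
        gamma_used=gamma,
        training_fingerprint=_fingerprint(X, y),
    )


def predict(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Majority vote over the pairwise separators.

    Each binary separator casts one vote per row; the class with the
    most votes wins, ties going to the lowest class index.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.scaler.mean_.shape[0]:
        raise ValueError(
            f"expected {model.scaler.mean_.shape[0]} features, got shape {X.shape}"
        )
    Xs = model.scaler.transform(X)
    class_pos = {c: i for i, c in enumerate(model.classes)}
    votes = np.zeros((X.shape[0], len(model.classes)), dtype=int)
    for (a, b), svc in model.separators.items():
        pred = svc.predict(Xs)
        for c in (a, b):
            votes[pred == c, class_pos[c]] += 1
    # argmax returns the first (lowest-class) maximum: the tie-break.
    winners = np.argmax(votes, axis=1)
    return np.asarray(model.classes, dtype=int)[winners]


def accuracy(model: TrainedModel, X: np.ndarray, y: np.ndarray) -> float:
    """Fraction of rows predicted correctly, in [0, 1]."""
    y = np.asarray(y, dtype=int)
    if y.size == 0:
        raise ValueError("no rows to evaluate")
    return float(np.mean(predict(model, X) == y))
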