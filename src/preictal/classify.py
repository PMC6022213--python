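"""Base binary classifiers with crisp and calibrated soft labels.

Pre-ictal is the positive class (1), inter-ictal the negative (0).  Seven
algorithms sit behind one interface: a linear SVM (cost C = 5, Platt-scaled
probabilities via the estimator's internal cross-validated sigmoid fit),
kNN with k = 3 and k = 5, logistic regression, Gaussian naive Bayes, LDA
and QDA.  Each model emits, per window, a crisp class and a soft label —
the probability of the *predicted* class, hence always in [0.5, 1].

Windows whose soft label does not exceed the certainty cutoff (default
0.80, read strictly: exactly 0.80 is still ambiguous) form the ambiguous
set handed to the active learner.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

ALGORITHMS = ("svm", "knn3", "knn5", "logistic", "naive_bayes", "lda", "qda")

_PERSIST_VERSION = 1


def _estimator(algorithm: str, seed: int, svm_cost: float, min_class_count: int = 5):
    if algorithm == "svm":
        # Platt scaling: sigmoid calibration fitted by internal cross-validation
        svc = SVC(kernel="linear", C=svm_cost, random_state=seed)
        cv = int(np.clip(min_class_count, 2, 5))
        return CalibratedClassifierCV(svc, method="sigmoid", cv=cv, ensemble=False)
    if algorithm == "knn3":
        return KNeighborsClassifier(n_neighbors=3)
    if algorithm == "knn5":
        return KNeighborsClassifier(n_neighbors=5)
    if algorithm == "logistic":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if algorithm == "naive_bayes":
        return GaussianNB()
    if algorithm == "lda":
        return LinearDiscriminantAnalysis()
    if algorithm == "qda":
        return QuadraticDiscriminantAnalysis(reg_param=1e-6)
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


@dataclass
class ClassifierModel:
    algorithm: str
    pipeline: Pipeline
    seed: int
    n_features: int
    train_X: np.ndarray
    train_y: np.ndarray
    meta: dict = field(default_factory=dict)

    def save(self, path) -> None:
        payload = {"version": _PERSIST_VERSION, "model": self}
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @staticmethod
    def load(path) -> "ClassifierModel":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("version") != _PERSIST_VERSION:
            raise ValueError(f"unsupported model file version {payload.get('version')}")
        return payload["model"]


@dataclass
class ClassifierOutput:
    """Per-window crisp labels and soft labels (probability of the argmax class)."""

    crisp: np.ndarray  # (n,) in {0, 1}
    soft: np.ndarray  # (n,) in [0.5, 1]
    p_preictal: np.ndarray  # (n,) probability of class 1
    window_index: np.ndarray  # (n,)

    def __len__(self) -> int:
        return len(self.crisp)


def train(
    X: np.ndarray,
    y: np.ndarray,
    algorithm: str = "svm",
    seed: int = 0,
    svm_cost: float = 5.0,
) -> ClassifierModel:
    """Fit one of the seven base classifiers; deterministic given the seed.

    The caller is responsible for class balancing; both classes must be
    present.  Features are standardized inside the pipeline.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(
            f"training data contains a single class {classes.tolist()}; "
            "both pre-ictal (1) and inter-ictal (0) samples are required"
        )
    counts = np.array([(y == c).sum() for c in classes])
    if counts.min() < 2:
        # degenerate desk-scale input: replicate the singleton class so the
        # calibration CV has two folds to work with
        idx = np.flatnonzero(y == classes[int(np.argmin(counts))])
        X = np.vstack([X, X[idx]])
        y = np.concatenate([y, y[idx]])
        counts = np.array([(y == c).sum() for c in classes])
    pipeline = Pipeline(
        [
            ("scale", StandardScaler()),
            ("clf", _estimator(algorithm, seed, svm_cost, int(counts.min()))),
        ]
    )
    pipeline.fit(X, y)
    return ClassifierModel(
        algorithm=algorithm,
        pipeline=pipeline,
        seed=seed,
        n_features=X.shape[1],
        train_X=X,
        train_y=y,
        meta={"n_train": len(y), "svm_cost": svm_cost},
    )


def predict(model: ClassifierModel, X: np.ndarray) -> ClassifierOutput:
    """Classify windows; order preserved, one output per row of X."""
    X = np.asarray(X, dtype=np.float64)
    if X.size and X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match training dimension "
            f"{model.n_features}"
        )
    if len(X) == 0:
        empty = np.zeros(0)
        return ClassifierOutput(empty.astype(int), empty, empty, empty.astype(int))
    proba = model.pipeline.predict_proba(X)
    classes = model.pipeline.classes_
    p1 = proba[:, int(np.flatnonzero(classes == 1)[0])]
    crisp = (p1 >= 0.5).astype(int)
    soft = np.where(crisp == 1, p1, 1.0 - p1)
    return ClassifierOutput(
        crisp=crisp, soft=soft, p_preictal=p1, window_index=np.arange(len(X))
    )


def partition_ambiguous(
    output: ClassifierOutput, certainty_cutoff: float = 0.80
) -> tuple[np.ndarray, np.ndarray]:
    """Split window indices into (clear, ambiguous) by the certainty cutoff.

    Clear samples have soft label strictly greater than the cutoff; the two
    index arrays are disjoint and cover every window.
    """
    if not (0.5 < certainty_cutoff <= 1.0):
        raise ValueError("certainty_cutoff must lie in (0.5, 1]")
    clear = output.window_index[output.soft > certainty_cutoff]
    ambiguous = output.window_index[output.soft <= certainty_cutoff]
    return clear, ambiguous
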