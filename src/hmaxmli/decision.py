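"""Linear-SVM decision layer over C2 feature vectors.

C2 vectors are L2-normalised and fed to a linear max-margin classifier for
the binary LONG/SHORT judgement.  (For two classes, an all-pairs SVM with
majority voting reduces to this single binary machine.)  The decision value
is signed so that positive means LONG; an exact tie at 0 is classified LONG
by convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .stimuli import LONG, SHORT


def normalize_c2(v: np.ndarray) -> np.ndarray:
    """Scale a C2 vector (or a matrix of row vectors) to unit L2 norm.

    A zero vector is passed through unchanged with a warning, so that
    degenerate inputs cannot silently become NaN.
    """
    v = np.asarray(v, dtype=np.float64)
    if v.size == 0:
        raise ValueError("empty C2 vector")
    if v.ndim == 1:
        n = np.linalg.norm(v)
        if n == 0.0:
            warnings.warn("zero C2 vector passed through unnormalised")
            return v.copy()
        return v / n
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    if np.any(norms == 0.0):
        warnings.warn("zero C2 vector(s) passed through unnormalised")
    return v / np.where(norms > 0.0, norms, 1.0)


@dataclass
class TrainedClassifier:
    """A trained linear decision layer.

    ``weights``/``bias`` define the decision value w·v_normalised + b, with
    positive values mapped to LONG.
    """

    weights: np.ndarray
    bias: float
    n_features: int
    c_reg: float

    def decision_values(self, vectors: np.ndarray) -> np.ndarray:
        v = np.atleast_2d(np.asarray(vectors, dtype=np.float64))
        if v.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {v.shape[1]}")
        return normalize_c2(v) @ self.weights + self.bias


def train_classifier(vectors: np.ndarray, labels, C: float = 1e4
                     ) -> TrainedClassifier:
    """Fit the linear SVM on (raw) C2 vectors and LONG/SHORT labels.

    Vectors are normalised internally, so classification is invariant to
    positive rescaling of the raw C2 vectors.
    """
    x = normalize_c2(np.asarray(vectors, dtype=np.float64))
    y = np.asarray([lab == LONG for lab in labels], dtype=bool)
    if y.all() or not y.any():
        raise ValueError("training data must contain both LONG and SHORT")
    svm = SVC(kernel="linear", C=C)
    svm.fit(x, y)
    # classes_ is [False, True]; positive decision_function ⇒ True ⇒ LONG
    return TrainedClassifier(weights=svm.coef_.ravel().copy(),
                             bias=float(svm.intercept_[0]),
                             n_features=x.shape[1], c_reg=C)


def predict(clf: TrainedClassifier, vectors: np.ndarray):
    """Labels and decision values for one vector or a batch.

    Decision value ≥ 0 ⇒ LONG (the tie at exactly 0 goes to LONG).
    """
    single = np.asarray(vectors).ndim == 1
    values = clf.decision_values(vectors)
    labels = np.where(values >= 0.0, LONG, SHORT)
    if single:
        return str(labels[0]), float(values[0])
    return labels, values


def save_classifier(path, clf: TrainedClassifier, prototype_key: str = "") -> None:
    np.savez(path, weights=clf.weights, bias=clf.bias,
             n_features=clf.n_features, c_reg=clf.c_reg,
             normalisation=np.str_("l2"), prototype_key=np.str_(prototype_key))


def load_classifier(path) -> TrainedClassifier:
    with np.load(path) as f:
        return TrainedClassifier(weights=f["weights"], bias=float(f["bias"]),
                                 n_features=int(f["n_features"]),
                                 c_reg=float(f["c_reg"]))
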