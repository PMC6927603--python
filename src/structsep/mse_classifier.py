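"""Multi-class minimum-squared-error (MSE) linear classifier.

Each of the c classes gets a linear discriminant g_i(x) = a_i^T (1, x) on
bias-augmented feature vectors.  Stacking the n augmented sample rows into
X (n x (d+1)) and the one-hot class indicators into B (n x c), the weight
matrix A (columns a_i) is the least-squares solution

    A = X^+ B,

with X^+ the Moore-Penrose pseudo-inverse; A minimizes
trace((XA - B)^T (XA - B)).  A point is assigned to the class whose
discriminant is largest; ties break to the earliest class in class order
(and are logged).  The pseudo-inverse is computed by SVD with a relative
singular-value cutoff so collinear features (e.g. natural-vector count
columns, which sum to sequence length) are handled without blowing up.

Separation quality is summarized by the per-class resubstitution rate
R_i = M_i / N_i: the classifier is fitted on all points and those same
points are re-classified, measuring how well hyperplanes carve the classes
apart rather than out-of-sample generalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .feature_table import FeatureMatrix
from .rates import ClassRate, RatesTable

logger = logging.getLogger(__name__)

#: Relative SVD cutoff for the pseudo-inverse.
PINV_RCOND = 1e-12


@dataclass
class MSEModel:
    A: np.ndarray  # (d+1, c); row 0 is the bias weights
    class_order: list[str]

    @property
    def d(self) -> int:
        return self.A.shape[0] - 1

    @property
    def c(self) -> int:
        return self.A.shape[1]

    def discriminants(self, X: np.ndarray) -> np.ndarray:
        """g_i(x) for each row of X (n x d) -> (n x c)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.d:
            raise ValueError(f"expected {self.d}-dim points, got {X.shape[1]}")
        aug = np.hstack([np.ones((X.shape[0], 1)), X])
        return aug @ self.A


def _class_order(labels: Sequence[str]) -> list[str]:
    order: dict[str, None] = {}
    for lab in labels:
        order.setdefault(lab, None)
    return list(order)


def one_hot_targets(labels: Sequence[str], class_order: Sequence[str]) -> np.ndarray:
    """n x c indicator matrix B; row of a class-i sample is e_i."""
    index = {c: j for j, c in enumerate(class_order)}
    B = np.zeros((len(labels), len(class_order)))
    for i, lab in enumerate(labels):
        B[i, index[lab]] = 1.0
    return B


def fit_mse(
    features: FeatureMatrix | np.ndarray,
    labels: Sequence[str] | None = None,
    class_order: Sequence[str] | None = None,
) -> MSEModel:
    """Fit the weight matrix A = X^+ B on bias-augmented features."""
    if isinstance(features, FeatureMatrix):
        X = features.values
        labels = labels if labels is not None else features.labels
    else:
        X = np.asarray(features, dtype=float)
    if labels is None:
        raise ValueError("labels are required")
    if len(labels) != X.shape[0]:
        raise ValueError("labels do not align with feature rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    order = list(class_order) if class_order is not None else _class_order(labels)
    if len(order) < 2:
        raise ValueError("need at least 2 classes")
    aug = np.hstack([np.ones((X.shape[0], 1)), X])
    B = one_hot_targets(labels, order)
    A = np.linalg.pinv(aug, rcond=PINV_RCOND) @ B
    return MSEModel(A, order)


def predict_mse(model: MSEModel, X: FeatureMatrix | np.ndarray) -> list[str]:
    """Classify rows of X by the argmax discriminant (ties -> earliest class)."""
    if isinstance(X, FeatureMatrix):
        X = X.values
    g = model.discriminants(X)
    out: list[str] = []
    for row in g:
        best = int(np.argmax(row))  # argmax returns the first maximum
        if np.sum(row == row[best]) > 1:
            logger.info("discriminant tie broken toward class %r", model.class_order[best])
        out.append(model.class_order[best])
    return out


def mse_rates(
    model: MSEModel,
    features: FeatureMatrix | np.ndarray,
    labels: Sequence[str] | None = None,
    method: str = "features",
) -> RatesTable:
    """Resubstitution rates R_i = M_i / N_i plus the full confusion counts."""
    if isinstance(features, FeatureMatrix) and labels is None:
        labels = features.labels
    if labels is None:
        raise ValueError("labels are required")
    predicted = predict_mse(model, features)
    confusion: dict[tuple[str, str], int] = {}
    for true, pred in zip(labels, predicted):
        confusion[(true, pred)] = confusion.get((true, pred), 0) + 1
    rates = []
    for cls in model.class_order:
        n_i = sum(1 for lab in labels if lab == cls)
        m_i = confusion.get((cls, cls), 0)
        if n_i == 0:
            continue
        rates.append(ClassRate(cls, m_i, n_i))
    return RatesTable(method=method, classifier="mse", rates=rates, confusion=confusion)


def mse_cv_rates(
    features: FeatureMatrix | np.ndarray,
    labels: Sequence[str] | None = None,
    k: int = 5,
    seed: int = 0,
    method: str = "features",
) -> RatesTable:
    """Per-class rates under k-fold cross-validation.

    Provided for users who want out-of-sample numbers; every reported
    separation rate uses resubstitution (:func:`mse_rates`), which is the
    separability measure, not this.
    """
    if isinstance(features, FeatureMatrix):
        X = features.values
        labels = labels if labels is not None else features.labels
    else:
        X = np.asarray(features, dtype=float)
    if labels is None:
        raise ValueError("labels are required")
    labels = list(labels)
    n = X.shape[0]
    if not 2 <= k <= n:
        raise ValueError("k must be between 2 and the sample count")
    order = _class_order(labels)
    rng = np.random.default_rng(seed)
    folds = rng.permutation(n) % k
    predicted: list[str | None] = [None] * n
    for fold in range(k):
        test = folds == fold
        model = fit_mse(
            X[~test], [lab for lab, t in zip(labels, test) if not t], class_order=order
        )
        for idx, pred in zip(np.flatnonzero(test), predict_mse(model, X[test])):
            predicted[idx] = pred
    rates = []
    for cls in order:
        n_i = sum(1 for lab in labels if lab == cls)
        m_i = sum(1 for lab, pred in zip(labels, predicted) if lab == cls and pred == cls)
        rates.append(ClassRate(cls, m_i, n_i))
    return RatesTable(method=method, classifier="mse-cv", rates=rates)
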