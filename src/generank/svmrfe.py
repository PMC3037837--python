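"""Linear SVM training and recursive feature elimination (stage 3).

Backward elimination: train a linear soft-margin SVM, rank features by the
squared entries of its weight vector, drop the lowest-ranked feature(s), and
repeat until none remain.  The final subset is the smallest prefix of the
survival order that attains the best internal cross-validated accuracy on
the training data.

The trained model exposes its dual coefficients so the KKT identities —
W = Σ αᵢ yᵢ Xᵢ and Σ yᵢ αᵢ = 0 — can be verified on every fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "LinearSVMModel",
    "EliminationOrder",
    "train_linear_svm",
    "kkt_residuals",
    "rfe_ranking",
    "select_best_subset",
]

#: When set, every trained model is checked against the dual identities
#: (W = Σ αᵢ yᵢ Xᵢ and Σ yᵢ αᵢ = 0) at KKT_TOL.  The test suite enables it.
VERIFY_KKT = False
KKT_TOL = 1e-6


@dataclass
class LinearSVMModel:
    """A fitted linear SVM with its dual solution.

    ``alpha`` holds one nonnegative multiplier per training sample (zero for
    non-support vectors); ``weights`` and ``bias`` define the decision
    function w·x + b.
    """

    weights: np.ndarray
    bias: float
    alpha: np.ndarray
    support_indices: np.ndarray

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0.0, 1, -1)


def train_linear_svm(
    X: np.ndarray, y: np.ndarray, C: float = 1.0
) -> LinearSVMModel:
    """Fit a soft-margin linear SVM on samples × features data, labels ±1."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2:
        raise ValueError("X must be samples x features")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in X")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data contains a single class")
    if set(classes) != {-1, 1}:
        raise ValueError(f"labels must be -1/+1, got {classes}")
    if C <= 0:
        raise ValueError("C must be positive")

    clf = SVC(kernel="linear", C=C)
    clf.fit(X, y)
    # dual_coef_ stores alpha_i * y_i for support vectors; classes_ is
    # sorted (-1, +1) so the stored sign convention matches y directly.
    alpha = np.zeros(X.shape[0])
    alpha[clf.support_] = clf.dual_coef_[0] * y[clf.support_]
    model = LinearSVMModel(
        weights=clf.coef_[0].astype(float),
        bias=float(clf.intercept_[0]),
        alpha=alpha,
        support_indices=clf.support_.copy(),
    )
    if VERIFY_KKT:
        r_w, r_sum = kkt_residuals(model, X, y)
        if r_w > KKT_TOL or r_sum > KKT_TOL:
            raise AssertionError(
                f"KKT residuals exceed {KKT_TOL}: |W - sum a_i y_i X_i| = {r_w}, "
                f"|sum y_i a_i| = {r_sum}"
            )
    return model


def kkt_residuals(
    model: LinearSVMModel, X: np.ndarray, y: np.ndarray
) -> tuple[float, float]:
    """Residuals of W = Σ αᵢ yᵢ Xᵢ (max-abs) and Σ yᵢ αᵢ (abs)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w_from_dual = (model.alpha * y) @ X
    return (
        float(np.max(np.abs(w_from_dual - model.weights))),
        float(abs(np.sum(y * model.alpha))),
    )


@dataclass
class EliminationOrder:
    """Feature ids from first-eliminated to last-surviving (a permutation)."""

    feature_ids: list
    weights_per_round: list | None = None

    def __len__(self) -> int:
        return len(self.feature_ids)

    def __iter__(self):
        return iter(self.feature_ids)

    def survival_order(self) -> list:
        """Best feature first (reverse of elimination)."""
        return list(reversed(self.feature_ids))


def _round_step(step: int | float, n_remaining: int) -> int:
    if isinstance(step, float):
        if not (0.0 < step < 1.0):
            raise ValueError("fractional step must lie in (0, 1)")
        # speed-up mode: batch removal while many features remain
        if n_remaining > 100:
            return max(1, int(step * n_remaining))
        return 1
    if step < 1:
        raise ValueError("step must be >= 1")
    return int(step)


def rfe_ranking(
    X: np.ndarray,
    y: np.ndarray,
    step: int | float = 1,
    C: float = 1.0,
    feature_ids: Sequence | None = None,
    keep_weights: bool = False,
) -> EliminationOrder:
    """Recursive feature elimination ranked by squared SVM weights.

    Each round trains on the surviving features and removes the ``step``
    features with the smallest w²; among ties the later original index goes
    first (earlier features survive).  A fractional ``step`` removes that
    fraction per round while more than 100 features remain, then reverts to
    one-at-a-time.
    """
    X = np.asarray(X, dtype=float)
    n_features = X.shape[1]
    ids = list(feature_ids) if feature_ids is not None else list(range(n_features))
    if len(ids) != n_features:
        raise ValueError("feature_ids length mismatch")

    remaining = np.arange(n_features)
    eliminated: list[int] = []
    rounds: list[np.ndarray] = []
    while remaining.size > 0:
        if remaining.size == 1:
            eliminated.append(int(remaining[0]))
            break
        model = train_linear_svm(X[:, remaining], y, C=C)
        w2 = model.weights**2
        if keep_weights:
            rounds.append(w2.copy())
        s = min(_round_step(step, remaining.size), remaining.size)
        # removal order: smallest w2 first; ties -> larger original index first
        order = sorted(
            range(remaining.size), key=lambda i: (w2[i], -remaining[i])
        )
        drop = order[:s]
        eliminated.extend(int(remaining[i]) for i in drop)
        keep_mask = np.ones(remaining.size, dtype=bool)
        keep_mask[drop] = False
        remaining = remaining[keep_mask]
    return EliminationOrder(
        feature_ids=[ids[i] for i in eliminated],
        weights_per_round=rounds if keep_weights else None,
    )


def _clip_inner_folds(y: np.ndarray, inner_folds: int) -> int:
    min_class = int(min(np.sum(y == 1), np.sum(y == -1)))
    if min_class < 2:
        raise ValueError("each class needs >= 2 training samples for inner CV")
    if inner_folds > min_class:
        warnings.warn(
            f"inner_folds clipped from {inner_folds} to {min_class} "
            "(smaller class size)"
        )
        return min_class
    return inner_folds


def select_best_subset(
    order: EliminationOrder,
    X_train: np.ndarray,
    y_train: np.ndarray,
    inner_folds: int = 5,
    C: float = 1.0,
    seed: int = 0,
    feature_index: dict | None = None,
) -> list:
    """Pick the best nested subset by internal CV on the training data only.

    Candidates are the n prefixes of the survival order (last eliminated
    first).  Returns the smallest subset attaining the maximum mean
    accuracy.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    survival = order.survival_order()
    if feature_index is None:
        feature_index = {f: i for i, f in enumerate(survival)}
        if X_train.shape[1] != len(survival):
            raise ValueError(
                "X_train width must match the elimination order "
                "(or pass feature_index)"
            )
    cols = np.array([feature_index[f] for f in survival], dtype=int)

    folds = _clip_inner_folds(y_train, inner_folds)
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(splitter.split(X_train, y_train))

    best_k, best_acc = None, -1.0
    for k in range(1, len(survival) + 1):
        sub = X_train[:, cols[:k]]
        fold_accs = []
        for tr, te in splits:
            model = train_linear_svm(sub[tr], y_train[tr], C=C)
            fold_accs.append(float(np.mean(model.predict(sub[te]) == y_train[te])))
        acc = float(np.mean(fold_accs))
        if acc > best_acc:  # strict: keeps the smallest subset at ties
            best_k, best_acc = k, acc
    return survival[:best_k]
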