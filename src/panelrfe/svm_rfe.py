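"""Soft-margin RBF-SVM training and recursive feature elimination.

The classifier is the standard soft-margin SVM in its dual form: maximise
``sum(alpha) - 1/2 alpha' H alpha`` subject to ``0 <= alpha_i <= C`` and
``sum(alpha_i y_i) = 0``, where ``H_hk = y_h y_k K(x_h, x_k)`` and K is the
Gaussian RBF kernel ``K(x, x') = exp(-gamma ||x - x'||^2)``.  The dual optimum
is obtained through scikit-learn's SMO solver; the decision function, the
feature-elimination criterion and the elimination loop are implemented here
on top of the extracted multipliers.

The elimination criterion scores each active feature i by the change in the
dual quadratic form when that feature is deleted with the multipliers held
fixed::

    DJ(i) = 1/2 | alpha' H alpha - alpha' H(-i) alpha |

For the RBF kernel, deleting feature i from the squared distance factorises,
so ``K(-i)_hk = K_hk * exp(gamma (x_hi - x_ki)^2)`` — a multiplicative
downdate of the full kernel, evaluated on support vectors only.  The feature
with the smallest DJ is removed, the SVM is retrained on the survivors, and
the loop repeats down to a single feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .panel import PANEL
from .resampling import Partition
from .simulate import Cohort

__all__ = [
    "KernelConfig",
    "TrainedSVM",
    "AccuracyReport",
    "RFEResult",
    "RFEError",
    "rbf_kernel",
    "train_svm",
    "predict",
    "evaluate",
    "dj_scores",
    "dj_objective_change",
    "rfe_run",
    "evaluate_subset",
]


@dataclass(frozen=True)
class KernelConfig:
    """RBF-SVM hyperparameters.

    gamma
        Kernel width; ``None`` (default) resolves to
        ``1 / (d * pooled variance)`` of the (standardised) training matrix,
        d being the active feature count.
    C
        Soft-margin penalty (default 1.0).
    standardize
        z-score each feature by training-set statistics before the kernel
        (default True — raw analytes span four orders of magnitude, and an
        unscaled RBF would be dominated by the large-valued electrolytes).
    """

    gamma: float | None = None
    C: float = 1.0
    standardize: bool = True

    def __post_init__(self):
        if self.gamma is not None and not (np.isfinite(self.gamma) and self.gamma > 0):
            raise ValueError("gamma must be finite and positive")
        if not (np.isfinite(self.C) and self.C > 0):
            raise ValueError("C must be finite and positive")


class RFEError(RuntimeError):
    """Training failure inside the elimination loop (active-set size attached)."""

    def __init__(self, msg: str, active_size: int | None = None):
        super().__init__(msg)
        self.active_size = active_size


def rbf_kernel(X_a: np.ndarray, X_b: np.ndarray, gamma: float) -> np.ndarray:
    """Gaussian kernel matrix ``exp(-gamma ||x_a - x_b||^2)``.

    Entries lie in (0, 1]; the matrix is symmetric with unit diagonal when
    both arguments coincide.
    """
    if not (np.isfinite(gamma) and gamma > 0):
        raise ValueError("gamma must be finite and positive")
    X_a = np.atleast_2d(np.asarray(X_a, dtype=float))
    X_b = np.atleast_2d(np.asarray(X_b, dtype=float))
    if X_a.shape[1] != X_b.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: {X_a.shape[1]} vs {X_b.shape[1]}"
        )
    sq = (
        np.sum(X_a**2, axis=1)[:, None]
        + np.sum(X_b**2, axis=1)[None, :]
        - 2.0 * X_a @ X_b.T
    )
    np.maximum(sq, 0.0, out=sq)
    return np.exp(-gamma * sq)


@dataclass
class TrainedSVM:
    """Dual solution of one soft-margin RBF-SVM fit.

    ``alphas`` holds one multiplier per training row (zero off the support
    set); ``X`` is the training matrix after standardisation, i.e. in the
    space the kernel was evaluated in.
    """

    alphas: np.ndarray
    bias: float
    support_indices: np.ndarray
    X: np.ndarray
    y: np.ndarray
    gamma_: float
    config: KernelConfig
    scaler_mean: np.ndarray = field(repr=False, default=None)
    scaler_scale: np.ndarray = field(repr=False, default=None)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def transform(self, rows: np.ndarray) -> np.ndarray:
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        if rows.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {rows.shape[1]}"
            )
        if self.config.standardize:
            rows = (rows - self.scaler_mean) / self.scaler_scale
        return rows

    def decision_values(self, rows: np.ndarray) -> np.ndarray:
        """``sum_SV alpha_k y_k K(x_k, x) + b`` for each input row."""
        rows = self.transform(rows)
        sv = self.support_indices
        K = rbf_kernel(rows, self.X[sv], self.gamma_)
        return K @ (self.alphas[sv] * self.y[sv]) + self.bias


def _resolve_gamma(Xs: np.ndarray, config: KernelConfig) -> float:
    if config.gamma is not None:
        return config.gamma
    var = float(Xs.var())
    if var <= 0:
        var = 1.0
    return 1.0 / (Xs.shape[1] * var)


def train_svm(train_rows: np.ndarray, labels: np.ndarray,
              config: KernelConfig = KernelConfig()) -> TrainedSVM:
    """Solve the dual soft-margin problem on one training set.

    Features are optionally z-scored by training-set statistics; the scaler
    is stored on the model and reapplied to test rows.  Raises on degenerate
    (single-class) input.
    """
    X = np.atleast_2d(np.asarray(train_rows, dtype=float))
    y = np.asarray(labels, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("row/label count mismatch")
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")

    if config.standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0  # constant feature: leave centred at 0
        Xs = (X - mean) / scale
    else:
        mean = np.zeros(X.shape[1])
        scale = np.ones(X.shape[1])
        Xs = X

    gamma = _resolve_gamma(Xs, config)
    clf = SVC(C=config.C, kernel="rbf", gamma=gamma)
    clf.fit(Xs, y)

    alphas = np.zeros(X.shape[0])
    alphas[clf.support_] = np.abs(clf.dual_coef_[0])
    model = TrainedSVM(
        alphas=alphas,
        bias=float(clf.intercept_[0]),
        support_indices=clf.support_.copy(),
        X=Xs,
        y=y.astype(int),
        gamma_=gamma,
        config=config,
        scaler_mean=mean,
        scaler_scale=scale,
    )
    # dual feasibility: sum(alpha_i y_i) = 0, 0 <= alpha <= C
    resid = float(np.dot(alphas, y))
    if abs(resid) > 1e-6 * max(1.0, alphas.sum()):
        raise RFEError(f"dual equality constraint violated (residual {resid:g})")
    return model


def predict(model: TrainedSVM, rows: np.ndarray) -> np.ndarray:
    """Predicted labels: sign of the decision value, with 0 mapped to +1."""
    d = model.decision_values(rows)
    return np.where(d >= 0.0, 1, -1)


@dataclass(frozen=True)
class AccuracyReport:
    """Test-set confusion summary; P = (TP + TN) / M."""

    tp: int
    tn: int
    m: int

    @property
    def P(self) -> float:
        return (self.tp + self.tn) / self.m


def evaluate(model: TrainedSVM, rows: np.ndarray,
             labels: np.ndarray) -> AccuracyReport:
    pred = predict(model, rows)
    labels = np.asarray(labels)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == -1) & (labels == -1)))
    return AccuracyReport(tp=tp, tn=tn, m=len(labels))


def dj_objective_change(a_signed: np.ndarray, K_full: np.ndarray,
                        K_reduced: np.ndarray) -> float:
    """``1/2 |a' K a - a' K(-i) a|`` with ``a_k = alpha_k y_k`` held fixed.

    The y factors of H cancel into the signed multipliers, so the quadratic
    form over H equals the form over K with signed coefficients.
    """
    return 0.5 * abs(a_signed @ K_full @ a_signed
                     - a_signed @ K_reduced @ a_signed)


def dj_scores(model: TrainedSVM) -> np.ndarray:
    """Elimination score DJ(i) for every active feature of the model.

    Uses the multiplicative RBF downdate restricted to support vectors; a
    feature constant across the training rows scores exactly zero.
    """
    sv = model.support_indices
    Xsv = model.X[sv]
    a = model.alphas[sv] * model.y[sv]
    K = rbf_kernel(Xsv, Xsv, model.gamma_)
    base = a @ K @ a
    scores = np.empty(model.n_features)
    for i in range(model.n_features):
        diff = Xsv[:, i][:, None] - Xsv[:, i][None, :]
        K_red = K * np.exp(model.gamma_ * diff**2)
        scores[i] = 0.5 * abs(base - a @ K_red @ a)
    return scores


@dataclass
class RFEResult:
    """Outcome of one elimination run on one partition.

    ``elimination_order`` lists panel feature indices from first-removed to
    last-surviving (a permutation of the input features);
    ``accuracy_curve[s]`` is the test report for the active set of size s.
    """

    elimination_order: list[int]
    accuracy_curve: dict[int, AccuracyReport]
    best_subset: tuple[int, ...]
    best_accuracy: float
    ratio_tag: str = ""

    def active_set(self, size: int) -> tuple[int, ...]:
        """The active feature set when ``size`` features remained."""
        if not 1 <= size <= len(self.elimination_order):
            raise ValueError("size out of range")
        return tuple(sorted(self.elimination_order[-size:]))


def _feature_columns(features) -> list[int]:
    idx = [PANEL.resolve(f) for f in features]
    if len(set(idx)) != len(idx):
        raise ValueError("duplicate features")
    return idx


def evaluate_subset(partition: Partition, cohort: Cohort, features,
                    config: KernelConfig = KernelConfig()) -> AccuracyReport:
    """Train on the partition's training rows restricted to ``features`` and
    report test accuracy.  ``features`` are panel indices or analyte names."""
    cols = np.array(_feature_columns(features)) - 1
    X, y = cohort.X, cohort.y
    model = train_svm(X[np.ix_(partition.train_indices, cols)],
                      y[partition.train_indices], config)
    return evaluate(model, X[np.ix_(partition.test_indices, cols)],
                    y[partition.test_indices])


def rfe_run(partition: Partition, cohort: Cohort,
            config: KernelConfig = KernelConfig(),
            features=None) -> RFEResult:
    """Backward-eliminate features on one train/test partition.

    Starting from the full panel (or ``features``): train, record test
    accuracy, score every active feature with DJ, drop the single lowest
    scorer (ties drop the higher panel index), retrain — down to one feature.
    The best subset is the active set with maximal test accuracy, the
    smallest such set on ties.

    With ``config.gamma=None`` the kernel width is resolved **once**, on the
    full starting panel, and held fixed for every retrain in the loop: the
    elimination scores of successive stages must live on a single kernel
    scale, and a width re-inflated as the active set shrinks makes the
    absolute-value criterion favour noise features in the endgame.
    """
    active = _feature_columns(features if features is not None
                              else PANEL.indices)
    X, y = cohort.X, cohort.y
    tr, te = partition.train_indices, partition.test_indices

    if config.gamma is None:
        X0 = X[np.ix_(tr, np.array(active) - 1)]
        if config.standardize:
            scale = X0.std(axis=0)
            scale[scale == 0] = 1.0
            X0 = (X0 - X0.mean(axis=0)) / scale
        config = KernelConfig(gamma=_resolve_gamma(X0, config),
                              C=config.C, standardize=config.standardize)

    order: list[int] = []
    curve: dict[int, AccuracyReport] = {}
    best_size, best_p = None, -1.0
    while active:
        cols = np.array(active) - 1
        try:
            model = train_svm(X[np.ix_(tr, cols)], y[tr], config)
        except (ValueError, RFEError) as exc:
            raise RFEError(
                f"training failed with {len(active)} active features: {exc}",
                active_size=len(active),
            ) from exc
        report = evaluate(model, X[np.ix_(te, cols)], y[te])
        curve[len(active)] = report
        # descending sizes: '>=' keeps the smallest set among ties
        if report.P >= best_p:
            best_p, best_size = report.P, len(active)
        if len(active) == 1:
            order.append(active.pop())
            break
        scores = dj_scores(model)
        lowest = np.flatnonzero(scores <= scores.min() + 1e-15)
        drop_pos = max(lowest, key=lambda p: active[p])
        order.append(active.pop(int(drop_pos)))

    result = RFEResult(
        elimination_order=order,
        accuracy_curve=curve,
        best_subset=(),
        best_accuracy=best_p,
        ratio_tag=partition.ratio_tag,
    )
    result.best_subset = result.active_set(best_size)
    return result
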