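"""Linear soft-margin SVM, confusion-matrix metrics, and repeated k-fold CV.

The classifier is the standard L1 soft-margin maximum-margin hyperplane

    min_{w,b}  0.5 ||w||^2 + C * sum_i max(0, 1 - y_i (w . x_i + b)),

trained by SMO on the dual (see :mod:`citnirs._solver`).  Labels are
+1 for the patient group (CL) and -1 for healthy controls (HC); a
decision value of exactly zero is classified as positive.

Performance is summarised by sensitivity, specificity, accuracy, the
Matthews correlation coefficient (MCC) and balanced accuracy
(bACC = (sensitivity + specificity) / 2), the two headline measures for
the imbalanced 30-vs-25 cohort.  Cross-validation is stratified 5-fold,
repeated 20 times with fresh seeded shuffles, and fold partitions are a
pure function of (seed, repeat) so that different channel subsets can be
compared on identical folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold, StratifiedGroupKFold, StratifiedKFold

from ._solver import _cv_counts, _smo

__all__ = [
    "LinearModel",
    "ConfusionMatrix",
    "MetricSet",
    "CVConfig",
    "CVResult",
    "train_linear_svm",
    "decision_function",
    "predict",
    "confusion",
    "metrics",
    "svm_objective",
    "fold_assignments",
    "repeated_kfold",
    "compare_metric_distributions",
]

TRAIN_TOL = 1e-6


@dataclass
class LinearModel:
    """Separating hyperplane w . x + b = 0 with the penalty it was fit at."""

    w: np.ndarray
    b: float
    C: float

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if not np.all(np.isfinite(self.w)) or not np.isfinite(self.b):
            raise ValueError("model parameters must be finite")

    def to_json(self, path, channels: tuple[str, ...] | None = None,
                **metadata) -> None:
        import json

        payload = {"w": self.w.tolist(), "b": self.b, "C": self.C,
                   "channels": list(channels) if channels else None,
                   **metadata}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "LinearModel":
        import json

        with open(path) as fh:
            payload = json.load(fh)
        return cls(w=np.asarray(payload["w"]), b=payload["b"], C=payload["C"])


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class MetricSet:
    """sensitivity/specificity/accuracy/bACC as fractions, MCC in [-1, 1]."""

    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    bacc: float

    @property
    def bacc_pct(self) -> float:
        return 100.0 * self.bacc


@dataclass(frozen=True)
class CVConfig:
    """Repeated k-fold setup: k folds x `repeats` seeded shuffles."""

    folds: int = 5
    repeats: int = 20
    stratified: bool = True
    grouped: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("need at least 2 folds")
        if self.repeats < 1:
            raise ValueError("need at least 1 repeat")


@dataclass
class CVResult:
    fold_metrics: list[MetricSet]
    fold_counts: np.ndarray  # (folds*repeats, 4) TP, FN, FP, TN

    @property
    def mean_mcc(self) -> float:
        return float(np.mean([m.mcc for m in self.fold_metrics]))

    @property
    def mean_bacc(self) -> float:
        return float(np.mean([m.bacc for m in self.fold_metrics]))

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([m.accuracy for m in self.fold_metrics]))

    def to_frame(self, folds: int) -> "pd.DataFrame":
        """One row per (repeat, fold): counts and the five metrics."""
        import pandas as pd

        rows = []
        for i, (counts, m) in enumerate(zip(self.fold_counts, self.fold_metrics)):
            rows.append(
                {"repeat": i // folds, "fold": i % folds,
                 "TP": int(counts[0]), "FN": int(counts[1]),
                 "FP": int(counts[2]), "TN": int(counts[3]),
                 "sensitivity": m.sensitivity, "specificity": m.specificity,
                 "accuracy": m.accuracy, "MCC": m.mcc, "bACC": m.bacc_pct}
            )
        return pd.DataFrame(rows)

    def to_csv(self, path, folds: int) -> None:
        self.to_frame(folds).to_csv(path, index=False)


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, d) with one label per row")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise ValueError("labels must be +1/-1")
    return X, y


def train_linear_svm(
    X: np.ndarray, y: np.ndarray, C: float = 1.0, tol: float = TRAIN_TOL
) -> LinearModel:
    """Fit the maximum-margin hyperplane on labelled feature vectors.

    Requires both classes present and C > 0.  ``tol`` is the maximal
    KKT violation accepted on the dual.
    """
    X, y = _check_xy(X, y)
    if C <= 0:
        raise ValueError("C must be positive")
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    K = X @ X.T
    alpha, b, n_iter = _smo(K, y, float(C), float(tol), 1_000_000)
    w = X.T @ (alpha * y)
    return LinearModel(w=w, b=float(b), C=float(C))


def decision_function(model: LinearModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.w.shape[0]:
        raise ValueError(
            f"dimension mismatch: model is {model.w.shape[0]}-d, got {X.shape[1]}-d"
        )
    return X @ model.w + model.b


def predict(model: LinearModel, X: np.ndarray) -> np.ndarray:
    """Class labels: +1 where w . x + b >= 0 (ties go to the positive class)."""
    return np.where(decision_function(model, X) >= 0.0, 1, -1)


def svm_objective(model: LinearModel, X: np.ndarray, y: np.ndarray) -> float:
    """Primal objective 0.5 ||w||^2 + C sum hinge at the model's parameters."""
    X, y = _check_xy(X, y)
    margins = 1.0 - y * (X @ model.w + model.b)
    return float(0.5 * model.w @ model.w + model.C * np.clip(margins, 0.0, None).sum())


def confusion(y_pred: np.ndarray, y_true: np.ndarray) -> ConfusionMatrix:
    """Count the four confusion-matrix cells; positive class is +1 (CL)."""
    y_pred = np.asarray(y_pred).ravel()
    y_true = np.asarray(y_true).ravel()
    if y_pred.shape != y_true.shape:
        raise ValueError("prediction/label length mismatch")
    for arr, name in ((y_pred, "predicted"), (y_true, "actual")):
        if not np.all(np.isin(arr, (-1, 1))):
            raise ValueError(f"{name} labels must be +1/-1")
    pos = y_true == 1
    pred_pos = y_pred == 1
    return ConfusionMatrix(
        tp=int(np.sum(pos & pred_pos)),
        fn=int(np.sum(pos & ~pred_pos)),
        fp=int(np.sum(~pos & pred_pos)),
        tn=int(np.sum(~pos & ~pred_pos)),
    )


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """Sensitivity, specificity, accuracy, MCC and bACC from the counts.

    A zero factor in the MCC denominator yields MCC = 0; sensitivity or
    specificity with an empty denominator is reported as 0.
    """
    if cm.n < 1:
        raise ValueError("empty confusion matrix")
    tp, fn, fp, tn = cm.tp, cm.fn, cm.fp, cm.tn
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / cm.n
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(den) if den else 0.0
    return MetricSet(
        sensitivity=float(sens),
        specificity=float(spec),
        accuracy=float(acc),
        mcc=float(mcc),
        bacc=float(0.5 * (sens + spec)),
    )


def _repeat_seeds(seed: int, repeats: int) -> np.ndarray:
    # independent, reproducible per-repeat shuffles below 2**31
    return np.random.SeedSequence(seed).generate_state(repeats) % np.uint32(2**31)


def fold_assignments(
    y: np.ndarray,
    cfg: CVConfig,
    groups: np.ndarray | None = None,
) -> np.ndarray:
    """(repeats, n) fold index per sample; pure function of (seed, repeat).

    Stratified by class by default; with ``cfg.grouped`` all rows of a
    subject stay in the same fold (avoids two CIT rows of one subject
    straddling train and test).
    """
    y = np.asarray(y)
    n = y.shape[0]
    if cfg.grouped and groups is None:
        raise ValueError("grouped folding requires a groups array")
    out = np.empty((cfg.repeats, n), dtype=np.int64)
    for r, s in enumerate(_repeat_seeds(cfg.seed, cfg.repeats)):
        if cfg.grouped:
            splitter = StratifiedGroupKFold(cfg.folds, shuffle=True, random_state=int(s))
            split = splitter.split(np.zeros((n, 1)), y, groups)
        elif cfg.stratified:
            splitter = StratifiedKFold(cfg.folds, shuffle=True, random_state=int(s))
            split = splitter.split(np.zeros((n, 1)), y)
        else:
            splitter = KFold(cfg.folds, shuffle=True, random_state=int(s))
            split = splitter.split(np.zeros((n, 1)))
        for f, (_, test_idx) in enumerate(split):
            out[r, test_idx] = f
    return out


def repeated_kfold(
    X: np.ndarray,
    y: np.ndarray,
    cfg: CVConfig,
    C: float = 1.0,
    groups: np.ndarray | None = None,
) -> CVResult:
    """folds x repeats fold-level metric sets for the linear SVM on (X, y)."""
    X, y = _check_xy(X, y)
    if np.unique(y).size < 2:
        raise ValueError("cross-validation requires both classes")
    per_class = np.bincount((y > 0).astype(int))
    if per_class.min() < cfg.folds and cfg.stratified:
        raise ValueError("not enough samples per class for stratified folds")
    fold_ids = fold_assignments(y, cfg, groups)
    if not cfg.stratified:
        for r in range(cfg.repeats):
            for f in range(cfg.folds):
                if np.unique(y[fold_ids[r] == f]).size < 2:
                    warnings.warn(
                        f"repeat {r} fold {f} lacks a class; its MCC is 0",
                        stacklevel=2,
                    )
    K = X @ X.T
    counts = _cv_counts(K, y, fold_ids, cfg.folds, float(C), 1e-4, 100_000)
    fold_metrics = [metrics(ConfusionMatrix(*map(int, row))) for row in counts]
    return CVResult(fold_metrics=fold_metrics, fold_counts=counts)


def compare_metric_distributions(a, b) -> tuple[float, float]:
    """Welch two-sample t-test on fold-level metric values.

    Positive statistic means ``a`` scored higher.  Used to compare the
    hemispheric groupings' fold-level MCC distributions.
    """
    from scipy import stats

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two values per sample")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        raise ValueError("both samples have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)
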