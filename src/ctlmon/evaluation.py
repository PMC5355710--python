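"""Multiclass evaluation of load classifiers.

The confusion matrix convention follows the study layout: **rows are
predicted classes, columns are target classes**.  Per-class accuracy is
column recall (diagonal over column sum).  The five ordered load classes
also induce four binary problems ("cases"): in case m, classes 1..m are
the negative (lower-load) class and classes m+1..5 the positive
(higher-load) class, with

    FPR = FP / (FP + TN)        FNR = FN / (FN + TP)

where a false positive is a truly-negative epoch predicted positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ClassifierEvaluation:
    """Confusion matrix (predicted rows x target columns) and derived rates."""

    matrix: np.ndarray
    n_classes: int = 5

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.shape != (self.n_classes, self.n_classes):
            raise ValueError(f"matrix must be {self.n_classes} x {self.n_classes}")
        if (self.matrix < 0).any():
            raise ValueError("confusion-matrix entries must be nonnegative")

    @classmethod
    def from_labels(
        cls, predicted: np.ndarray, target: np.ndarray, n_classes: int = 5
    ) -> "ClassifierEvaluation":
        predicted = np.asarray(predicted, int)
        target = np.asarray(target, int)
        if predicted.shape != target.shape:
            raise ValueError("predicted and target labels must have equal length")
        m = np.zeros((n_classes, n_classes), dtype=int)
        np.add.at(m, (predicted - 1, target - 1), 1)
        return cls(m, n_classes)

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.matrix) / self.total)

    @property
    def per_class_accuracy(self) -> np.ndarray:
        """Column recall; NaN for empty target classes (printed as '-')."""
        col = self.matrix.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(col > 0, np.diag(self.matrix) / col, np.nan)

    def case_rates(self, case: int) -> tuple[float, float]:
        """(FPR, FNR) of the binary problem with classes 1..case negative."""
        if not 1 <= case <= self.n_classes - 1:
            raise ValueError(f"case must lie in 1..{self.n_classes - 1}")
        neg = slice(0, case)
        pos = slice(case, self.n_classes)
        tn = self.matrix[neg, neg].sum()
        fp = self.matrix[pos, neg].sum()  # target negative, predicted positive
        fn = self.matrix[neg, pos].sum()
        tp = self.matrix[pos, pos].sum()
        fpr = fp / (fp + tn) if fp + tn > 0 else float("nan")
        fnr = fn / (fn + tp) if fn + tp > 0 else float("nan")
        return float(fpr), float(fnr)

    @property
    def fpr(self) -> np.ndarray:
        return np.array([self.case_rates(m)[0] for m in range(1, self.n_classes)])

    @property
    def fnr(self) -> np.ndarray:
        return np.array([self.case_rates(m)[1] for m in range(1, self.n_classes)])

    def to_frame(self) -> pd.DataFrame:
        idx = [f"pred_{i}" for i in range(1, self.n_classes + 1)]
        cols = [f"target_{i}" for i in range(1, self.n_classes + 1)]
        return pd.DataFrame(self.matrix, index=idx, columns=cols)

    def to_dict(self) -> dict:
        return {
            "confusion_matrix": self.matrix.tolist(),
            "axis": "rows=predicted, columns=target",
            "accuracy": self.accuracy,
            "per_class_accuracy": [
                None if np.isnan(v) else float(v) for v in self.per_class_accuracy
            ],
            "case_fpr": list(map(float, self.fpr)),
            "case_fnr": list(map(float, self.fnr)),
        }


def evaluate(predicted, target, n_classes: int = 5) -> ClassifierEvaluation:
    """Confusion-matrix evaluation of predicted vs target class labels."""
    return ClassifierEvaluation.from_labels(predicted, target, n_classes)


def cohens_d_paired(a: np.ndarray, b: np.ndarray) -> float:
    """Paired Cohen's d: mean(a - b) / s.d.(a - b) (sample s.d., ddof = 1)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired samples of equal length >= 2 required")
    diff = a - b
    sd = float(np.std(diff, ddof=1))
    if sd == 0:
        return float("nan") if diff.mean() != 0 else 0.0
    return float(diff.mean() / sd)


def baseline_accuracy(
    name: str,
    X_train: np.ndarray,
    C_train: np.ndarray,
    X_test: np.ndarray,
    C_test: np.ndarray,
    n_neighbors: int = 30,
) -> float:
    """Static reference classifiers for comparison: naive Bayes or KNN (K = 30)."""
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier

    if name == "nb":
        clf = GaussianNB()
    elif name == "knn":
        clf = KNeighborsClassifier(n_neighbors=n_neighbors)
    else:
        raise ValueError(f"unknown baseline {name!r}")
    clf.fit(np.asarray(X_train, float), np.asarray(C_train, int))
    pred = clf.predict(np.asarray(X_test, float))
    return float(np.mean(pred == np.asarray(C_test, int)))
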