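"""The final logistic signature model and its cutoff diagnostics.

An L2-regularized logistic regression on the standardized log10(TPM+1)
expression of the optimal gene panel.  The score is the predicted
probability of the resistant class; a sample is called resistant when its
score exceeds the operating cutoff (default 0.5).  The model serializes
to a plain-text descriptor (per-gene center, scale and coefficient plus
intercept and cutoff) so any implementation can rescore.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .ranking import HoldoutMetrics, evaluate_holdout, _as_binary

__all__ = [
    "SignatureClassifier",
    "fit_signature",
    "predict_score",
    "cutoff_sweep",
    "evaluate_signature",
]


class SignatureClassifier(ClassifierMixin, BaseEstimator):
    """Standardized L2 logistic signature with a tunable operating cutoff.

    Parameters
    ----------
    C : float
        Inverse L2 regularization strength (sklearn convention).
    max_iter : int
        Iteration cap for the lbfgs solver.
    cutoff : float
        Operating probability cutoff: resistant iff score > cutoff.
    random_state : int
        Recorded for provenance; the lbfgs fit itself is deterministic.

    Attributes after ``fit``: ``genes_``, ``coef_`` (standardized scale),
    ``intercept_``, ``center_``, ``scale_``, ``classes_``, ``converged_``.
    """

    def __init__(
        self,
        C: float = 1.0,
        max_iter: int = 1000,
        cutoff: float = 0.5,
        random_state: int = 0,
    ):
        self.C = C
        self.max_iter = max_iter
        self.cutoff = cutoff
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y: pd.Series):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X))
        yb = _as_binary(pd.Series(y).to_numpy())
        if len(np.unique(yb)) < 2:
            raise ValueError("both classes must be present")
        arr = X.to_numpy(dtype=float)
        scaler = StandardScaler().fit(arr)
        model = LogisticRegression(
            C=self.C, solver="lbfgs", max_iter=self.max_iter
        )
        model.fit(scaler.transform(arr), yb)
        self.genes_ = list(X.columns)
        self.center_ = pd.Series(scaler.mean_, index=self.genes_)
        self.scale_ = pd.Series(scaler.scale_, index=self.genes_)
        self.coef_ = pd.Series(model.coef_[0], index=self.genes_)
        self.intercept_ = float(model.intercept_[0])
        self.classes_ = np.array(["sensitive", "resistant"])
        self.converged_ = bool((model.n_iter_ < self.max_iter).all())
        return self

    def _standardize(self, X: pd.DataFrame) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [g for g in self.genes_ if g not in X.columns]
            if missing:
                raise KeyError(f"missing panel gene(s): {missing}")
            arr = X.loc[:, self.genes_].to_numpy(dtype=float)
        else:
            arr = np.asarray(X, dtype=float)
            if arr.shape[1] != len(self.genes_):
                raise ValueError("feature count does not match the panel")
        return (arr - self.center_.to_numpy()) / self.scale_.to_numpy()

    def decision_function(self, X) -> np.ndarray:
        return self._standardize(X) @ self.coef_.to_numpy() + self.intercept_

    def predict_proba(self, X) -> np.ndarray:
        score = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1.0 - score, score])

    def score_resistant(self, X) -> np.ndarray:
        """Signature score: probability of the resistant class, in [0, 1]."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        return np.where(
            self.score_resistant(X) > self.cutoff, "resistant", "sensitive"
        )

    def to_text(self, path: str | Path | None = None) -> str:
        """Plain-text descriptor: gene, center, scale, coefficient rows."""
        lines = [
            "# signature model descriptor",
            f"intercept\t{float(self.intercept_)!r}",
            f"cutoff\t{float(self.cutoff)!r}",
            "gene\tcenter\tscale\tcoefficient",
        ]
        for g in self.genes_:
            lines.append(
                f"{g}\t{float(self.center_[g])!r}\t{float(self.scale_[g])!r}"
                f"\t{float(self.coef_[g])!r}"
            )
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_text(cls, source: str | Path) -> "SignatureClassifier":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        intercept = cutoff = None
        genes, centers, scales, coefs = [], [], [], []
        for line in text.splitlines():
            if not line or line.startswith("#") or line.startswith("gene\t"):
                continue
            parts = line.split("\t")
            if parts[0] == "intercept":
                intercept = float(parts[1])
            elif parts[0] == "cutoff":
                cutoff = float(parts[1])
            else:
                genes.append(parts[0])
                centers.append(float(parts[1]))
                scales.append(float(parts[2]))
                coefs.append(float(parts[3]))
        if intercept is None or cutoff is None or not genes:
            raise ValueError("malformed model descriptor")
        obj = cls(cutoff=cutoff)
        obj.genes_ = genes
        obj.center_ = pd.Series(centers, index=genes)
        obj.scale_ = pd.Series(scales, index=genes)
        obj.coef_ = pd.Series(coefs, index=genes)
        obj.intercept_ = intercept
        obj.classes_ = np.array(["sensitive", "resistant"])
        obj.converged_ = True
        return obj


def fit_signature(
    features: pd.DataFrame,
    labels: pd.Series,
    C: float = 1.0,
    iteration_cap: int = 1000,
    cutoff: float = 0.5,
    seed: int = 0,
) -> SignatureClassifier:
    """Fit the signature model on panel-restricted features."""
    model = SignatureClassifier(C=C, max_iter=iteration_cap, cutoff=cutoff, random_state=seed)
    return model.fit(features, labels.loc[features.index])


def predict_score(model: SignatureClassifier, features: pd.DataFrame) -> np.ndarray:
    """Signature scores in [0, 1]; raises naming any missing panel gene."""
    return model.score_resistant(features)


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den > 0 else np.nan


def cutoff_sweep(
    scores: np.ndarray,
    true_labels: pd.Series | np.ndarray,
    cutoffs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Confusion-matrix metrics at each cutoff, resistant = positive.

    Undefined ratios (0/0, e.g. precision when nothing is called
    resistant) are reported as NaN, never silently as 0.  Default cutoffs
    are 0.1 .. 0.9 in steps of 0.1.
    """
    if cutoffs is None:
        cutoffs = np.round(np.arange(0.1, 0.95, 0.1), 10)
    y = _as_binary(true_labels)
    scores = np.asarray(scores, dtype=float)
    rows = []
    for c in cutoffs:
        pred = (scores > c).astype(int)
        tp = int(((pred == 1) & (y == 1)).sum())
        tn = int(((pred == 0) & (y == 0)).sum())
        fp = int(((pred == 1) & (y == 0)).sum())
        fn = int(((pred == 0) & (y == 1)).sum())
        recall = _safe_ratio(tp, tp + fn)
        precision = _safe_ratio(tp, tp + fp)
        f1 = (
            2 * precision * recall / (precision + recall)
            if (precision + recall) and not np.isnan(precision) and not np.isnan(recall)
            else np.nan
        )
        rows.append(
            {
                "cutoff": float(c),
                "accuracy": (tp + tn) / len(y),
                "recall": recall,
                "precision": precision,
                "npv": _safe_ratio(tn, tn + fn),
                "specificity": _safe_ratio(tn, tn + fp),
                "f1": f1,
                "tn": tn,
                "fp": fp,
                "fn": fn,
                "tp": tp,
            }
        )
    return pd.DataFrame(rows)


def evaluate_signature(
    model: SignatureClassifier,
    test_features: pd.DataFrame,
    test_labels: pd.Series,
) -> HoldoutMetrics:
    """Holdout metrics of the signature score at the model's cutoff."""
    scores = predict_score(model, test_features)
    return evaluate_holdout(scores, test_labels.loc[test_features.index], cutoff=model.cutoff)
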