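"""Attribution-based gene ranking with a gradient-boosted classifier.

A LightGBM binary classifier (resistant = positive class) is trained on
log10(TPM+1) features and explained with exact per-sample TreeSHAP
attributions (LightGBM's ``pred_contrib`` output, which satisfies the
additivity identity: attributions plus the expected-value offset equal the
raw margin).  Attribution magnitudes are aggregated as the mean absolute
value per gene over the held-out folds of repeated stratified
cross-validation, so no sample is explained by a model that saw it.
"""

from __future__ import annotations

from dataclasses import dataclass

import lightgbm as lgb
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.metrics import precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "SplitSpec",
    "ShapSummary",
    "HoldoutMetrics",
    "ShapRanker",
    "stratified_split",
    "train_gbdt",
    "shap_repeated_cv",
    "contributing_genes",
    "evaluate_holdout",
    "roc_auc",
    "pr_auc",
]

POSITIVE_CLASS = "resistant"

DEFAULT_GBDT_PARAMS: dict = {
    "max_depth": 8,
    "learning_rate": 0.1,
    "n_estimators": 300,
    "reg_alpha": 0.1,
    "reg_lambda": 0.1,
    "min_child_samples": 10,
    "num_leaves": 31,
    # feature subsampling per tree: with far more genes than samples this
    # both regularizes and spreads splits (hence attributions) across
    # redundant informative genes instead of a dominant few
    "colsample_bytree": 0.2,
}


@dataclass
class SplitSpec:
    train_ids: list[str]
    test_ids: list[str]
    fraction_test: float
    seed: int


@dataclass
class ShapSummary:
    """Per-gene mean |attribution| with per-repeat detail and dense ranks."""

    mean_abs_shap: pd.Series  # gene -> mean |SHAP| over repeats x folds x samples
    per_repeat: pd.DataFrame  # repeats x genes
    ranks: pd.Series  # 1 = largest mean_abs_shap

    def table(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"mean_abs_shap": self.mean_abs_shap, "rank": self.ranks}
        )
        rep = self.per_repeat.T
        rep.columns = [f"repeat_{i}" for i in range(rep.shape[1])]
        return out.join(rep)


@dataclass
class HoldoutMetrics:
    accuracy: float
    roc_auc: float | None
    pr_auc: float | None
    confusion: np.ndarray  # rows true (neg, pos), cols predicted (neg, pos)


def _as_binary(y) -> np.ndarray:
    """Map labels to {0, 1} with resistant (or 1/True) as the positive class."""
    arr = np.asarray(y)
    if arr.dtype.kind in "OU":
        uniq = set(arr.tolist())
        if not uniq <= {"sensitive", "resistant"}:
            raise ValueError(f"unrecognized labels: {uniq}")
        return (arr == POSITIVE_CLASS).astype(int)
    return arr.astype(int)


def stratified_split(
    labels: pd.Series, fraction_test: float, seed: int = 42
) -> SplitSpec:
    """Deterministic per-class split: round(class_size * fraction_test) test.

    Shuffles within each class with the given seed, so identical seeds
    give identical splits; class proportions in the test set match the
    cohort to within rounding.
    """
    if not 0 < fraction_test < 1:
        raise ValueError("fraction_test must be in (0, 1)")
    rng = np.random.default_rng(seed)
    test_ids: list[str] = []
    train_ids: list[str] = []
    for cls in sorted(labels.unique()):
        ids = sorted(labels.index[labels == cls])
        if len(ids) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")
        n_test = int(round(len(ids) * fraction_test))
        perm = rng.permutation(len(ids))
        test_ids += [ids[i] for i in perm[:n_test]]
        train_ids += [ids[i] for i in perm[n_test:]]
    return SplitSpec(
        train_ids=sorted(train_ids),
        test_ids=sorted(test_ids),
        fraction_test=fraction_test,
        seed=seed,
    )


def _fit_one(
    X: np.ndarray,
    y: np.ndarray,
    params: dict,
    seed: int,
    early_stopping_rounds: int = 50,
    validation_fraction: float = 0.2,
) -> lgb.LGBMClassifier:
    """Fit one LightGBM model with an internal early-stopping slice.

    A stratified ``validation_fraction`` of the training data is held out
    for AUC-based early stopping with the given patience; training is
    single-threaded and deterministic under the seed.
    """
    clf = lgb.LGBMClassifier(
        **params,
        random_state=seed,
        deterministic=True,
        n_jobs=1,
        verbose=-1,
    )
    rng = np.random.default_rng(seed)
    val_idx: list[int] = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        n_val = max(1, int(round(len(idx) * validation_fraction)))
        val_idx += list(rng.permutation(idx)[:n_val])
    val_mask = np.zeros(len(y), dtype=bool)
    val_mask[val_idx] = True
    if len(np.unique(y[~val_mask])) < 2 or len(np.unique(y[val_mask])) < 2:
        raise ValueError("training labels must contain both classes")
    clf.fit(
        X[~val_mask],
        y[~val_mask],
        eval_set=[(X[val_mask], y[val_mask])],
        eval_metric="auc",
        callbacks=[lgb.early_stopping(early_stopping_rounds, verbose=False)],
    )
    return clf


def train_gbdt(
    features: pd.DataFrame,
    labels: pd.Series,
    hyperparams: dict | None = None,
    seed: int = 42,
) -> lgb.LGBMClassifier:
    """Train the attribution base model on (samples x genes) features."""
    y = _as_binary(labels.loc[features.index])
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    params = {**DEFAULT_GBDT_PARAMS, **(hyperparams or {})}
    return _fit_one(features.to_numpy(dtype=float), y, params, seed)


def shap_contributions(clf: lgb.LGBMClassifier, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact TreeSHAP attributions and the expected-value offset per sample."""
    contrib = clf.booster_.predict(X, pred_contrib=True)
    return contrib[:, :-1], contrib[:, -1]


def shap_repeated_cv(
    features: pd.DataFrame,
    labels: pd.Series,
    n_repeats: int = 12,
    n_folds: int = 5,
    base_seed: int = 42,
    hyperparams: dict | None = None,
    max_redraws: int = 20,
) -> ShapSummary:
    """Mean |SHAP| per gene over repeated stratified cross-validation.

    For repeat ``r`` (seed ``base_seed + r``) the samples are partitioned
    into ``n_folds`` stratified folds; each fold's attributions come from
    a model trained on the remaining folds.  The repeat summary is the
    mean |attribution| per gene over all held-out samples, and the final
    score is the mean over repeats.  Samples are canonicalized to id order
    first, so the output does not depend on input column order.
    """
    features = features.sort_index()
    y = _as_binary(labels.loc[features.index])
    if np.bincount(y, minlength=2).min() < n_folds:
        raise ValueError("each class needs at least n_folds members")
    X = features.to_numpy(dtype=float)
    params = {**DEFAULT_GBDT_PARAMS, **(hyperparams or {})}
    n, p = X.shape

    per_repeat = np.zeros((n_repeats, p))
    for r in range(n_repeats):
        seed = base_seed + r
        folds = None
        for attempt in range(max_redraws):
            skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + 1000 * attempt)
            candidate = list(skf.split(X, y))
            if all(len(np.unique(y[tr])) == 2 for tr, _ in candidate):
                folds = candidate
                break
        if folds is None:
            raise ValueError("could not draw folds with both classes present")
        abs_shap = np.zeros((n, p))
        for tr, te in folds:
            clf = _fit_one(X[tr], y[tr], params, seed)
            contrib, _ = shap_contributions(clf, X[te])
            abs_shap[te] = np.abs(contrib)
        per_repeat[r] = abs_shap.mean(axis=0)

    mean_abs = per_repeat.mean(axis=0)
    genes = features.columns
    mean_series = pd.Series(mean_abs, index=genes, name="mean_abs_shap")
    order = np.lexsort((genes, -mean_abs))
    ranks = np.empty(p, dtype=int)
    ranks[order] = np.arange(1, p + 1)
    return ShapSummary(
        mean_abs_shap=mean_series,
        per_repeat=pd.DataFrame(per_repeat, columns=genes),
        ranks=pd.Series(ranks, index=genes, name="rank"),
    )


def contributing_genes(summary: ShapSummary, epsilon: float = 0.0) -> set[str]:
    """Genes whose mean |attribution| strictly exceeds ``epsilon``."""
    s = summary.mean_abs_shap
    return set(s.index[s > epsilon])


def roc_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """ROC AUC by trapezoidal integration over all score thresholds."""
    fpr, tpr, _ = roc_curve(y, scores)
    return float(np.trapezoid(tpr, fpr))


def pr_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Precision-recall AUC by trapezoidal integration over recall."""
    precision, recall, _ = precision_recall_curve(y, scores)
    # precision_recall_curve returns recall in decreasing order
    return float(np.trapezoid(precision[::-1], recall[::-1]))


def evaluate_holdout(
    scores: np.ndarray,
    test_labels: pd.Series | np.ndarray,
    cutoff: float = 0.5,
) -> HoldoutMetrics:
    """Holdout metrics from probability scores for the resistant class.

    The confusion matrix is taken at the probability cutoff; AUCs are
    reported as None (undefined) when only one class is present.
    """
    y = _as_binary(test_labels)
    scores = np.asarray(scores, dtype=float)
    if len(y) == 0:
        raise ValueError("empty test set")
    pred = (scores > cutoff).astype(int)
    confusion = np.array(
        [
            [(pred[y == 0] == 0).sum(), (pred[y == 0] == 1).sum()],
            [(pred[y == 1] == 0).sum(), (pred[y == 1] == 1).sum()],
        ]
    )
    accuracy = float((pred == y).mean())
    if len(np.unique(y)) < 2:
        return HoldoutMetrics(accuracy, None, None, confusion)
    return HoldoutMetrics(accuracy, roc_auc(scores, y), pr_auc(scores, y), confusion)


class ShapRanker(BaseEstimator):
    """Estimator facade for the repeated-CV attribution ranking.

    ``fit(X, y)`` expects a (samples x genes) frame and labels in
    {sensitive, resistant}; it exposes ``mean_abs_shap_``, ``per_repeat_``,
    ``ranks_`` and a ``classifier_`` trained on all of ``X`` for holdout
    scoring.
    """

    def __init__(
        self,
        n_repeats: int = 12,
        n_folds: int = 5,
        base_seed: int = 42,
        hyperparams: dict | None = None,
    ):
        self.n_repeats = n_repeats
        self.n_folds = n_folds
        self.base_seed = base_seed
        self.hyperparams = hyperparams

    def fit(self, X: pd.DataFrame, y: pd.Series):
        summary = shap_repeated_cv(
            X,
            y,
            n_repeats=self.n_repeats,
            n_folds=self.n_folds,
            base_seed=self.base_seed,
            hyperparams=self.hyperparams,
        )
        self.summary_ = summary
        self.mean_abs_shap_ = summary.mean_abs_shap
        self.per_repeat_ = summary.per_repeat
        self.ranks_ = summary.ranks
        self.classifier_ = train_gbdt(X, y, self.hyperparams, seed=self.base_seed)
        return self

    def score_resistant(self, X: pd.DataFrame) -> np.ndarray:
        """Probability of the resistant class from the full-data model."""
        return np.asarray(self.classifier_.booster_.predict(X.to_numpy(dtype=float)))

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        p = self.score_resistant(X)
        return np.column_stack([1.0 - p, p])
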