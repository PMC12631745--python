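"""Candidate panel construction and specificity-driven recursive elimination.

The DEG and attribution rankings are intersected with sign partitioning
(up- and down-regulated genes kept separate), then recursively pruned: at
each step the current panel's mean specificity is measured by stratified
5-fold cross-validation of a standardized L2 logistic model (specificity =
true-sensitive lines predicted sensitive; resistant is the positive
class), the model is refitted on all data, and the gene with the smallest
absolute standardized coefficient is dropped.  The optimal panel is the
size with maximal mean specificity; ties are resolved toward the larger
panel, retaining biomarkers when specificity cannot distinguish sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .ranking import _as_binary

__all__ = [
    "CandidatePanel",
    "EliminationTrace",
    "SpecificityRFE",
    "sign_intersection",
    "standardized_logit_coefficients",
    "recursive_specificity_elimination",
    "optimal_panel",
    "panel_correlation",
]


@dataclass
class CandidatePanel:
    up_genes: set[str]
    down_genes: set[str]

    def __post_init__(self) -> None:
        if self.up_genes & self.down_genes:
            raise ValueError("up and down gene sets must be disjoint")

    @property
    def genes(self) -> list[str]:
        return sorted(self.up_genes | self.down_genes)

    def __len__(self) -> int:
        return len(self.up_genes) + len(self.down_genes)


@dataclass
class EliminationTrace:
    """Per-size records of the elimination path.

    ``records`` has one row per panel size (descending by 1 down to 1)
    with columns panel_size, mean_specificity, sd_specificity and
    eliminated_gene (None on the final row); ``panels`` maps each recorded
    size to the gene tuple evaluated at that size.
    """

    records: pd.DataFrame
    panels: dict[int, tuple[str, ...]] = field(repr=False)

    @property
    def elimination_order(self) -> list[str]:
        return [g for g in self.records["eliminated_gene"] if g is not None]


def sign_intersection(
    deg_up: set[str], deg_down: set[str], shap_genes: set[str]
) -> CandidatePanel:
    """Intersect each DEG direction with the attribution gene set."""
    if deg_up & deg_down:
        raise ValueError("deg_up and deg_down must be disjoint")
    return CandidatePanel(up_genes=deg_up & shap_genes, down_genes=deg_down & shap_genes)


def standardized_logit_coefficients(
    features: pd.DataFrame, labels: pd.Series, C: float = 1.0, max_iter: int = 1000
) -> pd.Series:
    """L2 logistic coefficients on unit-variance standardized features.

    Zero-variance features get coefficient 0 by convention (with a
    warning) — they carry no class information and must not perturb
    elimination order.
    """
    y = _as_binary(labels.loc[features.index])
    if np.bincount(y, minlength=2).min() < 2:
        raise ValueError("need >= 2 samples per class")
    X = features.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    zero_var = X.std(axis=0) == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance feature(s); coefficients set to 0",
            stacklevel=2,
        )
    scaler = StandardScaler().fit(X)
    model = LogisticRegression(C=C, solver="lbfgs", max_iter=max_iter)
    model.fit(scaler.transform(X), y)
    coefs = model.coef_[0].copy()
    coefs[zero_var] = 0.0
    return pd.Series(coefs, index=features.columns, name="coefficient")


def _cv_specificity(
    X: np.ndarray,
    y: np.ndarray,
    folds: list[tuple[np.ndarray, np.ndarray]],
    C: float,
    max_iter: int,
) -> tuple[float, float]:
    """Mean/sd of per-fold specificity; scaler refitted inside each fold."""
    specs = []
    for tr, te in folds:
        scaler = StandardScaler().fit(X[tr])
        model = LogisticRegression(C=C, solver="lbfgs", max_iter=max_iter)
        model.fit(scaler.transform(X[tr]), y[tr])
        pred = model.predict_proba(scaler.transform(X[te]))[:, 1] > 0.5
        sens = y[te] == 0
        specs.append(float((~pred[sens]).mean()) if sens.any() else np.nan)
    specs_arr = np.asarray(specs, dtype=float)
    return float(np.nanmean(specs_arr)), float(np.nanstd(specs_arr, ddof=0))


def _draw_folds(
    y: np.ndarray, n_folds: int, seed: int, max_redraws: int = 20
) -> list[tuple[np.ndarray, np.ndarray]]:
    for attempt in range(max_redraws):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + 1000 * attempt)
        folds = list(skf.split(np.zeros_like(y), y))
        if all(len(np.unique(y[tr])) == 2 and (y[te] == 0).any() for tr, te in folds):
            return folds
    raise ValueError("could not draw folds with both classes in every split")


def recursive_specificity_elimination(
    features: pd.DataFrame,
    labels: pd.Series,
    n_folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
    max_iter: int = 1000,
) -> EliminationTrace:
    """Drop the smallest-|coefficient| gene per step, scoring by specificity.

    The fold partition is drawn once and reused across panel sizes so the
    specificity curve is comparable along the path.  Coefficient ties are
    broken toward the lexicographically smallest gene id.  The trace has
    one record per panel size from the full panel down to 1.
    """
    if features.shape[1] == 0:
        raise ValueError("panel is empty")
    features = features.sort_index()
    y = _as_binary(labels.loc[features.index])
    folds = _draw_folds(y, n_folds, seed)
    current = sorted(features.columns)
    rows = []
    panels: dict[int, tuple[str, ...]] = {}
    while current:
        X = features.loc[:, current].to_numpy(dtype=float)
        mean_spec, sd_spec = _cv_specificity(X, y, folds, C, max_iter)
        panels[len(current)] = tuple(current)
        if len(current) > 1:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                coefs = standardized_logit_coefficients(
                    features.loc[:, current], labels, C=C, max_iter=max_iter
                )
            # ties toward the lexicographically smallest gene id
            victim = min(current, key=lambda g: (abs(coefs[g]), g))
        else:
            victim = None
        rows.append((len(current), mean_spec, sd_spec, victim))
        if victim is None:
            break
        current.remove(victim)
    records = pd.DataFrame(
        rows, columns=["panel_size", "mean_specificity", "sd_specificity", "eliminated_gene"]
    )
    return EliminationTrace(records=records, panels=panels)


def optimal_panel(trace: EliminationTrace) -> set[str]:
    """The gene set at the panel size with maximal mean specificity.

    Ties across sizes are broken toward the larger panel: when
    cross-validated specificity cannot distinguish sizes, the biomarkers
    are retained rather than discarded.
    """
    rec = trace.records
    if rec.empty:
        raise ValueError("empty elimination trace")
    best = rec["mean_specificity"].max()
    sizes = rec.loc[rec["mean_specificity"] == best, "panel_size"]
    return set(trace.panels[int(sizes.max())])


def panel_correlation(features: pd.DataFrame) -> pd.DataFrame:
    """Pearson gene-gene correlations; zero-variance genes report NaN."""
    if features.shape[1] < 2:
        raise ValueError("need >= 2 genes")
    return features.corr(method="pearson")


class SpecificityRFE(BaseEstimator):
    """Estimator facade: fit(X, y) runs the elimination and stores the path.

    Attributes after ``fit``: ``trace_`` (:class:`EliminationTrace`),
    ``elimination_order_``, ``optimal_genes_`` (set) and ``support_``
    (boolean mask over the input columns).
    """

    def __init__(self, n_folds: int = 5, seed: int = 0, C: float = 1.0, max_iter: int = 1000):
        self.n_folds = n_folds
        self.seed = seed
        self.C = C
        self.max_iter = max_iter

    def fit(self, X: pd.DataFrame, y: pd.Series):
        self.trace_ = recursive_specificity_elimination(
            X, y, n_folds=self.n_folds, seed=self.seed, C=self.C, max_iter=self.max_iter
        )
        self.elimination_order_ = self.trace_.elimination_order
        self.optimal_genes_ = optimal_panel(self.trace_)
        self.support_ = np.asarray([g in self.optimal_genes_ for g in X.columns])
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.loc[:, sorted(self.optimal_genes_)]
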