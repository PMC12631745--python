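"""External-validity statistics for a fitted signature.

Survival stratification (Kaplan-Meier, log-rank, Cox proportional
hazards, landmark ROC at fixed horizons), fold-change concordance between
expression platforms, and the cross-drug IC50 fold-change panel (Welch
tests with geometric-mean fold changes and log-scale confidence
intervals).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .de import bh_adjust
from .ranking import roc_auc

__all__ = [
    "KMEstimate",
    "CoxResult",
    "DrugComparison",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "landmark_roc",
    "welch_t_test",
    "drug_panel_compare",
    "foldchange_concordance",
]


@dataclass
class KMEstimate:
    """Product-limit survival curve plus the median survival time."""

    survival: pd.Series  # time -> S(t), step function values at event times
    median: float  # NaN when the curve never reaches 0.5

    def at(self, t: float) -> float:
        s = self.survival[self.survival.index <= t]
        return float(s.iloc[-1]) if len(s) else 1.0


@dataclass
class DrugComparison:
    drug: str
    n_sensitive: int
    n_resistant: int
    fold_change: float  # geometric-mean IC50 resistant / sensitive
    ci_low: float
    ci_high: float
    p: float
    padj: float | None = None


def km_estimate(times: np.ndarray, events: np.ndarray) -> KMEstimate:
    """Kaplan-Meier product-limit estimate and median survival.

    With no censoring the curve equals the empirical survivor function;
    the median is the earliest time at which survival drops to <= 0.5 and
    is NaN when never reached (e.g. everything censored).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(times) == 0:
        raise ValueError("empty survival table")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    surv = kmf.survival_function_["KM_estimate"]
    median = float(kmf.median_survival_time_)
    if np.isinf(median):
        median = float("nan")
    return KMEstimate(survival=surv, median=median)


def logrank_test(
    table_a: pd.DataFrame, table_b: pd.DataFrame
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p).

    Expects frames with ``time`` and ``event`` columns.  Symmetric in
    group order.  Undefined (NaN, NaN) when there are no events at all.
    """
    if len(table_a) == 0 or len(table_b) == 0:
        raise ValueError("both groups must be non-empty")
    if not (table_a["event"].any() or table_b["event"].any()):
        return float("nan"), float("nan")
    res = _ll_logrank(
        table_a["time"], table_b["time"],
        event_observed_A=table_a["event"].astype(bool),
        event_observed_B=table_b["event"].astype(bool),
    )
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    table: pd.DataFrame,
    covariates: list[str],
    iteration_cap: int = 100,
) -> pd.DataFrame:
    """Cox proportional hazards regression with estimability screening.

    Covariates with fewer than two observed levels cannot contribute to
    the partial likelihood; they are flagged ``estimable = False`` and
    excluded from the fit rather than silently dropped or fabricated.
    Returns a frame indexed by covariate with hazard_ratio, ci_low,
    ci_high, p and estimable columns (NaN entries for inestimable rows).

    Expects ``time`` and ``event`` columns plus the covariates; string
    covariates are dummy-coded against their first (sorted) level.
    """
    if not table["event"].astype(bool).any():
        raise ValueError("no events observed; Cox model is undefined")
    estimable = {c: table[c].nunique() >= 2 for c in covariates}
    usable = [c for c in covariates if estimable[c]]
    df = table[["time", "event"]].copy()
    df["event"] = df["event"].astype(int)
    name_map: dict[str, str] = {}
    for c in usable:
        col = table[c]
        if col.dtype.kind in "OUb":
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:
                newc = f"{c}[{lev}]" if len(levels) > 2 else c
                df[newc] = (col.astype(str) == lev).astype(float)
                name_map[newc] = c
        else:
            df[c] = col.astype(float)
            name_map[c] = c
    fitter = CoxPHFitter()
    try:
        fitter.fit(
            df, duration_col="time", event_col="event",
            fit_options={"max_steps": iteration_cap},
        )
    except Exception as exc:  # pragma: no cover - surfaced, not silenced
        raise RuntimeError(f"Cox partial-likelihood fit failed: {exc}") from exc
    summary = fitter.summary
    rows = []
    for c in covariates:
        if not estimable[c]:
            rows.append((c, np.nan, np.nan, np.nan, np.nan, False))
            continue
        for term in [t for t, base in name_map.items() if base == c]:
            s = summary.loc[term]
            rows.append(
                (
                    term,
                    float(np.exp(s["coef"])),
                    float(np.exp(s["coef lower 95%"])),
                    float(np.exp(s["coef upper 95%"])),
                    float(s["p"]),
                    True,
                )
            )
    out = pd.DataFrame(
        rows, columns=["covariate", "hazard_ratio", "ci_low", "ci_high", "p", "estimable"]
    ).set_index("covariate")
    return out


def landmark_roc(
    scores: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    horizon: float,
) -> float:
    """ROC AUC of a score against survival status at a fixed horizon.

    Positives died before the horizon; negatives were followed event-free
    beyond it; patients censored before the horizon are excluded from both
    classes.  NaN when either class is empty.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    pos = (times <= horizon) & events
    neg = times > horizon
    keep = pos | neg
    if not pos.any() or not neg.any():
        return float("nan")
    return roc_auc(scores[keep], pos[keep].astype(int))


def welch_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, df, two-sided p).

    Degenerate zero-variance equal-mean input returns (0, df, 1) rather
    than a division error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each arm needs >= 2 values")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
        return float("inf") if x.mean() > y.mean() else float("-inf"), float(
            len(x) + len(y) - 2
        ), 0.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def drug_panel_compare(
    ic50_panel: pd.DataFrame,
    predicted_labels: pd.Series,
    bh_correct: bool = False,
    min_arm: int = 2,
) -> tuple[list[DrugComparison], dict[str, str]]:
    """Per-drug resistant-vs-sensitive IC50 comparison on the log scale.

    For each drug (column), Welch's t-test and a 95% CI are computed on
    natural-log IC50 and exponentiated, giving a geometric-mean fold
    change (resistant / sensitive) whose CI cannot cover negative
    concentrations.  Drugs with fewer than ``min_arm`` lines per predicted
    arm are skipped with a reason.  Optional BH adjustment across drugs.
    """
    labels = predicted_labels.reindex(ic50_panel.index)
    results: list[DrugComparison] = []
    skipped: dict[str, str] = {}
    for drug in ic50_panel.columns:
        vals = ic50_panel[drug]
        ok = vals.notna() & labels.notna()
        res = np.log(vals[ok & (labels == "resistant")].to_numpy(dtype=float))
        sen = np.log(vals[ok & (labels == "sensitive")].to_numpy(dtype=float))
        if len(res) < min_arm or len(sen) < min_arm:
            skipped[drug] = (
                f"insufficient arm size (resistant {len(res)}, sensitive {len(sen)})"
            )
            continue
        t, df, p = welch_t_test(res, sen)
        diff = res.mean() - sen.mean()
        se = np.sqrt(res.var(ddof=1) / len(res) + sen.var(ddof=1) / len(sen))
        tcrit = stats.t.ppf(0.975, df) if np.isfinite(df) and se > 0 else 0.0
        results.append(
            DrugComparison(
                drug=drug,
                n_sensitive=len(sen),
                n_resistant=len(res),
                fold_change=float(np.exp(diff)),
                ci_low=float(np.exp(diff - tcrit * se)),
                ci_high=float(np.exp(diff + tcrit * se)),
                p=p,
            )
        )
    if bh_correct and results:
        padj = bh_adjust(np.array([r.p for r in results]))
        for r, q in zip(results, padj):
            r.padj = float(q)
    return results, skipped


def foldchange_concordance(
    log2fc_a: np.ndarray, log2fc_b: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation of paired log2 fold changes; (r, two-sided p).

    Undefined (NaN, NaN) when either vector has zero variance.
    """
    a = np.asarray(log2fc_a, dtype=float)
    b = np.asarray(log2fc_b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if a.var() == 0 or b.var() == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
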