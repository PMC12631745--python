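"""Simplified negative-binomial Wald differential expression.

A deliberately transparent DESeq2-family analysis: median-of-ratios size
factors, method-of-moments gene dispersions, a Wald test on the log2 ratio
of normalized group means, and Benjamini-Hochberg adjustment, gated at
padj < 0.05 and |log2FC| > 1.  No shrinkage, outlier filtering or
independent filtering — the pipeline's contribution is how the DE axis is
combined with attribution ranking, not the DE internals, and the full
external estimator can be slotted in as a comparator.

log2 fold changes are oriented resistant over sensitive throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["size_factors", "nb_wald", "bh_adjust", "call_deg", "deg_table"]

_DISPERSION_FLOOR = 1e-8
_PSEUDOCOUNT = 0.5


def size_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios per-sample normalization factors.

    Reference genes are those with strictly positive counts in every
    sample; each sample's factor is the median ratio of its counts to the
    per-gene geometric means, normalized to geometric mean 1.
    """
    c = np.asarray(counts, dtype=float)
    allpos = (c > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has positive counts in every sample; relax the "
            "low-expression filter or check the input matrix"
        )
    ref = c[allpos]
    geo = np.exp(np.log(ref).mean(axis=1))
    factors = np.median(ref / geo[:, None], axis=0)
    return factors / np.exp(np.log(factors).mean())


def nb_wald(
    counts: pd.DataFrame,
    factors: np.ndarray,
    labels: pd.Series,
) -> pd.DataFrame:
    """Per-gene Wald test of resistant vs sensitive normalized means.

    The NB variance mu + phi * mu^2 (phi by method of moments on the
    normalized counts, floored at 1e-8, averaged over the two groups) is
    propagated through the delta method to a standard error for
    log2(mean_resistant / mean_sensitive); a pseudo-count of 0.5 replaces
    zero group means so the fold change stays finite.  Genes with all-zero
    counts get log2fc 0 and p 1 by definition.

    Returns a frame indexed by gene with columns log2fc, se, p.
    """
    lab = labels.loc[counts.columns]
    is_res = (lab == "resistant").to_numpy()
    is_sen = (lab == "sensitive").to_numpy()
    if is_res.sum() < 2 or is_sen.sum() < 2:
        raise ValueError("need >= 2 samples per group")
    norm = counts.to_numpy(dtype=float) / np.asarray(factors, dtype=float)[None, :]
    n_r, n_s = int(is_res.sum()), int(is_sen.sum())
    mu_r = norm[:, is_res].mean(axis=1)
    mu_s = norm[:, is_sen].mean(axis=1)
    var_r = norm[:, is_res].var(axis=1, ddof=1)
    var_s = norm[:, is_sen].var(axis=1, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        phi_r = np.where(mu_r > 0, (var_r - mu_r) / mu_r**2, 0.0)
        phi_s = np.where(mu_s > 0, (var_s - mu_s) / mu_s**2, 0.0)
    phi = np.maximum((phi_r + phi_s) / 2.0, _DISPERSION_FLOOR)

    m_r = np.where(mu_r > 0, mu_r, _PSEUDOCOUNT)
    m_s = np.where(mu_s > 0, mu_s, _PSEUDOCOUNT)
    log2fc = np.log2(m_r / m_s)
    # delta method: var(ln mean_g) ~= (mu + phi mu^2) / (n mu^2)
    se = np.sqrt(
        (m_r + phi * m_r**2) / (n_r * m_r**2)
        + (m_s + phi * m_s**2) / (n_s * m_s**2)
    ) / np.log(2.0)
    z = np.divide(log2fc, se, out=np.zeros_like(se), where=se > 0)
    p = 2.0 * stats.norm.sf(np.abs(z))

    allzero = counts.to_numpy().sum(axis=1) == 0
    log2fc[allzero] = 0.0
    p[allzero] = 1.0

    return pd.DataFrame({"log2fc": log2fc, "se": se, "p": p}, index=counts.index)


def bh_adjust(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D array of p-values")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def call_deg(
    records: pd.DataFrame,
    padj_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
) -> tuple[set[str], set[str]]:
    """Split significant genes by direction with strict inequalities.

    up = {padj < threshold and log2fc > lfc_threshold}; down likewise with
    log2fc < -lfc_threshold.
    """
    sig = records["padj"] < padj_threshold
    up = set(records.index[sig & (records["log2fc"] > lfc_threshold)])
    down = set(records.index[sig & (records["log2fc"] < -lfc_threshold)])
    return up, down


def deg_table(
    counts: pd.DataFrame,
    labels: pd.Series,
    padj_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """The full DE stage: size factors, Wald test, BH, significance calls.

    Adds ``padj`` and a ``call`` column in {up, down, ns} to the
    :func:`nb_wald` output.
    """
    factors = size_factors(counts)
    records = nb_wald(counts, factors, labels)
    records["padj"] = bh_adjust(records["p"].to_numpy())
    up, down = call_deg(records, padj_threshold, lfc_threshold)
    call = pd.Series("ns", index=records.index, dtype=object)
    call[list(up)] = "up"
    call[list(down)] = "down"
    records["call"] = call
    return records
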