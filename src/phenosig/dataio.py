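"""Reading, merging and filtering of the three input sources.

Two IC50 tables (keyed by a shared cell-line identifier), a raw count
matrix and a log10(TPM+1) matrix are merged into one analysis-ready
dataset: only cell lines with complete, non-missing values in all four
sources survive, in deterministic (lexicographic) order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "IntegratedDataset",
    "merge_cohort",
    "filter_low_expression",
    "read_ic50_table",
    "read_expression_matrix",
    "read_manifest",
    "load_dataset",
]

# tokens accepted as "missing" in exported tables, besides empty fields
_NA_TOKENS = ["", "NA", "NaN", "nan", "null", "None", "."]


@dataclass
class IntegratedDataset:
    """Matched cell lines with both IC50 values and both expression views."""

    sample_ids: list[str]
    ic50_a: pd.Series
    ic50_b: pd.Series
    counts: pd.DataFrame  # genes x samples, nonnegative integers
    log_tpm: pd.DataFrame  # genes x samples

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def ic50_points(self) -> np.ndarray:
        """The per-sample (source A, source B) IC50 pairs as an (n, 2) array."""
        return np.column_stack([self.ic50_a.to_numpy(), self.ic50_b.to_numpy()])


def merge_cohort(
    ic50_table_a: pd.Series,
    ic50_table_b: pd.Series,
    counts: pd.DataFrame,
    log_tpm: pd.DataFrame,
) -> IntegratedDataset:
    """Retain exactly the ids with non-missing values in all four sources.

    Raises ``ValueError`` naming the per-source id counts when the
    intersection is empty.  Sample order is lexicographic by id so the
    result does not depend on input file order; gene order follows the
    count matrix.  Idempotent: merging a merged dataset changes nothing.
    """
    a_ok = set(ic50_table_a.dropna().index)
    b_ok = set(ic50_table_b.dropna().index)
    c_ok = set(counts.columns[counts.notna().all(axis=0)])
    t_ok = set(log_tpm.columns[log_tpm.notna().all(axis=0)])
    shared = a_ok & b_ok & c_ok & t_ok
    if not shared:
        raise ValueError(
            "no cell line has complete data in all four sources "
            f"(ic50_a: {len(a_ok)}, ic50_b: {len(b_ok)}, counts: {len(c_ok)}, "
            f"log_tpm: {len(t_ok)}, overlap: 0)"
        )
    ids = sorted(shared)
    genes = counts.index
    if not log_tpm.index.equals(genes):
        log_tpm = log_tpm.reindex(genes)
        if log_tpm.isna().any().any():
            raise ValueError("counts and log_tpm do not share gene ids")
    sub_counts = counts.loc[:, ids]
    return IntegratedDataset(
        sample_ids=ids,
        ic50_a=ic50_table_a.loc[ids].astype(float),
        ic50_b=ic50_table_b.loc[ids].astype(float),
        counts=sub_counts.round().astype(np.int64),
        log_tpm=log_tpm.loc[:, ids].astype(float),
    )


def filter_low_expression(counts: pd.DataFrame, min_total: int = 10) -> pd.DataFrame:
    """Keep genes whose summed count across samples is >= ``min_total``.

    Gene order is preserved; ``min_total = 0`` is the identity.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    keep = counts.sum(axis=1) >= min_total
    return counts.loc[keep]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","


def read_ic50_table(path: str | Path) -> pd.Series:
    """Read a two-column (id, value) table; empty/sentinel fields become NaN."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), na_values=_NA_TOKENS, keep_default_na=True)
    if df.shape[1] < 2:
        raise ValueError(f"{path} must have (id, value) columns")
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str), name="ic50")
    return s.astype(float)


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes-in-rows matrix with a header row of sample ids."""
    path = Path(path)
    df = pd.read_csv(
        path, sep=_sep_for(path), index_col=0, na_values=_NA_TOKENS, keep_default_na=True
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_manifest(path: str | Path) -> dict[str, str]:
    """Read a flat key=value (or 'key: value') manifest naming the inputs."""
    out: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        for sep in ("=", ":"):
            if sep in line:
                key, _, value = line.partition(sep)
                out[key.strip()] = value.strip()
                break
        else:
            raise ValueError(f"malformed manifest line: {raw!r}")
    return out


def load_dataset(manifest: dict[str, str], base: str | Path = ".") -> IntegratedDataset:
    """Load and merge the four inputs named by a manifest.

    Expects keys ``ic50_a``, ``ic50_b``, ``counts`` and ``tpm`` with paths
    relative to ``base`` (or absolute).
    """
    base = Path(base)
    required = ["ic50_a", "ic50_b", "counts", "tpm"]
    missing = [k for k in required if k not in manifest]
    if missing:
        raise ValueError(f"manifest lacks required inputs: {missing}")

    def _resolve(key: str) -> Path:
        p = Path(manifest[key])
        return p if p.is_absolute() else base / p

    return merge_cohort(
        read_ic50_table(_resolve("ic50_a")),
        read_ic50_table(_resolve("ic50_b")),
        read_expression_matrix(_resolve("counts")),
        read_expression_matrix(_resolve("tpm")),
    )
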