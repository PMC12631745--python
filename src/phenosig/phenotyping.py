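"""Sensitive/resistant phenotype labels from two-source IC50 profiles.

Cell lines are clustered on their (source A, source B) IC50 pairs with
Ward agglomeration; the number of clusters is chosen by mean silhouette
across hierarchical and k-means candidates.  A cluster whose mean IC50
rank is the highest in *both* sources becomes the resistant class, the
cluster lowest in both becomes the sensitive class, and clusters without a
consistent extreme profile are excluded — the cross-source consistency
rule that turns a four-cluster IC50 plane into a binary phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "ClusterAssignment",
    "SensitivityLabels",
    "IC50Phenotyper",
    "ward_cluster",
    "silhouette_mean",
    "choose_clustering",
    "assign_sensitivity",
    "anova_tukey",
]


@dataclass
class ClusterAssignment:
    labels: pd.Series  # sample id -> 1-based contiguous cluster index
    n_clusters: int
    linkage_record: np.ndarray | None  # scipy linkage matrix (hierarchical only)
    silhouette: float | None


@dataclass
class SensitivityLabels:
    labels: pd.Series  # sample id -> {sensitive, resistant}
    excluded: list[str]
    source_cluster: dict[str, int] = field(default_factory=dict)

    @property
    def sensitive_ids(self) -> list[str]:
        return list(self.labels.index[self.labels == "sensitive"])

    @property
    def resistant_ids(self) -> list[str]:
        return list(self.labels.index[self.labels == "resistant"])


def _validate_points(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points")
    if not np.isfinite(pts).all():
        raise ValueError("non-finite coordinates")
    return pts


def _contiguous(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters as 1..k preserving first-appearance order."""
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, c in enumerate(raw):
        if c not in mapping:
            mapping[c] = len(mapping) + 1
        out[i] = mapping[c]
    return out


def ward_cluster(
    points: np.ndarray,
    cut_distance: float = 8.0,
    index: pd.Index | None = None,
) -> ClusterAssignment:
    """Ward agglomeration on Euclidean distances, cut at a merge height.

    Clusters are the connected groups left after removing all merges whose
    height exceeds ``cut_distance``; a cut below the first merge height
    yields all singletons.
    """
    pts = _validate_points(points)
    Z = linkage(pts, method="ward")
    raw = fcluster(Z, t=cut_distance, criterion="distance")
    labels = _contiguous(raw)
    k = labels.max()
    sil = silhouette_mean(pts, labels) if 2 <= k <= len(pts) - 1 else None
    idx = index if index is not None else pd.RangeIndex(len(pts))
    return ClusterAssignment(
        labels=pd.Series(labels, index=idx),
        n_clusters=int(k),
        linkage_record=Z,
        silhouette=sil,
    )


def silhouette_mean(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette (b - a) / max(a, b) over samples.

    ``a`` is the mean intra-cluster distance, ``b`` the smallest mean
    distance to another cluster; singleton samples contribute 0.  Requires
    at least 2 non-empty clusters.
    """
    pts = _validate_points(points)
    lab = np.asarray(labels)
    if len(np.unique(lab)) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    if len(np.unique(lab)) > len(pts) - 1:
        raise ValueError("silhouette undefined when every sample is a singleton")
    return float(silhouette_score(pts, lab, metric="euclidean"))


def choose_clustering(
    points: np.ndarray,
    k_range: range | tuple[int, int] = (2, 10),
    seed: int = 0,
    index: pd.Index | None = None,
) -> tuple[str, int, ClusterAssignment, pd.DataFrame]:
    """Silhouette-guided model selection over hierarchical and k-means.

    Evaluates the mean silhouette for every (method, k) with k in
    ``k_range``; reports the per-method silhouette table and returns the
    assignment of the selected method at its best k.  Hierarchical wins
    whenever its best silhouette is at least as high as k-means' best (the
    more interpretable dendrogram is preferred on ties).  K-means uses 10
    seeded restarts.
    """
    pts = _validate_points(points)
    if isinstance(k_range, range):
        ks = list(k_range)
    else:
        ks = list(range(k_range[0], k_range[1] + 1))
    ks = [k for k in ks if 2 <= k <= len(pts) - 1]
    if not ks:
        raise ValueError("k_range leaves no feasible cluster count")
    if np.allclose(pts, pts[0]):
        raise ValueError("all points identical: clustering degenerate")

    Z = linkage(pts, method="ward")
    rows = []
    best: dict[str, tuple[float, int, np.ndarray]] = {}
    for k in ks:
        h_labels = _contiguous(fcluster(Z, t=k, criterion="maxclust"))
        if h_labels.max() >= 2:
            h_sil = silhouette_mean(pts, h_labels)
            rows.append(("hierarchical", k, h_sil))
            if "hierarchical" not in best or h_sil > best["hierarchical"][0]:
                best["hierarchical"] = (h_sil, k, h_labels)
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(pts)
        k_sil = silhouette_mean(pts, km.labels_)
        rows.append(("kmeans", k, k_sil))
        if "kmeans" not in best or k_sil > best["kmeans"][0]:
            best["kmeans"] = (k_sil, k, _contiguous(km.labels_ + 1))
    if not best:
        raise ValueError("no clustering produced a defined silhouette")
    report = pd.DataFrame(rows, columns=["method", "k", "silhouette"])

    if "hierarchical" in best and best["hierarchical"][0] >= best.get("kmeans", (-2,))[0]:
        method = "hierarchical"
    else:
        method = "kmeans"
    sil, k, labels = best[method]
    idx = index if index is not None else pd.RangeIndex(len(pts))
    assignment = ClusterAssignment(
        labels=pd.Series(labels, index=idx),
        n_clusters=int(k),
        linkage_record=Z if method == "hierarchical" else None,
        silhouette=sil,
    )
    return method, int(k), assignment, report


def assign_sensitivity(
    assignment: ClusterAssignment,
    ic50_a: pd.Series,
    ic50_b: pd.Series,
) -> SensitivityLabels:
    """Label clusters by cross-source agreement of extreme mean IC50 rank.

    Per cluster, the mean rank of its members' IC50 values is computed in
    each source and compared with the grand mean rank (n+1)/2.  The
    resistant class is the cluster ranked high in *both* sources (largest
    rank sum if several qualify), the sensitive class the cluster ranked
    low in both (smallest rank sum); clusters high in one source but low
    in the other — discordant between platforms — are excluded.  Raises
    with a per-cluster rank report when no cluster is consistently high
    or none is consistently low.
    """
    if assignment.n_clusters < 2:
        raise ValueError("need at least 2 clusters to assign sensitivity")
    ids = assignment.labels.index
    ra = pd.Series(stats.rankdata(ic50_a.loc[ids]), index=ids)
    rb = pd.Series(stats.rankdata(ic50_b.loc[ids]), index=ids)
    mean_ranks = pd.DataFrame(
        {
            "rank_a": ra.groupby(assignment.labels).mean(),
            "rank_b": rb.groupby(assignment.labels).mean(),
        }
    )
    mid = (len(ids) + 1) / 2.0
    high_both = mean_ranks[(mean_ranks["rank_a"] > mid) & (mean_ranks["rank_b"] > mid)]
    low_both = mean_ranks[(mean_ranks["rank_a"] < mid) & (mean_ranks["rank_b"] < mid)]
    if high_both.empty or low_both.empty:
        raise ValueError(
            "no cluster is consistently extreme in both IC50 sources; "
            f"per-cluster mean ranks:\n{mean_ranks}"
        )
    resistant_cluster = int(high_both.sum(axis=1).idxmax())
    sensitive_cluster = int(low_both.sum(axis=1).idxmin())
    labels = pd.Series(index=ids, dtype=object)
    labels[assignment.labels == sensitive_cluster] = "sensitive"
    labels[assignment.labels == resistant_cluster] = "resistant"
    excluded = list(ids[labels.isna()])
    return SensitivityLabels(
        labels=labels.dropna(),
        excluded=excluded,
        source_cluster={"sensitive": sensitive_cluster, "resistant": resistant_cluster},
    )


def anova_tukey(
    values: np.ndarray, labels: np.ndarray
) -> tuple[float, float, pd.DataFrame]:
    """One-way fixed-effects ANOVA plus Tukey HSD pairwise comparisons.

    Returns (F, p, pairwise table with Tukey-adjusted p-values).  When all
    groups have identical constant values the test degenerates to p = 1
    rather than a division error.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in np.unique(labels)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 members each")
    if all(np.ptp(g) == 0 for g in groups) and np.ptp(values) == 0:
        pairs = pd.DataFrame(columns=["group1", "group2", "meandiff", "p_adj"])
        return 0.0, 1.0, pairs
    F, p = stats.f_oneway(*groups)
    tukey = pairwise_tukeyhsd(values, labels)
    frame = pd.DataFrame(
        tukey.summary().data[1:], columns=[str(c) for c in tukey.summary().data[0]]
    )
    frame = frame.rename(columns={"p-adj": "p_adj"})
    return float(F), float(p), frame


class IC50Phenotyper(ClusterMixin, BaseEstimator):
    """Estimator wrapper: IC50 pairs in, sensitive/resistant labels out.

    Parameters
    ----------
    k_range : (int, int)
        Inclusive range of cluster counts scanned by silhouette.
    log_scale : bool
        Cluster ln-transformed IC50s instead of raw concentrations.  Raw
        matches the concentration axes of typical IC50 scatter plots; the
        log option guards against extreme skew.
    cut_distance : float or None
        When set, skip model selection and cut the Ward tree at this merge
        height instead.
    random_state : int
        Seed for the k-means comparator.

    Attributes (after ``fit``)
    --------------------------
    method_, n_clusters_, assignment_, silhouette_report_ : model selection
    labels_ : ndarray of cluster indices
    sensitivity_ : :class:`SensitivityLabels`
    """

    def __init__(
        self,
        k_range: tuple[int, int] = (2, 10),
        log_scale: bool = False,
        cut_distance: float | None = None,
        random_state: int = 0,
    ):
        self.k_range = k_range
        self.log_scale = log_scale
        self.cut_distance = cut_distance
        self.random_state = random_state

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            index, pts = X.index, X.to_numpy(dtype=float)
        else:
            pts = np.asarray(X, dtype=float)
            index = pd.RangeIndex(len(pts))
        if self.log_scale:
            pts = np.log(pts)
        if self.cut_distance is not None:
            assignment = ward_cluster(pts, self.cut_distance, index=index)
            self.method_ = "hierarchical"
            self.silhouette_report_ = None
        else:
            self.method_, _, assignment, self.silhouette_report_ = choose_clustering(
                pts, self.k_range, seed=self.random_state, index=index
            )
        self.assignment_ = assignment
        self.n_clusters_ = assignment.n_clusters
        self.labels_ = assignment.labels.to_numpy()
        a = pd.Series(pts[:, 0], index=index)
        b = pd.Series(pts[:, 1], index=index)
        self.sensitivity_ = assign_sensitivity(assignment, a, b)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
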