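"""Clustering, silhouette, model selection and the consistency rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from phenosig import (
    anova_tukey,
    assign_sensitivity,
    choose_clustering,
    silhouette_mean,
    simulate_cohort,
    ward_cluster,
    IC50Phenotyper,
    SyntheticConfig,
)


# ---------------------------------------------------------------------------
# independent oracles


def ward_oracle(points):
    """Brute-force Ward agglomeration: exhaustively merge the cheapest pair.

    Returns the merge sequence [(frozenset_a, frozenset_b, height), ...]
    using the Ward distance sqrt(2|A||B|/(|A|+|B|)) * ||centroid diff||.
    """
    clusters = {i: frozenset([i]) for i in range(len(points))}
    merges = []
    while len(clusters) > 1:
        best = None
        for i in clusters:
            for j in clusters:
                if i >= j:
                    continue
                a, b = clusters[i], clusters[j]
                ca = points[list(a)].mean(axis=0)
                cb = points[list(b)].mean(axis=0)
                d = np.sqrt(2 * len(a) * len(b) / (len(a) + len(b))) * np.linalg.norm(
                    ca - cb
                )
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        merges.append((clusters[i], clusters[j], d))
        clusters[min(i, j)] = clusters[i] | clusters[j]
        del clusters[max(i, j)]
    return merges


def silhouette_oracle(points, labels):
    """Direct formula evaluation from the pairwise distance matrix."""
    D = squareform(pdist(points))
    labels = np.asarray(labels)
    scores = []
    for i in range(len(points)):
        same = (labels == labels[i]) & (np.arange(len(points)) != i)
        if not same.any():
            scores.append(0.0)
            continue
        a = D[i, same].mean()
        b = min(
            D[i, labels == other].mean()
            for other in np.unique(labels)
            if other != labels[i]
        )
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


# ---------------------------------------------------------------------------


class TestWardCluster:
    def test_two_blobs_recovered(self, rng):
        pts = np.vstack(
            [rng.normal(0, 0.1, (10, 2)), rng.normal(20, 0.1, (10, 2))]
        )
        res = ward_cluster(pts, cut_distance=8.0)
        assert res.n_clusters == 2
        labels = res.labels.to_numpy()
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[-1]

    def test_merge_sequence_matches_bruteforce_oracle(self, rng):
        """Six hand-traceable points: scipy Ward equals exhaustive merging."""
        pts = rng.normal(0, 1, (6, 2)) * 3
        res = ward_cluster(pts, cut_distance=1e9)
        oracle = ward_oracle(pts)
        heights = res.linkage_record[:, 2]
        np.testing.assert_allclose(heights, [m[2] for m in oracle], rtol=1e-9)
        # membership of each merged pair matches
        members = {i: frozenset([i]) for i in range(6)}
        for step, row in enumerate(res.linkage_record):
            a, b = members[int(row[0])], members[int(row[1])]
            assert {a, b} == {oracle[step][0], oracle[step][1]}
            members[6 + step] = a | b

    def test_cut_below_first_merge_gives_singletons(self, rng):
        pts = rng.normal(0, 1, (5, 2))
        first = ward_cluster(pts, cut_distance=1e9).linkage_record[0, 2]
        res = ward_cluster(pts, cut_distance=first * 0.5)
        assert res.n_clusters == 5

    def test_heights_monotone(self, rng):
        pts = rng.normal(0, 1, (30, 2))
        heights = ward_cluster(pts, 8.0).linkage_record[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ward_cluster(np.array([[0.0, np.nan], [1.0, 1.0]]), 8.0)


class TestSilhouette:
    def test_far_pairs_approach_one(self):
        pts = np.array([[0, 0], [0, 0.001], [1e6, 0], [1e6, 0.001]])
        s = silhouette_mean(pts, [1, 1, 2, 2])
        assert s > 0.999

    def test_matches_direct_formula(self, rng):
        pts = rng.normal(0, 1, (4, 2))
        labels = np.array([1, 1, 2, 2])
        assert silhouette_mean(pts, labels) == pytest.approx(
            silhouette_oracle(pts, labels), abs=1e-9
        )

    def test_random_labels_on_one_blob_near_zero(self, rng):
        pts = rng.normal(0, 1, (200, 2))
        labels = rng.integers(1, 3, 200)
        assert silhouette_mean(pts, labels) <= 0.1

    def test_single_cluster_rejected(self, rng):
        with pytest.raises(ValueError):
            silhouette_mean(rng.normal(size=(5, 2)), [1, 1, 1, 1, 1])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        scale=st.floats(0.01, 100.0, allow_nan=False),
    )
    def test_bounded_and_scale_invariant(self, seed, scale):
        r = np.random.default_rng(seed)
        pts = r.normal(0, 1, (12, 2))
        labels = r.integers(1, 4, 12)
        if len(np.unique(labels)) < 2:
            labels[0] = 1
            labels[1] = 2
        s = silhouette_mean(pts, labels)
        assert -1.0 <= s <= 1.0
        assert silhouette_mean(pts * scale, labels) == pytest.approx(s, abs=1e-9)


class TestChooseClustering:
    def test_four_planted_blobs(self, rng):
        centers = np.array([[0, 0], [40, 0], [0, 40], [40, 40]])
        pts = np.vstack([rng.normal(c, 1.0, (15, 2)) for c in centers])
        method, k, assignment, report = choose_clustering(pts, seed=0)
        assert k == 4
        assert assignment.n_clusters == 4
        assert set(report["method"]) == {"hierarchical", "kmeans"}

    def test_two_planted_blobs(self, rng):
        pts = np.vstack([rng.normal(0, 1, (20, 2)), rng.normal(50, 1, (20, 2))])
        _, k, _, _ = choose_clustering(pts, seed=0)
        assert k == 2

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError):
            choose_clustering(np.ones((10, 2)), seed=0)


class TestAssignSensitivity:
    @staticmethod
    def _blob_assignment(means):
        """One 5-point blob per (mu_a, mu_b) pair; tiny within-blob spread."""
        r = np.random.default_rng(0)
        pts, labels = [], []
        for c, (ma, mb) in enumerate(means, start=1):
            pts.append(np.column_stack([r.normal(ma, 0.01, 5), r.normal(mb, 0.01, 5)]))
            labels += [c] * 5
        pts = np.vstack(pts)
        ids = [f"s{i}" for i in range(len(labels))]
        from phenosig.phenotyping import ClusterAssignment

        return (
            ClusterAssignment(
                labels=pd.Series(labels, index=ids),
                n_clusters=len(means),
                linkage_record=None,
                silhouette=None,
            ),
            pd.Series(pts[:, 0], index=ids),
            pd.Series(pts[:, 1], index=ids),
        )

    def test_four_quadrants(self):
        assignment, a, b = self._blob_assignment(
            [(1, 1), (9, 9), (1, 9), (9, 1)]
        )
        res = assign_sensitivity(assignment, a, b)
        assert res.source_cluster == {"sensitive": 1, "resistant": 2}
        assert len(res.excluded) == 10
        assert set(res.labels.unique()) == {"sensitive", "resistant"}

    def test_two_concordant_clusters_nothing_excluded(self):
        assignment, a, b = self._blob_assignment([(1, 1), (9, 9)])
        res = assign_sensitivity(assignment, a, b)
        assert res.excluded == []
        assert len(res.labels) == 10

    def test_anti_ordered_sources_rejected(self):
        assignment, a, b = self._blob_assignment([(1, 9), (9, 1)])
        with pytest.raises(ValueError, match="consistently extreme"):
            assign_sensitivity(assignment, a, b)

    def test_labels_and_excluded_partition_cohort(self):
        assignment, a, b = self._blob_assignment([(1, 1), (9, 9), (1, 9)])
        res = assign_sensitivity(assignment, a, b)
        assert set(res.labels.index) | set(res.excluded) == set(a.index)
        assert not set(res.labels.index) & set(res.excluded)


class TestAnovaTukey:
    def test_closed_form_toy(self):
        # groups {1,2,3} and {4,5,6}: MSB = 13.5, MSW = 1 -> F = 13.5
        F, p, pairs = anova_tukey([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert F == pytest.approx(13.5, abs=1e-9)
        assert len(pairs) == 1

    def test_shuffled_identical_groups_nonsignificant(self, rng):
        vals = rng.normal(0, 1, 60)
        labels = np.array(["a", "b", "c"] * 20)
        F, p, _ = anova_tukey(vals, labels)
        assert p > 0.01

    def test_separated_group_significant(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 20), rng.normal(10, 1, 20)])
        labels = ["a"] * 20 + ["b"] * 20
        _, p, pairs = anova_tukey(vals, labels)
        assert p < 1e-6

    def test_degenerate_constant_input(self):
        F, p, _ = anova_tukey([2.0] * 6, ["a"] * 3 + ["b"] * 3)
        assert p == 1.0


class TestPhenotyperRecovery:
    def test_default_cohort_recovers_truth(self, default_cohort):
        """k = 4 is selected and the labels match the planted classes."""
        ic50 = pd.DataFrame(
            {"a": default_cohort.ic50_a, "b": default_cohort.ic50_b}
        )
        ph = IC50Phenotyper(random_state=0).fit(ic50)
        assert ph.n_clusters_ == 4
        truth = default_cohort.truth_labels
        pred = ph.sensitivity_.labels
        agree = (truth.loc[pred.index] == pred).mean()
        assert agree > 0.95
        assert len(ph.sensitivity_.excluded) == default_cohort.config.n_discordant
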