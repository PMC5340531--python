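"""Ward clustering, validity indexes, inner distance, reference models."""

import itertools

import numpy as np
import pytest

import ionclamp as ic
from ionclamp.cluster import (
    WardClustering,
    cluster_names,
    cut,
    dunn_index,
    inner_distance,
    reference_models,
    scan_k,
    validity_indexes,
    ward_linkage,
)


# ---------------------------------------------------------------------------
# brute-force Ward oracle: recompute all pair costs at every step
# ---------------------------------------------------------------------------

def brute_force_ward(points):
    """Greedy agglomeration minimizing the within-cluster variance increase.

    Returns the merge sequence as (frozenset_a, frozenset_b, height) with
    the conventional height sqrt(2 * delta_ESS).
    """
    clusters = [frozenset([i]) for i in range(len(points))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            pa = points[list(a)]
            pb = points[list(b)]
            d2 = np.sum((pa.mean(0) - pb.mean(0)) ** 2)
            cost = len(a) * len(b) / (len(a) + len(b)) * d2
            if best is None or cost < best[0]:
                best = (cost, a, b)
        cost, a, b = best
        merges.append((a, b, np.sqrt(2 * cost)))
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    return merges


def _linkage_merge_sets(tree):
    """Per merge: the two leaf sets joined and the height."""
    n = tree.n_leaves
    sets = {i: frozenset([i]) for i in range(n)}
    out = []
    for row_idx, (a, b, h, _) in enumerate(tree.merges):
        sa, sb = sets[int(a)], sets[int(b)]
        out.append((sa, sb, h))
        sets[n + row_idx] = sa | sb
    return out


class TestWardLinkage:
    def test_two_points_merge_at_their_distance(self):
        pts = np.array([[0.0, 0.0], [3.0, 4.0]])
        tree = ward_linkage(pts)
        assert tree.merges.shape == (1, 4)
        assert tree.merges[0, 2] == pytest.approx(5.0)

    def test_duplicated_points_merge_at_zero_height(self):
        pts = np.zeros((5, 3))
        tree = ward_linkage(pts)
        assert np.allclose(tree.merges[:, 2], 0.0)

    def test_heights_are_monotone(self):
        rng = np.random.default_rng(0)
        tree = ward_linkage(rng.normal(size=(30, 4)))
        assert np.all(np.diff(tree.merges[:, 2]) >= -1e-12)

    @pytest.mark.parametrize("seed", range(50))
    def test_equals_brute_force_on_small_sets(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        pts = rng.normal(size=(n, int(rng.integers(1, 4))))
        tree = ward_linkage(pts)
        got = _linkage_merge_sets(tree)
        expected = brute_force_ward(pts)
        for (ga, gb, gh), (ea, eb, eh) in zip(got, expected):
            assert {ga, gb} == {ea, eb}
            assert gh == pytest.approx(eh, rel=1e-9)

    def test_non_finite_scores_rejected(self):
        pts = np.array([[0.0, np.nan], [1.0, 2.0]])
        with pytest.raises(ValueError):
            ward_linkage(pts)


@pytest.fixture(scope="module")
def tree():
    rng = np.random.default_rng(3)
    pts = np.vstack([rng.normal(0, 0.1, (4, 2)), rng.normal(5, 0.1, (4, 2))])
    return pts, ward_linkage(pts)


class TestCut:
    def test_extreme_cuts(self, tree):
        pts, t = tree
        assert len(np.unique(cut(t, 8))) == 8
        assert len(np.unique(cut(t, 1))) == 1
        with pytest.raises(ValueError):
            cut(t, 0)
        with pytest.raises(ValueError):
            cut(t, 9)

    def test_two_blob_recovery(self, tree):
        pts, t = tree
        labels = cut(t, 2)
        assert len(set(labels[:4])) == 1
        assert len(set(labels[4:])) == 1
        assert labels[0] != labels[4]

    def test_cuts_are_nested_refinements(self, tree):
        pts, t = tree
        for k in range(2, 9):
            fine = cut(t, k)
            coarse = cut(t, k - 1)
            # each fine cluster maps into exactly one coarse cluster
            for c in np.unique(fine):
                assert len(np.unique(coarse[fine == c])) == 1


# 6-point worked set: two tight pairs and one loose pair
WORKED_POINTS = np.array(
    [[0.0, 0.0], [1.0, 0.0], [10.0, 0.0], [11.0, 0.0], [0.0, 20.0], [4.0, 20.0]]
)
WORKED_LABELS = np.array([0, 0, 1, 1, 2, 2])


def _oracle_indexes(points, labels):
    """Direct evaluation of the four validity indexes from their formulas."""
    n = len(points)
    uniq = np.unique(labels)
    d = np.linalg.norm(points[:, None] - points[None, :], axis=2)

    # silhouette: mean over points of (b - a) / max(a, b)
    sil = []
    for i in range(n):
        own = labels[i]
        same = [j for j in range(n) if labels[j] == own and j != i]
        a = np.mean([d[i, j] for j in same])
        b = min(
            np.mean([d[i, j] for j in range(n) if labels[j] == other])
            for other in uniq
            if other != own
        )
        sil.append((b - a) / max(a, b))
    silhouette = float(np.mean(sil))

    # Dunn: min inter-cluster distance / max intra-cluster diameter
    inter = min(
        d[i, j]
        for i in range(n)
        for j in range(n)
        if labels[i] != labels[j]
    )
    diam = max(
        d[i, j]
        for i in range(n)
        for j in range(n)
        if labels[i] == labels[j]
    )
    dunn = inter / diam

    # Davies-Bouldin: mean over clusters of the worst (s_i + s_j) / d_ij
    centers = {c: points[labels == c].mean(0) for c in uniq}
    scatter = {
        c: np.mean(np.linalg.norm(points[labels == c] - centers[c], axis=1)) for c in uniq
    }
    db = np.mean(
        [
            max(
                (scatter[i] + scatter[j]) / np.linalg.norm(centers[i] - centers[j])
                for j in uniq
                if j != i
            )
            for i in uniq
        ]
    )

    # Calinski-Harabasz: between/within variance ratio
    grand = points.mean(0)
    ssb = sum(len(points[labels == c]) * np.sum((centers[c] - grand) ** 2) for c in uniq)
    ssw = sum(np.sum((points[labels == c] - centers[c]) ** 2) for c in uniq)
    ch = (ssb / (len(uniq) - 1)) / (ssw / (n - len(uniq)))
    return silhouette, dunn, float(db), float(ch)


class TestValidityIndexes:
    def test_worked_set_matches_direct_formulas(self):
        got = validity_indexes(WORKED_POINTS, WORKED_LABELS)
        sil, dunn, db, ch = _oracle_indexes(WORKED_POINTS, WORKED_LABELS)
        assert got["silhouette"] == pytest.approx(sil, rel=1e-9)
        assert got["dunn"] == pytest.approx(dunn, rel=1e-9)
        assert got["davies_bouldin"] == pytest.approx(db, rel=1e-9)
        assert got["calinski_harabasz"] == pytest.approx(ch, rel=1e-9)
        assert got["singleton_count"] == 0

    def test_zero_scatter_clusters_have_zero_davies_bouldin(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [5.0, 5.0]])
        labels = np.array([0, 0, 1, 1])
        got = validity_indexes(pts, labels)
        assert got["davies_bouldin"] == 0.0
        assert got["silhouette"] == pytest.approx(1.0)

    def test_silhouette_approaches_one_with_separation(self):
        for sep, expect_min in [(10.0, 0.8), (1000.0, 0.99)]:
            pts = np.array([[0.0, 0], [1.0, 0], [sep, 0], [sep + 1, 0]])
            got = validity_indexes(pts, np.array([0, 0, 1, 1]))
            assert got["silhouette"] > expect_min

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            validity_indexes(WORKED_POINTS, np.zeros(6, dtype=int))


class TestInnerDistance:
    def test_singleton_clusters_give_zero(self):
        mat = np.random.default_rng(1).normal(size=(5, 8))
        assert inner_distance(mat, np.arange(5)) == 0.0

    def test_identical_members_give_zero(self):
        mat = np.tile([[1.0, 2.0, 3.0]], (2, 1))
        assert inner_distance(mat, np.zeros(2, dtype=int)) == 0.0

    def test_small_integer_worked_example(self):
        # two clusters of two vectors each; direct arithmetic:
        # cluster 0: s = [0,0,0,0], [2,2,2,2]; mean [1,1,1,1];
        #   each member deviates by 1 everywhere -> mean |dev| = 1
        # cluster 1: s = [0,4,0,4], [0,0,0,0]; mean [0,2,0,2];
        #   each member deviates by (0+2+0+2)/4 = 1 -> 1
        # average over clusters: (1 + 1) / 2 = 1
        mat = np.array([[0, 0, 0, 0], [2, 2, 2, 2], [0, 4, 0, 4], [0, 0, 0, 0]], float)
        labels = np.array([0, 0, 1, 1])
        assert inner_distance(mat, labels) == pytest.approx(1.0)

    def test_per_protocol_dict_form(self):
        mats = {"activation": np.zeros((4, 6)), "ramp": np.ones((4, 3))}
        out = inner_distance(mats, np.array([0, 0, 1, 1]))
        assert out == {"activation": 0.0, "ramp": 0.0}


class TestReferenceModels:
    def test_singleton_cluster_returns_its_member(self):
        refs = reference_models(np.array([[0.0], [9.0]]), np.array([0, 1]), ["a", "b"])
        assert refs == {0: "a", 1: "b"}

    def test_symmetric_tie_broken_lexicographically(self):
        pts = np.array([[-1.0], [1.0]])
        refs = reference_models(pts, np.array([0, 0]), ["zed", "abe"])
        assert refs[0] == "abe"

    def test_argmin_matches_exhaustive_scan(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(5, 3))
        ids = [f"m{i}" for i in range(5)]
        refs = reference_models(pts, np.zeros(5, dtype=int), ids)
        center = pts.mean(0)
        best = ids[int(np.argmin(np.linalg.norm(pts - center, axis=1)))]
        assert refs[0] == best


class TestScanK:
    def test_monotone_singletons_and_terminal_inner_distance(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(10, 3))
        tree = ward_linkage(pts)
        feats = {"activation": rng.normal(size=(10, 16))}
        table = scan_k(tree, pts, feats, k_range=range(2, 11))
        # singleton count non-increasing as k decreases
        ordered = table.sort_values("k", ascending=False)["singleton_count"].to_numpy()
        assert np.all(np.diff(ordered) <= 0)
        last = table[table["k"] == 10].iloc[0]
        assert last["inner_distance_activation"] == 0.0

    def test_silhouette_peaks_at_true_cluster_count(self, recovery_ensemble):
        space = recovery_ensemble["space"]
        tree = ward_linkage(space.scores_, space.ensemble_ids_)
        table = scan_k(tree, space.scores_, k_range=range(2, 11))
        best_k = int(table.loc[table["silhouette"].idxmax(), "k"])
        assert best_k == 5


class TestClusterNames:
    def test_threshold_rule(self):
        labels = np.array([0, 0, 0, 1, 1, 1, 1])
        subtypes = ["A-type", "A-type", "dr", "a", "b", "c", "d"]
        names = cluster_names(labels, subtypes)
        assert names[0] == "A-type/dr"  # 2/3 and 1/3 both reach 30%
        assert names[1] == "mixed"  # four labels at 25% each


class TestWardClusteringEstimator:
    def test_fit_exposes_labels_and_references(self, recovery_ensemble):
        space = recovery_ensemble["space"]
        est = WardClustering(n_clusters=5)
        labels = est.fit_predict(space.scores_, ids=space.ensemble_ids_)
        assert len(np.unique(labels)) == 5
        assert set(est.reference_models_) == set(range(5))
        assert est.get_params() == {"n_clusters": 5}
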