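import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from outliersuite.clustering import (
    hierarchical,
    hopkins,
    k_selection,
    kmeans,
    merge_tree_newick,
    profile_clusters,
    vat_order,
)


def _blobs(n_per, centers, spread, seed):
    rng = np.random.default_rng(seed)
    parts = [rng.normal(c, spread, size=(n_per, len(c))) for c in centers]
    return pd.DataFrame(np.vstack(parts))


# ----------------------------------------------------------------- Hopkins


def test_hopkins_uniform_null_near_half():
    vals = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        m = pd.DataFrame(rng.uniform(size=(100, 3)))
        vals.append(hopkins(m, seed=seed).H)
    assert abs(np.mean(vals) - 0.5) < 0.1


def test_hopkins_two_blobs_high():
    m = _blobs(25, [(0, 0), (10, 10)], 0.2, seed=0)
    assert hopkins(m, seed=0).H > 0.75


def test_hopkins_deterministic():
    m = _blobs(20, [(0, 0), (5, 5)], 0.5, seed=1)
    assert hopkins(m, seed=3).H == hopkins(m, seed=3).H


def test_hopkins_degenerate_errors():
    with pytest.raises(ValueError, match="identical"):
        hopkins(pd.DataFrame(np.ones((12, 2))), seed=0)


# --------------------------------------------------------------------- VAT


def test_vat_sorted_line_is_monotone():
    pts = np.array([0.0, 1.0, 2.5, 4.0, 7.0, 11.0])[:, None]
    d = squareform(pdist(pts))
    perm, _ = vat_order(d)
    diffs = np.diff(pts[perm, 0])
    assert np.all(diffs > 0) or np.all(diffs < 0)


def test_vat_separated_clusters_form_blocks():
    m = _blobs(8, [(0, 0), (50, 50)], 0.3, seed=2)
    d = squareform(pdist(m.to_numpy()))
    perm, rd = vat_order(d)
    first_half = set(perm[:8])
    assert first_half in ({*range(8)}, {*range(8, 16)})
    within = max(rd[:8, :8].max(), rd[8:, 8:].max())
    between = rd[:8, 8:].min()
    assert within < between


def test_vat_single_point_identity():
    perm, rd = vat_order(np.zeros((1, 1)))
    assert perm.tolist() == [0]


def test_vat_rejects_asymmetric():
    with pytest.raises(ValueError, match="symmetric"):
        vat_order(np.array([[0.0, 1.0], [2.0, 0.0]]))


# ------------------------------------------------------------- k selection


def test_k_selection_two_blobs_prefers_k2():
    m = _blobs(20, [(0, 0), (10, 10)], 0.5, seed=3)
    table = k_selection(m, range(2, 7), seed=0)
    assert table["silhouette"].idxmax() == 2
    assert table["davies_bouldin"].idxmin() == 2


def test_k_selection_indices_match_brute_force_formulas():
    pts = pd.DataFrame([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
    table = k_selection(pts, range(2, 3), seed=0)
    # planted k=2 solution: {0,1} and {2,3}
    # silhouette: a=1, b=sqrt(100..101) mean -> per point (b-a)/b
    b = (np.sqrt(100.0) + np.sqrt(101.0)) / 2.0
    sil = (b - 1.0) / b
    assert table.loc[2, "silhouette"] == pytest.approx(sil, abs=1e-9)
    # WSS: each cluster two points 1 apart -> 2 * 2 * 0.25
    assert table.loc[2, "wss"] == pytest.approx(1.0, abs=1e-9)
    # CH: B/W * (n-k)/(k-1); between = sum sizes*||c_i - grand||^2 = 4*25
    ch = (100.0 / 1.0) * (4 - 2) / (2 - 1)
    assert table.loc[2, "calinski_harabasz"] == pytest.approx(ch, abs=1e-9)
    # DB: s_i = mean dist to centroid = 0.5; M_ij = 10 -> (0.5+0.5)/10
    assert table.loc[2, "davies_bouldin"] == pytest.approx(0.1, abs=1e-9)


def test_wss_zero_at_k_equals_n():
    pts = _blobs(3, [(0, 0), (5, 5)], 1.0, seed=4)
    km = kmeans(pts, k=len(pts), seed=0)
    assert km.wss == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------- K-means


def test_kmeans_recovers_planted_blobs():
    m = _blobs(15, [(0, 0), (8, 8)], 0.3, seed=5)
    km = kmeans(m, 2, seed=0)
    first = km.labels.iloc[:15]
    second = km.labels.iloc[15:]
    assert first.nunique() == 1 and second.nunique() == 1
    assert first.iloc[0] != second.iloc[0]


def test_kmeans_k1_wss_is_total_ss():
    m = _blobs(10, [(0, 0)], 1.0, seed=6)
    km = kmeans(m, 1, seed=0)
    x = m.to_numpy()
    assert km.wss == pytest.approx(((x - x.mean(axis=0)) ** 2).sum())


def test_kmeans_deterministic_given_seed():
    m = _blobs(20, [(0, 0), (4, 4)], 1.0, seed=7)
    l1 = kmeans(m, 3, seed=9).labels
    l2 = kmeans(m, 3, seed=9).labels
    pd.testing.assert_series_equal(l1, l2)


# ------------------------------------------------------------ hierarchical


def _brute_force_complete_linkage(x):
    """Naive agglomeration, recording merge heights."""
    clusters = [[i] for i in range(len(x))]
    d = squareform(pdist(x))
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None, None)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                h = max(d[i, j] for i in clusters[a] for j in clusters[b])
                if h < best[0]:
                    best = (h, a, b)
        h, a, b = best
        heights.append(h)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return np.array(heights)


def test_complete_linkage_matches_brute_force():
    rng = np.random.default_rng(8)
    x = rng.standard_normal((12, 3))
    hc = hierarchical(pd.DataFrame(x), k=2)
    np.testing.assert_allclose(
        np.sort(hc.merge_tree[:, 2]), np.sort(_brute_force_complete_linkage(x)), atol=1e-9)


def test_merge_heights_monotone():
    rng = np.random.default_rng(9)
    hc = hierarchical(pd.DataFrame(rng.standard_normal((25, 4))), k=3)
    heights = hc.merge_tree[:, 2]
    assert np.all(np.diff(heights) >= -1e-12)


def test_identical_points_merge_first_at_zero():
    pts = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [9.0, 1.0]])
    hc = hierarchical(pts, k=2)
    assert hc.merge_tree[0, 2] == pytest.approx(0.0)
    assert set(hc.merge_tree[0, :2].astype(int)) == {0, 1}


def test_cut_at_n_gives_singletons():
    m = _blobs(4, [(0, 0), (6, 6)], 1.0, seed=10)
    hc = hierarchical(m, k=len(m))
    assert hc.labels.nunique() == len(m)


def test_cut_at_k_yields_k_groups():
    m = _blobs(10, [(0, 0), (6, 6), (12, 0)], 0.4, seed=11)
    for k in (2, 3, 4):
        assert hierarchical(m, k=k).labels.nunique() == k


def test_newick_string_has_all_leaves():
    m = _blobs(3, [(0, 0), (5, 5)], 0.5, seed=12)
    m.index = [f"s{i}" for i in range(len(m))]
    hc = hierarchical(m, k=2)
    nwk = merge_tree_newick(hc.merge_tree, list(m.index))
    assert nwk.endswith(";")
    for leaf in m.index:
        assert leaf in nwk


def test_kmeans_and_hierarchical_agree_on_separated_planted_outliers(invitro):
    """On the cell-model fixture the two algorithms at k=2 split the
    standardized profiles identically."""
    from outliersuite.io import standardize
    m, _, truth = invitro
    std = standardize(m).values
    km = kmeans(std, 2, seed=0)
    hc = hierarchical(std, 2)
    agreement = (km.labels == hc.labels).mean()
    assert agreement in (0.0, 1.0)  # identical partitions up to label swap
    minority = km.labels.value_counts().idxmin()
    assert set(km.labels.index[km.labels == minority]) == set(truth.index[truth])


# ---------------------------------------------------------------- profiles


def test_profile_sizes_and_percentages():
    m = pd.DataFrame(np.zeros((44, 2)), columns=["a", "b"])
    labels = pd.Series([0] * 3 + [1] * 41, index=m.index)
    prof = profile_clusters(m, labels)
    assert prof.loc[0, "size"] == 3 and prof.loc[0, "percentage"] == 6.8
    assert prof.loc[1, "size"] == 41 and prof.loc[1, "percentage"] == 93.2


def test_profile_single_cluster_hundred_percent():
    m = pd.DataFrame(np.ones((7, 2)))
    prof = profile_clusters(m, pd.Series([0] * 7, index=m.index))
    assert prof.loc[0, "percentage"] == 100.0


def test_profile_planted_hyperexpressing_cluster_dominates():
    rng = np.random.default_rng(13)
    base = rng.standard_normal((30, 4))
    base[:5] += 5.0  # planted hyper-expressing group on every marker
    m = pd.DataFrame(base, columns=list("wxyz"))
    labels = pd.Series([0] * 5 + [1] * 25, index=m.index)
    prof = profile_clusters(m, labels)
    for feat in "wxyz":
        assert prof.loc[0, f"mean_{feat}"] > prof.loc[1, f"mean_{feat}"]
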