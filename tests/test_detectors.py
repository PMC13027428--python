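import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import squareform, pdist

from outliersuite.detectors import (
    DetectorParams,
    aggregate_to_samples,
    detect_all,
    detect_iqr,
    detect_isolation_forest,
    detect_lof,
    detect_mad,
    detect_mahalanobis,
    detect_zscore,
    test_dixon as dixon_test,
    test_grubbs as grubbs_test,
    test_rosner as rosner_test,
)

ANCHOR = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 100.0])


# ------------------------------------------------------------------ IQR


def test_iqr_flags_only_extreme_value():
    flags, info = detect_iqr(ANCHOR)
    assert info["hi"] == pytest.approx(14.5)
    assert flags.tolist() == [False] * 9 + [True]


def test_iqr_constant_vector_no_flags():
    flags, _ = detect_iqr(np.full(10, 3.0))
    assert not flags.any()


def test_iqr_flags_both_extremes():
    x = np.array([-100, 1, 2, 3, 4, 5, 6, 7, 8, 9, 100.0])
    flags, _ = detect_iqr(x)
    assert flags[0] and flags[-1]
    assert flags.sum() == 2


def test_iqr_tiny_sample_warns_no_flags():
    with pytest.warns(UserWarning):
        flags, _ = detect_iqr(np.array([1.0, 2.0, 3.0]))
    assert not flags.any()


# ---------------------------------------------------------------- z-score


def test_zscore_masking_on_anchor():
    """With one huge value inflating the SD, z stays below 3 (masking)."""
    flags, z = detect_zscore(ANCHOR)
    assert z[-1] == pytest.approx(2.8356, abs=1e-3)
    assert not flags.any()


def test_zscore_flags_clear_outlier():
    x = np.concatenate([np.zeros(19), [10.0]])
    flags, _ = detect_zscore(x)
    assert flags[-1] and flags.sum() == 1


def test_zscore_zero_sd_warns():
    with pytest.warns(UserWarning):
        flags, _ = detect_zscore(np.ones(5))
    assert not flags.any()


# ------------------------------------------------------------------- MAD


def test_mad_hand_oracle_on_anchor():
    flags, ratios = detect_mad(ANCHOR)
    assert ratios[-1] == pytest.approx(37.8)
    assert ratios[0] == pytest.approx(1.8)
    assert flags.tolist() == [False] * 9 + [True]


def test_mad_scale_does_not_change_flags_here():
    f1, _ = detect_mad(ANCHOR, scale=1.0)
    f2, _ = detect_mad(ANCHOR, scale=1.4826)
    assert (f1 == f2).all()


def test_mad_constant_vector_fallback():
    flags, _ = detect_mad(np.full(8, 2.0))
    assert not flags.any()


# ------------------------------------------------------------ Mahalanobis


def test_mahalanobis_centroid_not_flagged():
    rng = np.random.default_rng(0)
    x = rng.standard_normal((30, 3))
    m = pd.DataFrame(np.vstack([x, x.mean(axis=0)]))
    flags, d2, _ = detect_mahalanobis(m)
    assert d2[-1] == pytest.approx(d2.min(), abs=1e-9)


def test_mahalanobis_brute_force_oracle():
    rng = np.random.default_rng(5)
    m = pd.DataFrame(rng.standard_normal((20, 3)))
    _, d2, info = detect_mahalanobis(m)
    x = m.to_numpy()
    inv = np.linalg.inv(np.cov(x, rowvar=False, ddof=1))
    xc = x - x.mean(axis=0)
    expected = np.array([v @ inv @ v for v in xc])
    np.testing.assert_allclose(d2, expected, atol=1e-9)
    assert info["cutoff"] == pytest.approx(stats.chi2.ppf(0.975, 3))


def test_mahalanobis_diagonal_equals_sum_squared_z():
    rng = np.random.default_rng(2)
    x = rng.standard_normal((200, 2)) * np.array([1.0, 5.0])
    m = pd.DataFrame(x)
    _, d2, _ = detect_mahalanobis(m)
    # empirical covariance is not exactly diagonal; use its eigenbasis
    cov = np.cov(x, rowvar=False, ddof=1)
    w, v = np.linalg.eigh(cov)
    z = (x - x.mean(axis=0)) @ v / np.sqrt(w)
    np.testing.assert_allclose(d2, (z**2).sum(axis=1), atol=1e-9)


def test_mahalanobis_planted_extreme_is_only_flag():
    rng = np.random.default_rng(0)
    x = rng.standard_normal((50, 2))
    x[-1] = [10.0, 10.0]
    flags, _, _ = detect_mahalanobis(pd.DataFrame(x))
    assert flags[-1] and flags.sum() == 1


# ------------------------------------------------------------------- LOF


def _brute_force_lof(x: np.ndarray, k: int) -> np.ndarray:
    """Classic LOF with exactly-k (tie-free) neighborhoods."""
    n = x.shape[0]
    d = squareform(pdist(x))
    np.fill_diagonal(d, np.inf)
    nbrs = np.argsort(d, axis=1)[:, :k]
    kdist = np.array([d[i, nbrs[i][-1]] for i in range(n)])
    lrd = np.empty(n)
    for i in range(n):
        reach = np.maximum(kdist[nbrs[i]], d[i, nbrs[i]])
        lrd[i] = 1.0 / reach.mean()
    lof = np.array([lrd[nbrs[i]].mean() / lrd[i] for i in range(n)])
    return lof


def test_lof_matches_brute_force_oracle():
    rng = np.random.default_rng(0)
    x = rng.standard_normal((25, 2))
    _, lof = detect_lof(pd.DataFrame(x), k=5)
    np.testing.assert_allclose(lof, _brute_force_lof(x, 5), atol=1e-9)


def test_lof_grid_interior_near_one():
    xs, ys = np.meshgrid(np.arange(8.0), np.arange(8.0))
    grid = np.column_stack([xs.ravel(), ys.ravel()])
    _, lof = detect_lof(pd.DataFrame(grid), k=8)
    interior = [i for i, (a, b) in enumerate(grid) if 0 < a < 7 and 0 < b < 7]
    assert np.all(np.abs(lof[interior] - 1.0) < 0.2)


def test_lof_isolated_point_has_max_lof_and_flag():
    rng = np.random.default_rng(1)
    pts = np.vstack([
        rng.normal(0, 0.1, (10, 2)),
        rng.normal(5, 0.1, (10, 2)),
        [[50.0, 50.0]],
    ])
    flags, lof = detect_lof(pd.DataFrame(pts), k=5)
    assert np.argmax(lof) == 20
    assert flags[20]


def test_lof_identical_points_all_one():
    _, lof = detect_lof(pd.DataFrame(np.zeros((10, 2))), k=3)
    np.testing.assert_allclose(lof, 1.0, atol=1e-6)


# -------------------------------------------------------- Isolation Forest


def test_iforest_planted_point_max_score_across_seeds():
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((100, 2))
        x[0] = [20.0, 20.0]
        _, score = detect_isolation_forest(pd.DataFrame(x), seed=seed)
        hits += int(np.argmax(score) == 0)
    assert hits >= 19


def test_iforest_deterministic_given_seed():
    rng = np.random.default_rng(0)
    m = pd.DataFrame(rng.standard_normal((50, 3)))
    _, s1 = detect_isolation_forest(m, seed=42)
    _, s2 = detect_isolation_forest(m, seed=42)
    np.testing.assert_array_equal(s1, s2)


# ---------------------------------------------------------------- Grubbs


def test_grubbs_flags_anchor_outlier():
    flags, info = grubbs_test(ANCHOR)
    assert info["G"] == pytest.approx(2.8356, abs=1e-3)
    assert info["G"] > info["critical"]
    assert flags.tolist() == [False] * 9 + [True]


def test_grubbs_symmetric_small_sample_not_significant():
    flags, _ = grubbs_test(np.array([-1.0, 0.0, 1.0]))
    assert not flags.any()


def test_grubbs_constant_vector_no_detection():
    flags, _ = grubbs_test(np.full(10, 1.0))
    assert not flags.any()


# ----------------------------------------------------------------- Dixon


def test_dixon_r11_oracle_on_anchor():
    flags, info = dixon_test(ANCHOR)
    assert info["variant"] == "r11"
    assert info["Q"] == pytest.approx((100 - 9) / (100 - 2), abs=1e-9)
    assert flags[-1] and flags.sum() == 1


def test_dixon_out_of_range_skipped():
    with pytest.warns(UserWarning, match="inapplicable"):
        flags, info = dixon_test(np.arange(31.0))
    assert not flags.any()
    assert not info["applicable"]


def test_dixon_equally_spaced_not_flagged():
    flags, _ = dixon_test(np.array([1.0, 2.0, 3.0]))
    assert not flags.any()


# ---------------------------------------------------------------- Rosner


def test_rosner_recovers_three_planted_shifts():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(30)
    x[[3, 11, 25]] += 10.0
    flags, info = rosner_test(x)
    assert set(np.flatnonzero(flags)) == {3, 11, 25}
    assert info["applicable"]


def test_rosner_null_rarely_flags():
    false_rates = []
    for seed in range(50):
        x = np.random.default_rng(seed).standard_normal(30)
        flags, _ = rosner_test(x)
        false_rates.append(flags.any())
    assert np.mean(false_rates) <= 0.10


def test_rosner_small_sample_skipped():
    with pytest.warns(UserWarning, match="inapplicable"):
        flags, info = rosner_test(np.arange(20.0))
    assert not flags.any() and not info["applicable"]


# ----------------------------------------------------- aggregation & battery


def test_aggregate_any_feature_rule():
    ff = pd.DataFrame({"f1": [True, False, True], "f2": [False, False, True]},
                      index=list("abc"))
    agg = aggregate_to_samples(ff)
    assert agg.tolist() == [True, False, True]


@pytest.mark.parametrize("rescale", [(2.0, 0.0), (0.5, 10.0), (100.0, -3.0)])
def test_univariate_flags_affine_invariant(rescale):
    a, b = rescale
    rng = np.random.default_rng(0)
    x = rng.lognormal(size=40)
    for fn in (detect_iqr, detect_zscore, detect_mad):
        f1 = fn(x)[0]
        f2 = fn(a * x + b)[0]
        assert (f1 == f2).all(), fn.__name__


def test_battery_invariant_to_sample_reordering(small_matrix):
    det1 = detect_all(small_matrix, DetectorParams(seed=0))
    perm = np.random.default_rng(0).permutation(len(small_matrix))
    shuffled = small_matrix.iloc[perm]
    det2 = detect_all(shuffled, DetectorParams(seed=0))
    # deterministic (non-subsampled) methods must commute with reordering
    for meth in ["IQR", "Z", "MAD", "Mahalanobis", "LOF", "Grubbs", "Dixon", "Rosner"]:
        pd.testing.assert_series_equal(
            det1.sample_flags[meth].loc[shuffled.index],
            det2.sample_flags[meth], check_names=False)


def test_battery_bit_reproducible(clinical):
    m, _, _ = clinical
    det1 = detect_all(m, DetectorParams(seed=11))
    det2 = detect_all(m, DetectorParams(seed=11))
    pd.testing.assert_frame_equal(det1.sample_flags, det2.sample_flags)
    for k in det1.scores:
        pd.testing.assert_series_equal(det1.scores[k], det2.scores[k])


def test_battery_applicability_masks(clinical, invitro):
    m93, _, _ = clinical
    det = detect_all(m93)
    assert not det.applicable["Dixon"]          # n=93 outside 3..30
    assert det.applicable["Rosner"]
    assert not det.sample_flags["Dixon"].any()
    m39, _, _ = invitro
    det39 = detect_all(m39)
    assert not det39.applicable["Dixon"]        # n=39 outside 3..30 too
    assert det39.applicable["Rosner"]
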