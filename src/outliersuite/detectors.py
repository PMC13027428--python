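"""The nine outlier detection procedures feeding the consensus vote.

Univariate (per feature): Tukey IQR fences, Z-score, MAD ratio.
Multivariate (per sample): Mahalanobis distance against a chi-square
quantile, Local Outlier Factor, Isolation Forest.
Hypothesis tests (per feature): Grubbs, Dixon's Q, generalized ESD
(Rosner).

Every method is always computed and recorded; the normality gate decides
at consensus time which ones count.  Univariate and test flags are
aggregated to the sample level by the any-feature rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import IsolationForest
from sklearn.neighbors import LocalOutlierFactor

__all__ = [
    "METHODS",
    "DetectorParams",
    "DetectionResult",
    "detect_iqr",
    "detect_zscore",
    "detect_mad",
    "detect_mahalanobis",
    "detect_lof",
    "detect_isolation_forest",
    "test_grubbs",
    "test_dixon",
    "test_rosner",
    "aggregate_to_samples",
    "detect_all",
]

#: Fixed column order of the sample-by-method detection matrix.
METHODS = ["IQR", "Z", "MAD", "Mahalanobis", "LOF", "IsolationForest",
           "Grubbs", "Dixon", "Rosner"]


@dataclass
class DetectorParams:
    """Tunable cutoffs of the detection battery (all logged in outputs)."""

    iqr_k: float = 1.5
    z_cut: float = 3.0
    mad_cut: float = 3.0
    mad_scale: float = 1.0  # 1.4826 gives the Gaussian-consistent MAD
    maha_quantile: float = 0.975
    lof_k: int = 20
    lof_cut: float = 1.5
    iforest_trees: int = 100
    iforest_subsample: int = 256
    iforest_cut: float = 0.6
    test_alpha: float = 0.05
    rosner_max_frac: float = 0.10
    seed: int = 0


# ---------------------------------------------------------------- univariate


def detect_iqr(x: np.ndarray, k: float = 1.5) -> tuple[np.ndarray, dict]:
    """Tukey fences: flag values outside [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear interpolation (type-7).  Needs n >= 4; smaller
    vectors yield no flags and a warning.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        warnings.warn("IQR rule needs n >= 4; no flags")
        return np.zeros(x.size, dtype=bool), {"lo": np.nan, "hi": np.nan}
    q1, q3 = np.quantile(x, [0.25, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    return (x < lo) | (x > hi), {"lo": float(lo), "hi": float(hi), "q1": float(q1), "q3": float(q3)}


def detect_zscore(x: np.ndarray, cut: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """Flag |x - mean| / SD > cut (sample SD, n-1).  SD=0 yields no flags."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1) if x.size > 1 else 0.0
    if sd == 0.0:
        warnings.warn("zero SD: z-score rule yields no flags")
        return np.zeros(x.size, dtype=bool), np.zeros(x.size)
    z = (x - x.mean()) / sd
    return np.abs(z) > cut, z


def detect_mad(x: np.ndarray, cut: float = 3.0, scale: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Flag |x - median| / (scale * MAD) > cut.

    MAD is the raw median absolute deviation (unscaled by default).  When
    MAD = 0 the rule degenerates; any value differing from the median is
    then flagged, with a warning.
    """
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0.0:
        flags = x != med
        if flags.any():
            warnings.warn("MAD = 0: falling back to flagging values != median")
        ratios = np.where(flags, np.inf, 0.0)
        return flags, ratios
    ratios = np.abs(x - med) / (scale * mad)
    return ratios > cut, ratios


# -------------------------------------------------------------- multivariate


def detect_mahalanobis(m: pd.DataFrame, q: float = 0.975) -> tuple[np.ndarray, np.ndarray, dict]:
    """Flag samples whose squared Mahalanobis distance exceeds chi2(q, p).

    The covariance is formed from all samples (ddof=1).  A singular
    covariance is regularized by adding eps*trace/p (eps = 1e-8) to the
    diagonal, which is recorded in the returned info.
    """
    x = m.to_numpy(dtype=float)
    n, p = x.shape
    if p == 0:
        raise ValueError("Mahalanobis distance needs at least one feature")
    center = x.mean(axis=0)
    cov = np.cov(x, rowvar=False, ddof=1).reshape(p, p)
    ridged = False
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        cov = cov + 1e-8 * (np.trace(cov) / p) * np.eye(p)
        ridged = True
    xc = x - center
    d2 = np.einsum("ij,ij->i", xc, np.linalg.solve(cov, xc.T).T)
    cut = float(stats.chi2.ppf(q, df=p))
    return d2 > cut, d2, {"cutoff": cut, "ridged": ridged}


def detect_lof(m: pd.DataFrame, k: int = 20, cut: float = 1.5) -> tuple[np.ndarray, np.ndarray]:
    """Classic Local Outlier Factor on the Euclidean metric; flag LOF > cut.

    k is clamped to n-1 with a warning.  Exact duplicates have LOF 1.
    """
    x = m.to_numpy(dtype=float)
    n = x.shape[0]
    if k >= n:
        warnings.warn(f"LOF k={k} clamped to n-1={n - 1}")
        k = n - 1
    if k < 1:
        raise ValueError("LOF needs n >= 2")
    lof_est = LocalOutlierFactor(n_neighbors=k, metric="euclidean")
    lof_est.fit(x)
    lof = -lof_est.negative_outlier_factor_
    return lof > cut, lof


def detect_isolation_forest(
    m: pd.DataFrame,
    n_trees: int = 100,
    subsample: int = 256,
    cut: float = 0.6,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Isolation Forest anomaly score s(x) = 2^(-E[h(x)]/c(psi)); flag s > cut.

    Fully reproducible given the seed.  A point with average path length
    equal to c(psi) scores exactly 0.5.
    """
    x = m.to_numpy(dtype=float)
    n = x.shape[0]
    forest = IsolationForest(
        n_estimators=n_trees,
        max_samples=min(subsample, n),
        random_state=seed,
    )
    forest.fit(x)
    score = -forest.score_samples(x)
    return score > cut, score


# ----------------------------------------------------------- hypothesis tests


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value from the Student-t quantile."""
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return float((n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t)))


def test_grubbs(x: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, dict]:
    """Two-sided Grubbs test for a single outlier.

    G = max|x - mean|/SD; the argmax observation (lowest index on ties) is
    flagged iff G exceeds the t-based critical value.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    flags = np.zeros(n, dtype=bool)
    if n < 3:
        warnings.warn("Grubbs test needs n >= 3")
        return flags, {"G": np.nan, "critical": np.nan}
    sd = x.std(ddof=1)
    if sd == 0.0:
        return flags, {"G": 0.0, "critical": grubbs_critical(n, alpha)}
    dev = np.abs(x - x.mean()) / sd
    g = float(dev.max())
    crit = grubbs_critical(n, alpha)
    if g > crit:
        flags[int(np.argmax(dev))] = True
    return flags, {"G": g, "critical": crit}


# Two-sided Dixon Q critical values at alpha = 0.05 (Rorabacher 1991),
# indexed by n.  Ratio variant by sample size: r10 (3-7), r11 (8-10),
# r21 (11-13), r22 (14-30).
_DIXON_CRIT_05 = {
    3: 0.970, 4: 0.829, 5: 0.710, 6: 0.628, 7: 0.569,
    8: 0.608, 9: 0.564, 10: 0.530,
    11: 0.619, 12: 0.583, 13: 0.557,
    14: 0.670, 15: 0.637, 16: 0.611, 17: 0.589, 18: 0.571, 19: 0.555,
    20: 0.542, 21: 0.531, 22: 0.521, 23: 0.512, 24: 0.503, 25: 0.496,
    26: 0.489, 27: 0.483, 28: 0.477, 29: 0.472, 30: 0.467,
}


def _dixon_ratios(s: np.ndarray) -> tuple[float, float, str]:
    """Return (low-end ratio, high-end ratio, variant name) for sorted s."""
    n = s.size
    rng = s[-1] - s[0]
    if rng == 0.0:
        return 0.0, 0.0, "r10"

    def safe(num: float, den: float) -> float:
        return num / den if den > 0 else 0.0

    if n <= 7:
        return safe(s[1] - s[0], s[-1] - s[0]), safe(s[-1] - s[-2], s[-1] - s[0]), "r10"
    if n <= 10:
        return safe(s[1] - s[0], s[-2] - s[0]), safe(s[-1] - s[-2], s[-1] - s[1]), "r11"
    if n <= 13:
        return safe(s[2] - s[0], s[-2] - s[0]), safe(s[-1] - s[-3], s[-1] - s[1]), "r21"
    return safe(s[2] - s[0], s[-3] - s[0]), safe(s[-1] - s[-3], s[-1] - s[2]), "r22"


def test_dixon(x: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, dict]:
    """Dixon's Q-test for small samples (3 <= n <= 30).

    Both extremes are tested with the size-appropriate ratio variant; the
    extreme with the larger ratio is flagged when it exceeds the two-sided
    critical value.  Outside 3-30 the method is inapplicable (no flags,
    warning).  Critical values are tabulated for alpha = 0.05 only.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    flags = np.zeros(n, dtype=bool)
    if not 3 <= n <= 30:
        warnings.warn(f"Dixon Q-test inapplicable for n={n} (needs 3-30)")
        return flags, {"Q": np.nan, "critical": np.nan, "applicable": False}
    if alpha != 0.05:
        raise ValueError("Dixon critical values are tabulated for alpha=0.05 only")
    order = np.argsort(x, kind="stable")
    s = x[order]
    q_lo, q_hi, variant = _dixon_ratios(s)
    crit = _DIXON_CRIT_05[n]
    q = max(q_lo, q_hi)
    if q > crit:
        idx = order[-1] if q_hi >= q_lo else order[0]
        flags[idx] = True
    return flags, {"Q": float(q), "critical": crit, "variant": variant, "applicable": True}


def test_rosner(
    x: np.ndarray, alpha: float = 0.05, max_k: int | None = None
) -> tuple[np.ndarray, dict]:
    """Generalized ESD (Rosner) test for up to max_k outliers, n >= 25.

    Iteratively removes the most extreme studentized value and compares
    each R_i with its critical value lambda_i from the Student-t
    distribution; the flagged set is every removal up to the largest i
    with R_i > lambda_i.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    flags = np.zeros(n, dtype=bool)
    if n < 25:
        warnings.warn(f"Rosner test inapplicable for n={n} (needs >= 25)")
        return flags, {"R": [], "lam": [], "applicable": False}
    if max_k is None:
        max_k = int(np.ceil(0.10 * n))
    remaining = np.arange(n)
    removed: list[int] = []
    r_stats: list[float] = []
    lams: list[float] = []
    for i in range(1, max_k + 1):
        vals = x[remaining]
        sd = vals.std(ddof=1)
        if sd == 0.0:
            break
        dev = np.abs(vals - vals.mean()) / sd
        j = int(np.argmax(dev))
        r_stats.append(float(dev[j]))
        removed.append(int(remaining[j]))
        remaining = np.delete(remaining, j)
        ni = n - i + 1  # size before this removal
        p = 1.0 - alpha / (2.0 * ni)
        t = stats.t.ppf(p, ni - 2)
        lam = (ni - 1) * t / np.sqrt((ni - 2 + t * t) * ni)
        lams.append(float(lam))
    last = -1
    for i, (r, lam) in enumerate(zip(r_stats, lams)):
        if r > lam:
            last = i
    for idx in removed[: last + 1]:
        flags[idx] = True
    return flags, {"R": r_stats, "lam": lams, "applicable": True}


# ---------------------------------------------------------------- aggregation


def aggregate_to_samples(feature_flags: pd.DataFrame) -> pd.Series:
    """Any-feature rule: a sample is flagged iff >= 1 feature is flagged."""
    return feature_flags.any(axis=1)


@dataclass
class DetectionResult:
    """Full output of the nine-method battery on one matrix.

    ``sample_flags`` is the binary sample-by-method detection matrix in
    the fixed METHODS column order; ``applicable`` records methods skipped
    for size reasons (Dixon outside 3-30, Rosner below 25), which count as
    non-flags in the consensus.
    """

    sample_flags: pd.DataFrame
    feature_flags: dict[str, pd.DataFrame]
    scores: dict[str, pd.Series]
    applicable: dict[str, bool]
    params: DetectorParams
    notes: list[str] = field(default_factory=list)


def detect_all(m: pd.DataFrame, params: DetectorParams | None = None) -> DetectionResult:
    """Run the full nine-method battery and aggregate to the sample level."""
    params = params or DetectorParams()
    n, p = m.shape
    idx = m.index
    notes: list[str] = []
    feature_flags: dict[str, pd.DataFrame] = {}
    scores: dict[str, pd.Series] = {}
    applicable = {meth: True for meth in METHODS}

    def per_feature(fn) -> tuple[pd.DataFrame, pd.DataFrame]:
        flag_cols, score_cols = {}, {}
        for name in m.columns:
            fl, sc = fn(m[name].to_numpy(dtype=float))
            flag_cols[name] = fl
            score_cols[name] = sc
        return (pd.DataFrame(flag_cols, index=idx),
                pd.DataFrame(score_cols, index=idx))

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        ff, _ = per_feature(lambda x: (detect_iqr(x, params.iqr_k)[0],) * 2)
        feature_flags["IQR"] = ff

        ff, zsc = per_feature(lambda x: detect_zscore(x, params.z_cut))
        feature_flags["Z"] = ff
        scores["Z"] = zsc.abs().max(axis=1)

        ff, msc = per_feature(lambda x: detect_mad(x, params.mad_cut, params.mad_scale))
        feature_flags["MAD"] = ff
        with np.errstate(invalid="ignore"):
            scores["MAD"] = msc.replace(np.inf, np.nan).max(axis=1).fillna(0.0)

        maha_flags, d2, maha_info = detect_mahalanobis(m, params.maha_quantile)
        scores["Mahalanobis"] = pd.Series(d2, index=idx)
        if maha_info["ridged"]:
            notes.append("singular covariance regularized for Mahalanobis distance")

        lof_flags, lof = detect_lof(m, params.lof_k, params.lof_cut)
        scores["LOF"] = pd.Series(lof, index=idx)

        if_flags, if_score = detect_isolation_forest(
            m, params.iforest_trees, params.iforest_subsample, params.iforest_cut, params.seed
        )
        scores["IsolationForest"] = pd.Series(if_score, index=idx)

        ff, _ = per_feature(lambda x: (test_grubbs(x, params.test_alpha)[0],) * 2)
        feature_flags["Grubbs"] = ff

        ff, _ = per_feature(lambda x: (test_dixon(x, params.test_alpha)[0],) * 2)
        feature_flags["Dixon"] = ff
        applicable["Dixon"] = bool(3 <= n <= 30)

        max_k = int(np.ceil(params.rosner_max_frac * n))
        ff, _ = per_feature(lambda x: (test_rosner(x, params.test_alpha, max_k)[0],) * 2)
        feature_flags["Rosner"] = ff
        applicable["Rosner"] = bool(n >= 25)

    notes.extend(str(w.message) for w in caught)

    sample_flags = pd.DataFrame(index=idx)
    for meth in METHODS:
        if meth == "Mahalanobis":
            sample_flags[meth] = maha_flags
        elif meth == "LOF":
            sample_flags[meth] = lof_flags
        elif meth == "IsolationForest":
            sample_flags[meth] = if_flags
        else:
            sample_flags[meth] = aggregate_to_samples(feature_flags[meth])
        if not applicable[meth]:
            sample_flags[meth] = False
    return DetectionResult(
        sample_flags=sample_flags,
        feature_flags=feature_flags,
        scores=scores,
        applicable=applicable,
        params=params,
        notes=notes,
    )
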