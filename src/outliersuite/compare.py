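"""Outlier-vs-normal group comparison: descriptives, rank tests, categorical
association.

Continuous features are compared with the two-sided Mann-Whitney U test
(normal approximation with tie and 0.5 continuity corrections; an exact
permutation mode exists for tiny groups), Benjamini-Hochberg FDR across
the panel, and Rosenthal's r = |Z|/sqrt(N) effect sizes.  Categorical
design factors use the Pearson chi-square (no Yates correction) with phi
or Cramer's V, optionally with a fixed-margins Monte-Carlo p-value or
Fisher's exact test for 2x2 tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "describe_by_group",
    "mann_whitney_panel",
    "effect_size_label",
    "CategoricalAssociation",
    "categorical_association",
]


def describe_by_group(m: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-feature descriptive statistics for the outlier and normal groups.

    Returns one row per feature with mean/SD/median/quartiles/min/max per
    group plus outlier/normal ratio columns for the mean, median and max.
    """
    labels = labels.reindex(m.index)
    groups = {"outlier": m.loc[labels.astype(bool)], "normal": m.loc[~labels.astype(bool)]}
    for name, g in groups.items():
        if g.shape[0] == 0:
            raise ValueError(f"empty {name} group")
    rows = []
    for feat in m.columns:
        row: dict = {"feature": feat}
        for gname, g in groups.items():
            x = g[feat].to_numpy(dtype=float)
            row[f"{gname}_mean"] = x.mean()
            row[f"{gname}_sd"] = x.std(ddof=1) if x.size > 1 else 0.0
            row[f"{gname}_median"] = np.median(x)
            row[f"{gname}_q1"], row[f"{gname}_q3"] = np.quantile(x, [0.25, 0.75])
            row[f"{gname}_min"], row[f"{gname}_max"] = x.min(), x.max()
        for stat in ("mean", "median", "max"):
            denom = row[f"normal_{stat}"]
            row[f"{stat}_ratio"] = row[f"outlier_{stat}"] / denom if denom != 0 else np.inf
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature")


def effect_size_label(r: float) -> str:
    """Magnitude label for Rosenthal's r (|r| cutoffs 0.1 / 0.3 / 0.5)."""
    a = abs(r)
    if a >= 0.5:
        return "large"
    if a >= 0.3:
        return "medium"
    if a >= 0.1:
        return "small-to-medium"
    return "small"


def _mann_whitney_normal_approx(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """U (for the first group), z and two-sided p with tie + continuity
    correction."""
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return float(u1), 0.0, 1.0
    num = u1 - mu
    num -= 0.5 * np.sign(num)  # continuity correction toward the mean
    z = num / np.sqrt(var)
    return float(u1), float(z), float(2.0 * stats.norm.sf(abs(z)))


def mann_whitney_panel(
    m: pd.DataFrame,
    labels: pd.Series,
    alpha: float = 0.05,
    mode: str = "asymptotic",
) -> pd.DataFrame:
    """Mann-Whitney U panel across all features with BH FDR adjustment.

    ``mode='exact'`` uses the exhaustive permutation distribution (scipy),
    appropriate for tiny tie-free groups; the default asymptotic mode is
    the continuity- and tie-corrected normal approximation.  All-tied
    features are reported degenerate with p = 1 and r = 0.
    """
    labels = labels.reindex(m.index).astype(bool)
    xg, yg = m.loc[labels], m.loc[~labels]
    if xg.shape[0] < 2 or yg.shape[0] < 2:
        raise ValueError("each group needs at least 2 samples")
    n = m.shape[0]
    rows = []
    for feat in m.columns:
        x = xg[feat].to_numpy(dtype=float)
        y = yg[feat].to_numpy(dtype=float)
        if np.ptp(np.concatenate([x, y])) == 0.0:
            rows.append(dict(feature=feat, U=x.size * y.size / 2.0, z=0.0,
                             p_raw=1.0, r=0.0, degenerate=True))
            continue
        if mode == "exact":
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            u, p = float(res.statistic), float(res.pvalue)
            z = float(stats.norm.isf(min(p / 2.0, 0.5)))  # |z| equivalent
        else:
            u, z, p = _mann_whitney_normal_approx(x, y)
        r = abs(z) / np.sqrt(n)
        rows.append(dict(feature=feat, U=u, z=z, p_raw=p, r=r, degenerate=False))
    table = pd.DataFrame(rows).set_index("feature")
    table["p_adj"] = multipletests(table["p_raw"].to_numpy(), method="fdr_bh")[1]
    table["significant"] = table["p_adj"] < alpha
    table["magnitude"] = table["r"].map(effect_size_label)
    return table


@dataclass
class CategoricalAssociation:
    table: pd.DataFrame
    chi2: float
    df: int
    p_value: float
    mode: str
    effect_size: float
    effect_name: str  # "phi" for 2x2, "cramers_v" otherwise
    min_expected: float


def categorical_association(
    tbl,
    mode: str = "asymptotic",
    n_resamples: int = 10_000,
    seed: int = 0,
) -> CategoricalAssociation:
    """Pearson chi-square association for a contingency table of counts.

    phi = sqrt(chi2/n) for 2x2 tables, Cramer's V otherwise.  Monte-Carlo
    p-values resample tables with both margins fixed; ``mode='fisher'``
    runs Fisher's exact test (2x2 only) while still reporting the Pearson
    chi-square statistic and effect size.
    """
    table = pd.DataFrame(tbl)
    counts = table.to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValueError("negative counts")
    n = counts.sum()
    if n <= 0:
        raise ValueError("empty contingency table")
    row_m, col_m = counts.sum(axis=1), counts.sum(axis=0)
    if (row_m == 0).any():
        raise ValueError(f"zero row margin at row {int(np.flatnonzero(row_m == 0)[0])}")
    if (col_m == 0).any():
        raise ValueError(f"zero column margin at column {int(np.flatnonzero(col_m == 0)[0])}")
    expected = np.outer(row_m, col_m) / n
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    if counts.shape == (2, 2):
        effect, ename = float(np.sqrt(chi2 / n)), "phi"
    else:
        k = min(counts.shape[0] - 1, counts.shape[1] - 1)
        effect, ename = float(np.sqrt(chi2 / (n * k))), "cramers_v"
    if mode == "asymptotic":
        p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    elif mode == "monte_carlo":
        rng = np.random.default_rng(seed)
        sampler = stats.random_table(row_m.astype(int), col_m.astype(int))
        sims = sampler.rvs(n_resamples, random_state=rng)
        sim_chi2 = ((sims - expected) ** 2 / expected).sum(axis=(1, 2))
        p = float((1 + np.sum(sim_chi2 >= chi2 - 1e-12)) / (1 + n_resamples))
    elif mode == "fisher":
        if counts.shape != (2, 2):
            raise ValueError("Fisher's exact test requires a 2x2 table")
        p = float(stats.fisher_exact(counts)[1])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return CategoricalAssociation(
        table=table, chi2=chi2, df=df, p_value=p, mode=mode,
        effect_size=effect, effect_name=ename, min_expected=float(expected.min()),
    )
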