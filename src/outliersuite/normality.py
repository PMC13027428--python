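"""Per-variable normality assessment gating the consensus rule.

Each feature is tested with Shapiro-Wilk and Anderson-Darling.  The
dataset-level gate is the fraction-of-variables rule: the cohort counts as
Gaussian when at least ``gate_fraction`` of features pass both tests at
``alpha``.  Parametric detectors (Z-score, Mahalanobis) only join the
consensus vote when this gate passes.  An optional Mardia-style skewness
test of joint multivariate normality is exposed for diagnostics but does
not drive the gate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import normal_ad

__all__ = ["NormalityReport", "assess_normality", "mardia_skewness_test"]


@dataclass
class NormalityReport:
    per_feature: pd.DataFrame  # columns: shapiro_w, shapiro_p, ad_stat, ad_p, parametric
    gaussian_fraction: float
    parametric_features: list[str]
    dataset_gaussian: bool
    alpha: float
    gate_fraction: float
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "gaussian_fraction": self.gaussian_fraction,
            "dataset_gaussian": self.dataset_gaussian,
            "parametric_features": self.parametric_features,
            "alpha": self.alpha,
            "gate_fraction": self.gate_fraction,
            "per_feature": self.per_feature.round(6).to_dict(orient="index"),
            "warnings": self.warnings,
        }


def assess_normality(
    m: pd.DataFrame, alpha: float = 0.05, gate_fraction: float = 0.05
) -> NormalityReport:
    """Assess per-feature and dataset-level normality.

    A feature is "Gaussian" when both the Shapiro-Wilk and the
    Anderson-Darling p-value are >= ``alpha``; per-feature parametric
    eligibility uses the Shapiro-Wilk p alone.  With fewer than 8 samples
    the tests are unstable and every feature is marked non-parametric with
    a warning.  Constant features are non-parametric by definition.
    """
    notes: list[str] = []
    n = m.shape[0]
    rows = {}
    too_small = n < 8
    if too_small:
        notes.append(f"n={n} < 8: normality tests unstable, all features non-parametric")
        warnings.warn(notes[-1])
    for name in m.columns:
        x = m[name].to_numpy(dtype=float)
        if too_small or np.ptp(x) == 0.0:
            rows[name] = dict(shapiro_w=np.nan, shapiro_p=0.0, ad_stat=np.nan, ad_p=0.0,
                              parametric=False)
            if not too_small:
                notes.append(f"constant feature {name!r} marked non-parametric")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w, sw_p = stats.shapiro(x)
            ad_stat, ad_p = normal_ad(x)
        rows[name] = dict(
            shapiro_w=float(w),
            shapiro_p=float(sw_p),
            ad_stat=float(ad_stat),
            ad_p=float(np.clip(ad_p, 0.0, 1.0)),
            parametric=bool(sw_p >= alpha),
        )
    per_feature = pd.DataFrame.from_dict(rows, orient="index")
    both_pass = (per_feature["shapiro_p"] >= alpha) & (per_feature["ad_p"] >= alpha)
    gaussian_fraction = float(both_pass.mean()) if len(per_feature) else 0.0
    return NormalityReport(
        per_feature=per_feature,
        gaussian_fraction=gaussian_fraction,
        parametric_features=per_feature.index[per_feature["parametric"]].tolist(),
        dataset_gaussian=bool(gaussian_fraction >= gate_fraction),
        alpha=alpha,
        gate_fraction=gate_fraction,
        warnings=notes,
    )


def mardia_skewness_test(m: pd.DataFrame) -> tuple[float, float]:
    """Mardia's multivariate skewness statistic and asymptotic chi2 p-value."""
    x = m.to_numpy(dtype=float)
    n, p = x.shape
    xc = x - x.mean(axis=0)
    cov = np.cov(x, rowvar=False, ddof=1) + 1e-12 * np.eye(p)
    inv = np.linalg.inv(cov)
    g = xc @ inv @ xc.T
    b1 = float((g**3).sum()) / n**2
    stat = n * b1 / 6.0
    df = p * (p + 1) * (p + 2) / 6.0
    return stat, float(stats.chi2.sf(stat, df))
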