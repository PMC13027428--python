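"""Supervised prediction of consensus outlier status and bootstrap
stability of the detection pipeline.

A random-forest classifier (Gini splits, sqrt(p) features per split) is
trained on a stratified hold-out split; performance is summarized by the
confusion matrix, derived metrics and a rank-statistic AUC over the
out-of-sample vote fractions.  Bootstrap stability reruns the complete
gate -> detectors -> consensus pipeline on resampled cohorts and reports,
per sample, the fraction of resamples containing it in which it was
re-flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .consensus import apply_consensus
from .detectors import DetectorParams, detect_all
from .normality import assess_normality

__all__ = [
    "RFConfig",
    "RFReport",
    "train_classifier",
    "classification_metrics",
    "StabilityReport",
    "bootstrap_stability",
]

MIN_MINORITY_CLASS = 8


@dataclass
class RFConfig:
    """Random-forest hyperparameters (ensemble kept deliberately small for
    a cohort of ~100 samples)."""

    n_trees: int = 50
    max_depth: int = 7
    min_split: int = 3
    min_leaf: int = 1
    test_fraction: float = 0.20
    seed: int = 0


@dataclass
class RFReport:
    confusion: dict[str, int]          # TN, FP, FN, TP on the test set
    metrics: dict[str, float | None]
    auc: float
    importances: pd.Series             # Gini importances, sum 1
    test_index: list
    config: RFConfig


def classification_metrics(tn: int, fp: int, fn: int, tp: int) -> dict[str, float | None]:
    """Accuracy, precision, recall, specificity from confusion counts.

    Undefined ratios (zero denominator) are reported as None.
    """
    total = tn + fp + fn + tp
    if total <= 0:
        raise ValueError("empty confusion matrix")
    if min(tn, fp, fn, tp) < 0:
        raise ValueError("negative counts")

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return {
        "accuracy": (tp + tn) / total,
        "precision": ratio(tp, tp + fp),
        "recall": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
    }


def _rank_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """AUC as the Mann-Whitney rank statistic with midranks for ties."""
    pos, neg = scores[truth], scores[~truth]
    if pos.size == 0 or neg.size == 0:
        return np.nan
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def train_classifier(
    features: pd.DataFrame, labels: pd.Series, cfg: RFConfig | None = None
) -> RFReport:
    """Train and evaluate the outlier-status random forest.

    Refuses to train when the minority class has fewer than 8 samples:
    a supervised model fit on so few positives would memorize them
    rather than learn generalizable structure.
    """
    cfg = cfg or RFConfig()
    y = labels.reindex(features.index).astype(bool)
    counts = y.value_counts()
    if len(counts) < 2:
        raise ValueError("labels contain a single class")
    if counts.min() < MIN_MINORITY_CLASS:
        raise ValueError(
            f"minority class has {int(counts.min())} samples (< {MIN_MINORITY_CLASS}): "
            "supervised modeling refused to avoid extreme overfitting"
        )
    if features.shape[0] < 20:
        raise ValueError("training needs n >= 20")
    x_train, x_test, y_train, y_test = train_test_split(
        features, y, test_size=cfg.test_fraction, stratify=y, random_state=cfg.seed
    )
    forest = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_depth=cfg.max_depth,
        min_samples_split=cfg.min_split,
        min_samples_leaf=cfg.min_leaf,
        max_features="sqrt",
        criterion="gini",
        random_state=cfg.seed,
    )
    forest.fit(x_train.to_numpy(), y_train.to_numpy())
    pred = forest.predict(x_test.to_numpy())
    votes = forest.predict_proba(x_test.to_numpy())[:, list(forest.classes_).index(True)]
    truth = y_test.to_numpy()
    tn = int(np.sum(~truth & ~pred))
    fp = int(np.sum(~truth & pred))
    fn = int(np.sum(truth & ~pred))
    tp = int(np.sum(truth & pred))
    importances = pd.Series(forest.feature_importances_, index=features.columns)
    total = importances.sum()
    if total > 0:
        importances = importances / total
    return RFReport(
        confusion={"TN": tn, "FP": fp, "FN": fn, "TP": tp},
        metrics=classification_metrics(tn, fp, fn, tp),
        auc=_rank_auc(votes, truth),
        importances=importances.sort_values(ascending=False),
        test_index=list(x_test.index),
        config=cfg,
    )


@dataclass
class StabilityReport:
    per_sample: pd.DataFrame   # presence, flagged, stability per sample
    mean_stability: float
    n_iterations: int
    seed: int
    notes: list[str] = field(default_factory=list)


def bootstrap_stability(
    m: pd.DataFrame,
    params: DetectorParams | None = None,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    gate_fraction: float = 0.05,
    pipeline=None,
) -> StabilityReport:
    """Bootstrap detection stability of the full consensus pipeline.

    Each iteration draws n samples with replacement, reruns the normality
    gate, the nine detectors and the consensus vote, and records which
    original samples were re-flagged.  A sample's stability is
    flagged/presence, conditioned on the iterations in which it appears at
    least once (duplicated draws count once); the cohort mean is taken
    over samples with presence >= 1.  ``pipeline`` may override the
    per-iteration labeling function (matrix -> boolean array), which the
    tests use to inject stubs.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    params = params or DetectorParams()
    n = m.shape[0]
    rng = np.random.default_rng(seed)

    def default_pipeline(sub: pd.DataFrame) -> np.ndarray:
        gate = assess_normality(sub, alpha=alpha, gate_fraction=gate_fraction)
        det = detect_all(sub, params)
        return apply_consensus(det.sample_flags, gate).labels.to_numpy()

    label_fn = pipeline or default_pipeline
    presence = np.zeros(n, dtype=int)
    flagged = np.zeros(n, dtype=int)
    x = m.to_numpy(dtype=float)
    for _ in range(B):
        draw = rng.integers(0, n, size=n)
        sub = pd.DataFrame(x[draw], columns=m.columns,
                           index=pd.RangeIndex(n))
        labels = np.asarray(label_fn(sub), dtype=bool)
        seen = np.unique(draw)
        presence[seen] += 1
        hit = np.zeros(n, dtype=bool)
        for pos, orig in enumerate(draw):
            if labels[pos]:
                hit[orig] = True
        flagged[hit] += 1
    with np.errstate(invalid="ignore"):
        stability = np.where(presence > 0, flagged / np.maximum(presence, 1), np.nan)
    per_sample = pd.DataFrame(
        {"presence": presence, "flagged": flagged, "stability": stability},
        index=m.index,
    )
    mean_stab = float(np.nanmean(stability)) if np.any(presence > 0) else np.nan
    return StabilityReport(
        per_sample=per_sample, mean_stability=mean_stab, n_iterations=B, seed=seed
    )
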