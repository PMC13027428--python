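"""Adaptive consensus voting over the nine-method detection matrix.

A sample is a final outlier iff it satisfies at least one criterion:

* C1 (high confidence): flagged by any hypothesis test (Grubbs, Dixon,
  Rosner).
* C2: flagged by at least two univariate non-parametric methods.  With
  only IQR and MAD in the pool this means both; when the normality gate
  passes, Z-score joins the pool and any 2 of {IQR, MAD, Z} suffice.
* C3: flagged by at least one multivariate non-parametric method (LOF or
  Isolation Forest); when the gate passes, Mahalanobis joins this pool.

Methods inapplicable for size reasons count as non-flags, never vetoes.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .detectors import METHODS
from .normality import NormalityReport

__all__ = ["ConsensusResult", "apply_consensus", "consensus_vote", "summarize_convergence"]

_TEST_POOL = ("Grubbs", "Dixon", "Rosner")
_MULTI_POOL = ("LOF", "IsolationForest")


@dataclass
class ConsensusResult:
    labels: pd.Series            # bool per sample, True = outlier
    criteria: pd.DataFrame       # per sample: C1, C2, C3 booleans
    votes: pd.Series             # number of flagging methods per sample
    prevalence: float
    gate_passed: bool

    @property
    def n_outliers(self) -> int:
        return int(self.labels.sum())


def consensus_vote(flags: dict[str, bool], use_parametric: bool) -> tuple[bool, bool, bool]:
    """Evaluate (C1, C2, C3) for one sample's method flags."""
    c1 = any(flags[m] for m in _TEST_POOL)
    uni_pool = ["IQR", "MAD"] + (["Z"] if use_parametric else [])
    c2 = sum(flags[m] for m in uni_pool) >= 2
    multi_pool = list(_MULTI_POOL) + (["Mahalanobis"] if use_parametric else [])
    c3 = any(flags[m] for m in multi_pool)
    return c1, c2, c3


def apply_consensus(dm: pd.DataFrame, gate: NormalityReport | bool) -> ConsensusResult:
    """Convert the binary sample-by-method matrix into final outlier labels.

    ``gate`` may be a NormalityReport (its ``dataset_gaussian`` decides
    whether parametric methods join the pools) or a plain boolean.
    """
    missing = [m for m in METHODS if m not in dm.columns]
    if missing:
        raise ValueError(f"detection matrix missing method columns: {missing}")
    use_parametric = gate.dataset_gaussian if isinstance(gate, NormalityReport) else bool(gate)
    crit_rows = {}
    for sample, row in dm.iterrows():
        crit_rows[sample] = consensus_vote(row.to_dict(), use_parametric)
    criteria = pd.DataFrame.from_dict(crit_rows, orient="index", columns=["C1", "C2", "C3"])
    criteria = criteria.loc[dm.index]
    labels = criteria.any(axis=1)
    votes = dm[METHODS].sum(axis=1).astype(int)
    return ConsensusResult(
        labels=labels,
        criteria=criteria,
        votes=votes,
        prevalence=float(labels.mean()),
        gate_passed=use_parametric,
    )


def summarize_convergence(dm: pd.DataFrame, cr: ConsensusResult,
                          high_overlap: int = 5) -> dict:
    """Convergence table: per-method counts, criterion contributions,
    high-overlap samples (flagged by >= ``high_overlap`` methods) and
    prevalence (as a percentage, one decimal)."""
    per_method = dm[METHODS].sum(axis=0).astype(int).to_dict()
    per_criterion = cr.criteria.sum(axis=0).astype(int).to_dict()
    votes = dm[METHODS].sum(axis=1)
    return {
        "n_samples": int(dm.shape[0]),
        "n_outliers": cr.n_outliers,
        "prevalence_percent": round(100.0 * cr.prevalence, 1),
        "per_method_detections": per_method,
        "per_criterion_contributions": per_criterion,
        "high_overlap_samples": votes.index[votes >= high_overlap].tolist(),
        "gate_passed": cr.gate_passed,
    }
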