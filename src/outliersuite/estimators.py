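"""scikit-learn style estimators wrapping the detection and projection
stages, so they compose with sklearn pipelines and model selection.

``ConsensusOutlierDetector`` bundles the normality gate, the nine-method
battery and the adaptive consensus vote into one fit/fit_predict
estimator; ``RobustPCA`` exposes the grid-search projection pursuit as a
transformer.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, OutlierMixin, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from . import rpca
from .consensus import apply_consensus, summarize_convergence
from .detectors import DetectorParams, detect_all
from .normality import assess_normality

__all__ = ["ConsensusOutlierDetector", "RobustPCA"]


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        check_array(X.to_numpy(dtype=float))
        return X
    arr = check_array(X)
    return pd.DataFrame(arr, columns=[f"x{j}" for j in range(arr.shape[1])])


class ConsensusOutlierDetector(OutlierMixin, BaseEstimator):
    """Normality-gated multi-algorithm consensus outlier detector.

    Parameters mirror :class:`~outliersuite.detectors.DetectorParams`
    plus the gate settings.  After ``fit`` the estimator exposes:

    ``labels_`` : boolean outlier labels (sklearn convention: ``predict``
    returns -1 for outliers, +1 for inliers).
    ``detection_matrix_`` : the binary sample-by-method matrix.
    ``criteria_`` : per-sample satisfied consensus criteria (C1..C3).
    ``votes_`` : number of flagging methods per sample.
    ``normality_report_``, ``prevalence_``, ``convergence_``.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        gate_fraction: float = 0.05,
        iqr_k: float = 1.5,
        z_cut: float = 3.0,
        mad_cut: float = 3.0,
        mad_scale: float = 1.0,
        maha_quantile: float = 0.975,
        lof_k: int = 20,
        lof_cut: float = 1.5,
        iforest_trees: int = 100,
        iforest_cut: float = 0.6,
        test_alpha: float = 0.05,
        random_state: int = 0,
    ):
        self.alpha = alpha
        self.gate_fraction = gate_fraction
        self.iqr_k = iqr_k
        self.z_cut = z_cut
        self.mad_cut = mad_cut
        self.mad_scale = mad_scale
        self.maha_quantile = maha_quantile
        self.lof_k = lof_k
        self.lof_cut = lof_cut
        self.iforest_trees = iforest_trees
        self.iforest_cut = iforest_cut
        self.test_alpha = test_alpha
        self.random_state = random_state

    def _detector_params(self) -> DetectorParams:
        return DetectorParams(
            iqr_k=self.iqr_k, z_cut=self.z_cut, mad_cut=self.mad_cut,
            mad_scale=self.mad_scale, maha_quantile=self.maha_quantile,
            lof_k=self.lof_k, lof_cut=self.lof_cut,
            iforest_trees=self.iforest_trees, iforest_cut=self.iforest_cut,
            test_alpha=self.test_alpha, seed=self.random_state,
        )

    def fit(self, X, y=None):
        m = _as_frame(X)
        self.normality_report_ = assess_normality(
            m, alpha=self.alpha, gate_fraction=self.gate_fraction
        )
        self.detection_ = detect_all(m, self._detector_params())
        self.detection_matrix_ = self.detection_.sample_flags
        result = apply_consensus(self.detection_matrix_, self.normality_report_)
        self.consensus_ = result
        self.labels_ = result.labels
        self.criteria_ = result.criteria
        self.votes_ = result.votes
        self.prevalence_ = result.prevalence
        self.convergence_ = summarize_convergence(self.detection_matrix_, result)
        self.n_features_in_ = m.shape[1]
        return self

    def fit_predict(self, X, y=None):
        self.fit(X)
        return np.where(self.labels_.to_numpy(), -1, 1)

    def predict(self, X=None):
        """Labels of the fitted cohort (the consensus is transductive)."""
        check_is_fitted(self, "labels_")
        return np.where(self.labels_.to_numpy(), -1, 1)


class RobustPCA(TransformerMixin, BaseEstimator):
    """Grid-search projection-pursuit robust PCA as a sklearn transformer.

    Fitted attributes: ``components_`` (k x p), ``explained_variance_ratio_``
    (robust, relative to all p components), ``center_`` (per-feature
    median), ``scores_`` for the training data.
    """

    def __init__(self, n_components: int | None = None, scale_estimator: str = "MAD",
                 n_angles: int = 10, n_sweeps: int = 10):
        self.n_components = n_components
        self.scale_estimator = scale_estimator
        self.n_angles = n_angles
        self.n_sweeps = n_sweeps

    def fit(self, X, y=None):
        m = _as_frame(X)
        self.model_ = rpca.fit_robust_pca(
            m, k=self.n_components, scale_estimator=self.scale_estimator,
            n_angles=self.n_angles, n_sweeps=self.n_sweeps,
        )
        self.components_ = self.model_.loadings.to_numpy().T
        self.explained_variance_ratio_ = self.model_.explained_fraction
        self.center_ = self.model_.center.to_numpy()
        self.scores_ = self.model_.scores
        self.feature_names_in_ = np.asarray(self.model_.loadings.index)
        self.n_features_in_ = self.components_.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "model_")
        m = _as_frame(X)
        if m.shape[1] != self.n_features_in_:
            raise ValueError("feature dimension mismatch")
        if list(m.columns) != list(self.model_.loadings.index):
            m = pd.DataFrame(m.to_numpy(), index=m.index,
                             columns=self.model_.loadings.index)
        return rpca.project(self.model_, m).to_numpy()
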