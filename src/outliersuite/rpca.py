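"""Projection-pursuit robust PCA via sequential grid search.

Components are unit directions maximizing a robust scale (MAD by default,
made consistent at the normal with the 1.4826 factor) of the projected,
median-centered data.  The search follows the grid-algorithm idea:
starting from the best coordinate axis, the candidate direction is
iteratively rotated inside the plane it spans with each basis vector,
scanning a grid of angles whose span is halved on every refinement sweep.
After each component the data space is deflated to the orthogonal
complement.  Robust "eigenvalues" are the squared robust scales of the
component projections; explained fractions are relative to their total
over all components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RobustPCAModel", "fit_robust_pca", "project"]

_MAD_CONSISTENCY = 1.4826022185056018


@dataclass
class RobustPCAModel:
    loadings: pd.DataFrame            # features x k, orthonormal columns
    robust_eigenvalues: np.ndarray    # squared robust scale per component (all p)
    explained_fraction: np.ndarray    # per retained component
    center: pd.Series                 # per-feature median used for centering
    scores: pd.DataFrame              # samples x k
    scale_estimator: str
    n_components: int


def _scale(y: np.ndarray, estimator: str) -> float:
    if estimator == "MAD":
        return _MAD_CONSISTENCY * float(np.median(np.abs(y - np.median(y))))
    if estimator == "SD":
        return float(y.std(ddof=1))
    raise ValueError(f"unknown scale estimator {estimator!r}")


def _pursue_direction(y: np.ndarray, estimator: str, n_angles: int, n_sweeps: int) -> np.ndarray:
    """Best unit direction for the projected data ``y`` (n x q)."""
    q = y.shape[1]
    if q == 1:
        return np.ones(1)
    col_scales = [_scale(y[:, i], estimator) for i in range(q)]
    a = np.zeros(q)
    a[int(np.argmax(col_scales))] = 1.0
    best = _scale(y @ a, estimator)
    for sweep in range(n_sweeps):
        half_span = (np.pi / 2.0) * 0.5**sweep
        angles = np.linspace(-half_span, half_span, n_angles)
        # repeated coordinate-plane passes at each scale until no improvement
        for _ in range(3):
            improved = False
            for i in range(q):
                e = np.zeros(q)
                e[i] = 1.0
                # rotate inside span(a, e_i); skip if e_i ~ parallel to a
                ortho = e - a[i] * a
                norm = np.linalg.norm(ortho)
                if norm < 1e-12:
                    continue
                ortho /= norm
                ya, yo = y @ a, y @ ortho
                vals = [
                    _scale(np.cos(t) * ya + np.sin(t) * yo, estimator) for t in angles
                ]
                j = int(np.argmax(vals))
                if vals[j] > best + 1e-15:
                    best = vals[j]
                    t = angles[j]
                    a = np.cos(t) * a + np.sin(t) * ortho
                    a /= np.linalg.norm(a)
                    improved = True
            if not improved:
                break
    return a


def fit_robust_pca(
    m: pd.DataFrame,
    k: int | None = None,
    scale_estimator: str = "MAD",
    n_angles: int = 10,
    n_sweeps: int = 10,
) -> RobustPCAModel:
    """Fit the grid-search robust PCA on a (standardized) feature matrix.

    ``k`` components are retained (default min(n-1, p)); all p directions
    are pursued so explained fractions are relative to the full robust
    dispersion.  Component signs are fixed by making the largest-magnitude
    loading positive.
    """
    x = m.to_numpy(dtype=float)
    n, p = x.shape
    k = min(n - 1, p) if k is None else k
    if k > min(n - 1, p):
        raise ValueError(f"k={k} exceeds min(n-1, p)={min(n - 1, p)}")
    if k < 1:
        raise ValueError("k must be >= 1")
    center = np.median(x, axis=0)
    xc = x - center
    basis = np.eye(p)  # columns span the current complement
    directions = np.zeros((p, p))
    eigenvalues = np.zeros(p)
    for j in range(p):
        y = xc @ basis
        a = _pursue_direction(y, scale_estimator, n_angles, n_sweeps)
        d = basis @ a
        d /= np.linalg.norm(d)
        if d[np.argmax(np.abs(d))] < 0:
            d = -d
        directions[:, j] = d
        eigenvalues[j] = _scale(xc @ d, scale_estimator) ** 2
        if basis.shape[1] > 1:
            a_unit = a / np.linalg.norm(a)
            qmat, _ = np.linalg.qr(
                np.column_stack([a_unit, np.eye(basis.shape[1])])
            )
            basis = basis @ qmat[:, 1:basis.shape[1]]
        else:
            basis = basis[:, :0]
    order = np.argsort(eigenvalues)[::-1]
    directions, eigenvalues = directions[:, order], eigenvalues[order]
    total = eigenvalues.sum()
    explained = eigenvalues / total if total > 0 else np.zeros(p)
    loadings = pd.DataFrame(
        directions[:, :k], index=m.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
    center_s = pd.Series(center, index=m.columns)
    scores = pd.DataFrame(
        xc @ directions[:, :k], index=m.index, columns=loadings.columns
    )
    return RobustPCAModel(
        loadings=loadings,
        robust_eigenvalues=eigenvalues,
        explained_fraction=explained[:k],
        center=center_s,
        scores=scores,
        scale_estimator=scale_estimator,
        n_components=k,
    )


def project(model: RobustPCAModel, m: pd.DataFrame) -> pd.DataFrame:
    """Project new samples onto the fitted components."""
    if list(m.columns) != list(model.loadings.index):
        raise ValueError("feature sets of the model and the matrix do not match")
    xc = m.to_numpy(dtype=float) - model.center.to_numpy()
    return pd.DataFrame(
        xc @ model.loadings.to_numpy(), index=m.index, columns=model.loadings.columns
    )
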