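"""Nonmetric multidimensional scaling (NMDS) of census count matrices.

Units-by-species (or units-by-DT) count matrices are converted to
Euclidean distances and embedded in k dimensions by minimizing Kruskal
stress-1, with the disparity function fit by monotone (isotonic)
regression on the observed dissimilarity order.  The best configuration
over multiple restarts is kept: restart 0 starts from a classical
(Torgerson) metric-MDS solution, later restarts from random Gaussian
configurations.  The returned scores are centered and rotated to their
principal axes so that repeated runs are directly comparable (NMDS axes
are otherwise arbitrary up to rotation/reflection).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import smacof


@dataclass
class OrdinationResult:
    """NMDS scores and fit diagnostics."""

    site_scores: pd.DataFrame
    stress: float
    n_restarts: int
    seed: int
    converged: bool


def distance_matrix(matrix: pd.DataFrame, metric: str = "euclidean") -> pd.DataFrame:
    """Symmetric unit-to-unit distance table from a count matrix."""
    if metric != "euclidean":
        raise ValueError(f"unsupported metric {metric!r}")
    if matrix.shape[0] < 2:
        raise ValueError("need at least two units for a distance matrix")
    d = squareform(pdist(matrix.to_numpy(dtype=float), metric="euclidean"))
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


def _classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    """Torgerson metric-MDS embedding used to seed restart 0."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    vals_k = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals_k)


def _principal_axes(x: np.ndarray) -> np.ndarray:
    """Center and rotate a configuration onto its principal axes.

    Axis signs are fixed by making the largest-magnitude loading on each
    axis positive, so reflections are also deterministic.
    """
    x = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    y = x @ vt.T
    for col in range(y.shape[1]):
        i = np.argmax(np.abs(y[:, col]))
        if y[i, col] < 0:
            y[:, col] = -y[:, col]
    return y


def nmds(
    distances: pd.DataFrame,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int = 0,
) -> OrdinationResult:
    """Minimize Kruskal stress-1 over ``n_restarts`` initializations.

    Non-convergence is flagged, not raised; the best configuration found
    is always returned.
    """
    d = distances.to_numpy(dtype=float)
    n = d.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of units ({n})")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("distance table must be symmetric with a zero diagonal")

    rng = np.random.default_rng(seed)
    best_pos: np.ndarray | None = None
    best_stress = np.inf
    best_iter = max_iter
    for restart in range(n_restarts):
        if restart == 0:
            init = _classical_mds(d, k)
        else:
            init = rng.normal(size=(n, k))
        pos, stress, n_iter = smacof(
            d, metric=False, n_components=k, init=init, n_init=1,
            max_iter=max_iter, eps=tol, normalized_stress=True,
            return_n_iter=True,
        )
        if stress < best_stress:
            best_stress, best_pos, best_iter = float(stress), pos, n_iter
    assert best_pos is not None

    scores = _principal_axes(best_pos)
    axes = [f"NMDS{i + 1}" for i in range(k)]
    return OrdinationResult(
        site_scores=pd.DataFrame(scores, index=distances.index, columns=axes),
        stress=best_stress,
        n_restarts=n_restarts,
        seed=seed,
        converged=best_iter < max_iter,
    )


def variable_scores(
    site_scores: pd.DataFrame, matrix: pd.DataFrame
) -> pd.DataFrame:
    """Place each variable at the abundance-weighted mean of site scores.

    Variables absent from every unit get NaN coordinates (an explicit
    absent flag rather than an arbitrary position).
    """
    if list(site_scores.index) != list(matrix.index):
        raise ValueError("site_scores and matrix must share unit labels in order")
    w = matrix.to_numpy(dtype=float)
    totals = w.sum(axis=0)
    out = np.full((matrix.shape[1], site_scores.shape[1]), np.nan)
    present = totals > 0
    out[present] = (w[:, present].T @ site_scores.to_numpy()) / totals[present, None]
    return pd.DataFrame(out, index=matrix.columns, columns=site_scores.columns)


def kruskal_stress(distances: pd.DataFrame, scores: pd.DataFrame) -> float:
    """Recompute stress-1 for a given configuration (diagnostic).

    Uses isotonic regression of configuration distances on the rank order
    of the input dissimilarities, matching the objective minimized by
    :func:`nmds`.
    """
    from sklearn.isotonic import IsotonicRegression

    d = squareform(distances.to_numpy(dtype=float), checks=False)
    dhat = pdist(scores.to_numpy(dtype=float))
    disp = IsotonicRegression().fit_transform(d, dhat)
    denom = float((dhat ** 2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dhat - disp) ** 2).sum() / denom))
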