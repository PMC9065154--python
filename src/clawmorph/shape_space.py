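"""Principal component analysis of Procrustes shape coordinates.

The morphospace is the eigendecomposition of the covariance matrix (n-1
divisor) of the flattened, tangent-projected Procrustes coordinates.  Scores
are in dimensionless Procrustes (tangent-space) units.  Because eigenvector
signs are arbitrary, :func:`orient_axes` fixes each component's sign so its
scores correlate non-negatively with a per-specimen orientation statistic —
by default ungual elongation, so that high PC1 reads as elongate claws.

Thin-plate-spline warps visualize a point of the morphospace as the
deformation of the consensus landmarks toward the back-projected shape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .superimposition import ProcrustesResult

__all__ = [
    "ShapeSpace",
    "ShapeTangentPCA",
    "shape_pca",
    "orient_axes",
    "elongation_statistic",
    "tps_warp",
    "tps_bending_energy",
]


@dataclass
class ShapeSpace:
    """PCA decomposition of a set of aligned shapes.

    scores
        (n, m) specimen scores, zero column means.
    eigenvalues
        descending non-negative variances (n-1 divisor).
    loadings
        (m, 2K) orthonormal component vectors over the flattened coordinate
        space.
    percent_variance
        per-component percentage, sums to 100.
    """

    scores: np.ndarray
    eigenvalues: np.ndarray
    loadings: np.ndarray
    percent_variance: np.ndarray
    mean_shape: np.ndarray
    specimen_ids: list[str]

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


class ShapeTangentPCA(BaseEstimator, TransformerMixin):
    """PCA of flattened Procrustes coordinates (covariance matrix, n-1).

    Components with variance below ``rank_tol`` times the largest eigenvalue
    are dropped; at most min(n-1, 2K-4) shape dimensions survive the
    similarity-transform constraints.

    Attributes (fitted)
    -------------------
    shape_space_ : ShapeSpace
    components_, explained_variance_, explained_variance_ratio_ :
        sklearn-style aliases into the same decomposition.
    """

    def __init__(self, rank_tol: float = 1e-12):
        self.rank_tol = rank_tol

    def fit(self, X, y=None):
        flat, ids, mean_shape = _as_flat(X)
        n = flat.shape[0]
        if n < 3:
            raise ValueError("shape PCA requires at least 3 specimens")
        centered = flat - flat.mean(axis=0)
        cov = centered.T @ centered / (n - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order]
        keep = evals > self.rank_tol * max(evals[0], 1.0)
        evals, evecs = evals[keep], evecs[:, keep]
        scores = centered @ evecs
        total = evals.sum()
        pct = 100.0 * evals / total if total > 0 else np.zeros_like(evals)
        self.shape_space_ = ShapeSpace(
            scores=scores,
            eigenvalues=evals,
            loadings=evecs.T,
            percent_variance=pct,
            mean_shape=flat.mean(axis=0).reshape(-1, 2),
            specimen_ids=ids,
        )
        self.components_ = evecs.T
        self.explained_variance_ = evals
        self.explained_variance_ratio_ = evals / total if total > 0 else evals
        self.mean_ = flat.mean(axis=0)
        self.n_features_in_ = flat.shape[1]
        return self

    def transform(self, X):
        flat, _, _ = _as_flat(X)
        return (flat - self.mean_) @ self.components_.T

    def fit_transform(self, X, y=None):
        return self.fit(X).shape_space_.scores


def _as_flat(X):
    """Accept ProcrustesResult or (n, K, 2)/(n, 2K) arrays."""
    if isinstance(X, ProcrustesResult):
        arr = X.aligned
        ids = X.specimen_ids
    else:
        arr = np.asarray(X, dtype=float)
        ids = [str(i) for i in range(arr.shape[0])]
    if arr.ndim == 3:
        flat = arr.reshape(arr.shape[0], -1)
    elif arr.ndim == 2:
        flat = arr
    else:
        raise ValueError("expected (n, K, 2) or (n, 2K) array")
    return flat, list(ids), flat.mean(axis=0).reshape(-1, 2)


def shape_pca(procrustes_result) -> ShapeSpace:
    """PCA of a ProcrustesResult; see :class:`ShapeTangentPCA`."""
    est = ShapeTangentPCA()
    est.fit(procrustes_result)
    return est.shape_space_


def elongation_statistic(shape: np.ndarray, tip_index: int = 0,
                         proximal_index: int | None = None) -> float:
    """Tip-to-proximal chord length of one shape (default landmarks 1 and K).

    Used to orient PC signs: elongate claws have long chords.
    """
    shape = np.asarray(shape, dtype=float).reshape(-1, 2)
    if proximal_index is None:
        proximal_index = shape.shape[0] - 1
    return float(np.linalg.norm(shape[tip_index] - shape[proximal_index]))


def orient_axes(space: ShapeSpace, statistic: np.ndarray | None = None,
                tip_index: int = 0, proximal_index: int | None = None
                ) -> ShapeSpace:
    """Flip PC signs so scores correlate non-negatively with a statistic.

    ``statistic`` is one scalar per specimen; the default reconstructs each
    specimen's shape and measures its elongation chord.  Sign-only: |scores|,
    eigenvalues and explained variance are untouched, and the operation is
    idempotent.  A zero-variance statistic leaves the axes unchanged with a
    warning.
    """
    if statistic is None:
        flat = space.mean_shape.reshape(1, -1) + space.scores @ space.loadings
        statistic = np.array(
            [elongation_statistic(row, tip_index, proximal_index)
             for row in flat]
        )
    statistic = np.asarray(statistic, dtype=float)
    if statistic.shape[0] != space.scores.shape[0]:
        raise ValueError("one statistic value per specimen required")
    if np.std(statistic) == 0:
        warnings.warn("zero-variance orientation statistic; axes unchanged")
        return space
    stat_c = statistic - statistic.mean()
    signs = np.ones(space.n_components)
    for j in range(space.n_components):
        corr = float(space.scores[:, j] @ stat_c)
        if corr < 0:
            signs[j] = -1.0
    return replace(
        space,
        scores=space.scores * signs[None, :],
        loadings=space.loadings * signs[:, None],
    )


# ---------------------------------------------------------------------------
# Thin-plate spline


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(r2 > 0, r2 * np.log(r2), 0.0) / 2.0  # r^2 log r


def _tps_solve(source: np.ndarray, target: np.ndarray):
    """Solve the 2-D TPS interpolation from source to target landmarks."""
    k = source.shape[0]
    d2 = np.sum((source[:, None] - source[None, :]) ** 2, axis=-1)
    s = _tps_kernel(d2)
    p = np.column_stack([np.ones(k), source])
    lmat = np.zeros((k + 3, k + 3))
    lmat[:k, :k] = s
    lmat[:k, k:] = p
    lmat[k:, :k] = p.T
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = target
    try:
        coef = np.linalg.solve(lmat, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular thin-plate-spline system (coincident landmarks?)"
        ) from exc
    return coef[:k], coef[k:], s


def _tps_apply(points, source, w, a):
    pts = np.asarray(points, dtype=float)
    d2 = np.sum((pts[:, None] - source[None, :]) ** 2, axis=-1)
    u = _tps_kernel(d2)
    return a[0][None, :] + pts @ a[1:] + u @ w


def tps_warp(consensus: np.ndarray, target_scores: np.ndarray,
             space: ShapeSpace, grid: np.ndarray | None = None,
             n_grid: int = 20, margin: float = 0.15):
    """Thin-plate-spline deformation grid for a morphospace point.

    Back-projects ``target_scores`` (padded with zeros beyond the given
    components) to a shape, fits the TPS interpolant mapping the consensus
    landmarks onto it, and applies it to a rectangular grid.

    Returns ``(warped_grid, target_landmarks, warp_fn)``; ``warp_fn`` maps
    arbitrary (m, 2) points through the spline.
    """
    consensus = np.asarray(consensus, dtype=float).reshape(-1, 2)
    scores = np.zeros(space.n_components)
    target_scores = np.atleast_1d(np.asarray(target_scores, dtype=float))
    scores[: len(target_scores)] = target_scores
    target = (space.mean_shape.reshape(-1) + scores @ space.loadings
              ).reshape(-1, 2)
    w, a, _ = _tps_solve(consensus, target)

    def warp_fn(points):
        return _tps_apply(points, consensus, w, a)

    if grid is None:
        lo = consensus.min(axis=0)
        hi = consensus.max(axis=0)
        span = hi - lo
        lo -= margin * span
        hi += margin * span
        gx, gy = np.meshgrid(
            np.linspace(lo[0], hi[0], n_grid),
            np.linspace(lo[1], hi[1], n_grid),
        )
        grid = np.column_stack([gx.ravel(), gy.ravel()])
    else:
        grid = np.asarray(grid, dtype=float).reshape(-1, 2)
    return warp_fn(grid), target, warp_fn


def tps_bending_energy(source: np.ndarray, target: np.ndarray) -> float:
    """Bending energy of the TPS mapping source -> target landmarks.

    Zero for any affine displacement of the source.
    """
    source = np.asarray(source, dtype=float).reshape(-1, 2)
    target = np.asarray(target, dtype=float).reshape(-1, 2)
    w, _, s = _tps_solve(source, target)
    return float(np.sum(w * (s @ w)))
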