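"""Generalized Procrustes analysis with semi-landmark sliding.

The superimposition removes position, scale, and rotation differences among
2-D landmark configurations by iteratively aligning every configuration to
the current consensus (mean shape).  Outline semi-landmarks may additionally
slide along their local tangent direction each outer iteration, under either
the minimum-bending-energy criterion (default, the convention of the
standard morphometrics toolchain) or the minimum-Procrustes-distance
criterion.  After convergence, aligned coordinates are orthogonally
projected to the tangent space at the consensus.

Reflections are never fitted: left/right unguals must be mirrored at I/O so
every specimen is digitized in the same (lateral, proximal-left) view.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .landmarks import LandmarkDataset, SliderTable

__all__ = [
    "center_and_scale",
    "optimal_rotation",
    "procrustes_distance",
    "gpa",
    "GeneralizedProcrustes",
    "ProcrustesResult",
]


class ConvergenceError(RuntimeError):
    def __init__(self, delta: float, max_iter: int):
        super().__init__(
            f"GPA did not converge in {max_iter} iterations "
            f"(last consensus displacement {delta:.3e})"
        )
        self.delta = delta


def center_and_scale(coords: np.ndarray) -> np.ndarray:
    """Translate the centroid to the origin and scale centroid size to 1.

    Centroid size is the root summed squared distance of the landmarks to
    their centroid.  Raises on degenerate (all-coincident) configurations.
    """
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    cs = np.linalg.norm(centered)
    if cs <= 0 or not np.isfinite(cs):
        raise ValueError("degenerate configuration: centroid size is zero")
    return centered / cs


def optimal_rotation(shape: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Rotate ``shape`` to best fit ``reference`` (least squares, no reflection).

    Both must be centered (K, 2) arrays with the same K.  Uses the planar
    closed form: the optimal angle satisfies
    tan(phi) = sum(x_i ∧ y_i) / sum(x_i · y_i).
    """
    shape = np.asarray(shape, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if shape.shape != reference.shape:
        raise ValueError(
            f"landmark count mismatch: {shape.shape} vs {reference.shape}"
        )
    dot = float(np.sum(shape * reference))
    cross = float(
        np.sum(shape[:, 0] * reference[:, 1] - shape[:, 1] * reference[:, 0])
    )
    phi = np.arctan2(cross, dot)
    c, s = np.cos(phi), np.sin(phi)
    rot = np.array([[c, -s], [s, c]])
    return shape @ rot.T


def procrustes_distance(shape_a: np.ndarray, shape_b: np.ndarray) -> float:
    """Partial Procrustes distance between two centered, unit-size shapes.

    The minimized root summed squared difference over rotations.  Symmetric,
    and zero iff the shapes coincide up to a similarity transform.
    """
    a = center_and_scale(shape_a)
    b = center_and_scale(shape_b)
    return float(np.linalg.norm(optimal_rotation(a, b) - b))


def _tangent_directions(coords: np.ndarray, sliders: SliderTable) -> np.ndarray:
    """Unit tangent at each semi-landmark: chord through its neighbors."""
    dirs = np.zeros((len(sliders), 2))
    for j, (before, _, after) in enumerate(sliders.rows):
        chord = coords[after] - coords[before]
        norm = np.linalg.norm(chord)
        if norm <= 0:
            raise ValueError(
                f"coincident neighbors for semi-landmark row {j + 1}"
            )
        dirs[j] = chord / norm
    return dirs


def _bending_energy_matrix(reference: np.ndarray) -> np.ndarray:
    """Thin-plate-spline bending-energy matrix L_k of the reference shape."""
    k = reference.shape[0]
    d2 = np.sum(
        (reference[:, None, :] - reference[None, :, :]) ** 2, axis=-1
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(d2 > 0, d2 * np.log(d2), 0.0) / 2.0  # r^2 log r
    q = np.column_stack([np.ones(k), reference])
    lmat = np.zeros((k + 3, k + 3))
    lmat[:k, :k] = s
    lmat[:k, k:] = q
    lmat[k:, :k] = q.T
    linv = np.linalg.pinv(lmat)
    return linv[:k, :k]


def _slide_amounts(coords: np.ndarray, consensus: np.ndarray,
                   sliders: SliderTable, mode: str,
                   energy: np.ndarray | None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Sliding amounts (per semi-landmark) and unit tangents for one shape."""
    idx = sliders.slider_indices
    tangents = _tangent_directions(coords, sliders)
    if mode == "procd":
        # independent per landmark: project the residual onto the tangent
        resid = consensus[idx] - coords[idx]
        t = np.sum(resid * tangents, axis=1)
        return t, tangents
    # bending energy: joint quadratic minimization of the TPS energy of the
    # deformation consensus -> slid specimen over all sliding amounts
    m = len(idx)
    k = coords.shape[0]
    diff = coords - consensus  # (K, 2)
    bmat_x = np.zeros((k, m))
    bmat_y = np.zeros((k, m))
    bmat_x[idx, np.arange(m)] = tangents[:, 0]
    bmat_y[idx, np.arange(m)] = tangents[:, 1]
    lhs = bmat_x.T @ energy @ bmat_x + bmat_y.T @ energy @ bmat_y
    rhs = -(bmat_x.T @ energy @ diff[:, 0] + bmat_y.T @ energy @ diff[:, 1])
    t = np.linalg.lstsq(lhs, rhs, rcond=None)[0]
    return t, tangents


@dataclass
class ProcrustesResult:
    """Superimposed coordinates plus fit diagnostics.

    aligned
        (n, K, 2) tangent-projected Procrustes coordinates.
    consensus
        (K, 2) mean shape, centered with unit centroid size.
    centroid_sizes
        original centroid size per specimen.
    sliding_displacement
        (n, K) per-landmark total sliding displacement (zero at fixed
        landmarks).
    """

    aligned: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    iterations: int
    final_delta: float
    specimen_ids: list[str]
    sliding_displacement: np.ndarray
    objective_trace: list[float]


class GeneralizedProcrustes(BaseEstimator, TransformerMixin):
    """Generalized Procrustes superimposition as a transformer.

    Parameters
    ----------
    sliders : SliderTable or None
        Semi-landmark definition; ``None`` or empty means plain GPA.
    mode : {"bending_energy", "procd"}
        Sliding criterion.
    tol : float
        Convergence tolerance on the consensus displacement.
    max_iter : int
        Maximum outer iterations.
    project_to_tangent : bool
        Orthogonally project aligned shapes to the tangent space at the
        consensus after convergence (standard before PCA).

    Attributes
    ----------
    consensus_ : (K, 2) mean shape after fitting.
    result_ : ProcrustesResult for the training data.
    """

    def __init__(self, sliders: SliderTable | None = None,
                 mode: str = "bending_energy", tol: float = 1e-8,
                 max_iter: int = 100, project_to_tangent: bool = True):
        self.sliders = sliders
        self.mode = mode
        self.tol = tol
        self.max_iter = max_iter
        self.project_to_tangent = project_to_tangent

    def _validate(self, dataset):
        if isinstance(dataset, LandmarkDataset):
            shapes = dataset.coords_array()
            ids = dataset.specimen_ids
        else:
            shapes = np.asarray(dataset, dtype=float)
            ids = [str(i) for i in range(len(shapes))]
        if shapes.ndim != 3 or shapes.shape[-1] != 2:
            raise ValueError("expected (n, K, 2) landmark array")
        if shapes.shape[0] < 2:
            raise ValueError("GPA requires at least two configurations")
        if self.mode not in ("bending_energy", "procd"):
            raise ValueError(f"unknown sliding mode {self.mode!r}")
        sliders = self.sliders if self.sliders is not None else SliderTable(())
        sliders.validate(shapes.shape[1])
        return shapes, ids, sliders

    def fit(self, X, y=None):
        shapes, ids, sliders = self._validate(X)
        n = shapes.shape[0]
        centroid_sizes = np.array(
            [np.linalg.norm(s - s.mean(axis=0)) for s in shapes]
        )
        base = np.stack([center_and_scale(s) for s in shapes])
        aligned = base.copy()
        consensus = center_and_scale(base[0])
        displacement = np.zeros(shapes.shape[:2])
        delta = np.inf
        trace: list[float] = []
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            # rotate the digitized (unslid) shapes onto the current consensus
            for i in range(n):
                base[i] = optimal_rotation(base[i], consensus)
            if len(sliders):
                # slide from the digitized positions each outer iteration:
                # sliding amounts are re-estimated from scratch against the
                # new consensus, anchoring the along-curve gauge to the
                # original spacing (prevents cumulative drift)
                energy = (
                    _bending_energy_matrix(consensus)
                    if self.mode == "bending_energy" else None
                )
                idx = sliders.slider_indices
                amounts = np.zeros((n, len(idx)))
                tangents = np.zeros((n, len(idx), 2))
                for i in range(n):
                    amounts[i], tangents[i] = _slide_amounts(
                        base[i], consensus, sliders, self.mode, energy
                    )
                # a common slide of every specimen along the outline is an
                # unidentifiable gauge mode (it drags the consensus with
                # it); only relative spacing differences are meaningful, so
                # center the amounts across specimens
                amounts -= amounts.mean(axis=0, keepdims=True)
                for i in range(n):
                    slid = base[i].copy()
                    slid[idx] += amounts[i][:, None] * tangents[i]
                    displacement[i] = np.linalg.norm(slid - base[i], axis=-1)
                    aligned[i] = optimal_rotation(
                        center_and_scale(slid), consensus
                    )
            else:
                aligned = base.copy()
            new_consensus = center_and_scale(aligned.mean(axis=0))
            new_consensus = optimal_rotation(new_consensus, consensus)
            delta = float(np.linalg.norm(new_consensus - consensus))
            consensus = new_consensus
            trace.append(float(np.sum((aligned - consensus) ** 2)))
            if delta < self.tol:
                break
        else:
            raise ConvergenceError(delta, self.max_iter)

        # canonical orientation: the solution would otherwise inherit the
        # arbitrary input orientation of the first specimen.  Rotate so the
        # consensus major axis lies along x, with the first landmark on the
        # positive side (no reflection; deterministic up to the documented
        # digitizing convention).
        m2 = consensus.T @ consensus
        evals, evecs = np.linalg.eigh(m2)
        major = evecs[:, np.argmax(evals)]
        ang = np.arctan2(major[1], major[0])
        c, s = np.cos(-ang), np.sin(-ang)
        rot = np.array([[c, -s], [s, c]])
        consensus = consensus @ rot.T
        if consensus[0, 0] < 0:
            consensus = -consensus  # 180-degree flip, not a reflection
            rot = -rot
        aligned = aligned @ rot.T
        if self.project_to_tangent:
            flat = aligned.reshape(n, -1)
            mu = consensus.reshape(-1)
            mu = mu / np.linalg.norm(mu)
            proj = flat - (flat @ mu)[:, None] * mu[None, :] + mu[None, :]
            aligned = proj.reshape(n, -1, 2)
        # report the arithmetic mean of the aligned shapes as the consensus
        # (its centroid size is marginally below 1; the unit-size version
        # exists only as the internal iteration reference)
        consensus = aligned.mean(axis=0)
        self.consensus_ = consensus
        self.result_ = ProcrustesResult(
            aligned=aligned,
            consensus=consensus,
            centroid_sizes=centroid_sizes,
            iterations=n_iter,
            final_delta=delta,
            specimen_ids=list(ids),
            sliding_displacement=displacement,
            objective_trace=trace,
        )
        self.n_features_in_ = shapes.shape[1] * 2
        return self

    def transform(self, X):
        """Align configurations to the fitted consensus (no sliding)."""
        if not hasattr(self, "consensus_"):
            raise RuntimeError("GeneralizedProcrustes is not fitted")
        if isinstance(X, LandmarkDataset):
            shapes = X.coords_array()
        else:
            shapes = np.asarray(X, dtype=float)
        out = np.stack(
            [optimal_rotation(center_and_scale(s), self.consensus_)
             for s in shapes]
        )
        return out

    def fit_transform(self, X, y=None):
        return self.fit(X).result_.aligned


def gpa(dataset, sliders: SliderTable | None = None,
        mode: str = "bending_energy", tol: float = 1e-8,
        max_iter: int = 100, project_to_tangent: bool = True
        ) -> ProcrustesResult:
    """Run generalized Procrustes analysis and return the result bundle."""
    est = GeneralizedProcrustes(
        sliders=sliders, mode=mode, tol=tol, max_iter=max_iter,
        project_to_tangent=project_to_tangent,
    )
    est.fit(dataset)
    return est.result_
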