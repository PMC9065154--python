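"""Independent oracles used by the test suite.

Each oracle is deliberately implemented by a different route than the
package code it checks: closed forms, grid search, or exhaustive
enumeration at tiny problem sizes.
"""

from __future__ import annotations

import itertools

import numpy as np


def two_shape_procrustes_residual(a: np.ndarray, b: np.ndarray) -> float:
    """Closed-form 2-D rotation-only Procrustes residual via complex algebra.

    For centered unit-norm planar shapes written as complex vectors, the
    minimized residual over rotations is sqrt(2 - 2|<a, b>|).
    """
    za = (a[:, 0] + 1j * a[:, 1]).astype(complex)
    zb = (b[:, 0] + 1j * b[:, 1]).astype(complex)
    za = za - za.mean()
    zb = zb - zb.mean()
    za = za / np.linalg.norm(za)
    zb = zb / np.linalg.norm(zb)
    return float(np.sqrt(max(0.0, 2.0 - 2.0 * abs(np.vdot(zb, za)))))


def grid_procrustes_distance(a: np.ndarray, b: np.ndarray,
                             coarse: int = 3600) -> float:
    """Rotation-grid search with local refinement (no linear algebra)."""

    def centered_unit(x):
        x = x - x.mean(axis=0)
        return x / np.linalg.norm(x)

    a = centered_unit(np.asarray(a, float))
    b = centered_unit(np.asarray(b, float))

    def resid(phi):
        c, s = np.cos(phi), np.sin(phi)
        rot = np.array([[c, -s], [s, c]])
        return np.linalg.norm(a @ rot.T - b)

    phis = np.linspace(0, 2 * np.pi, coarse, endpoint=False)
    best = min(phis, key=resid)
    lo, hi = best - 2 * np.pi / coarse, best + 2 * np.pi / coarse
    for _ in range(60):
        third = (hi - lo) / 3
        m1, m2 = lo + third, hi - third
        if resid(m1) < resid(m2):
            hi = m2
        else:
            lo = m1
    return resid((lo + hi) / 2)


def plain_gpa_reference(shapes: np.ndarray, tol: float = 1e-12,
                        max_iter: int = 2000) -> np.ndarray:
    """Small, direct plain-GPA implementation (no sliding, no projection).

    Iterates the closed-form two-shape rotation against the running mean.
    Returns aligned (n, K, 2) coordinates in an arbitrary joint orientation.
    """

    def norm(x):
        x = x - x.mean(axis=0)
        return x / np.linalg.norm(x)

    def rotate_onto(x, ref):
        za = (x[:, 0] + 1j * x[:, 1])
        zb = (ref[:, 0] + 1j * ref[:, 1])
        w = np.vdot(za, zb)  # sum conj(za) zb
        phi = np.angle(w)
        c, s = np.cos(phi), np.sin(phi)
        rot = np.array([[c, -s], [s, c]])
        return x @ rot.T

    aligned = np.stack([norm(s) for s in shapes])
    consensus = aligned[0].copy()
    for _ in range(max_iter):
        for i in range(len(aligned)):
            aligned[i] = rotate_onto(aligned[i], consensus)
        new = norm(aligned.mean(axis=0))
        new = rotate_onto(new, consensus)
        if np.linalg.norm(new - consensus) < tol:
            consensus = new
            break
        consensus = new
    return aligned


def brute_force_character_length(tree, column, ordered: bool) -> int:
    """Exhaustive minimization over all internal-state assignments.

    ``column`` is one state-set (or None) per taxon index.  Leaves realize
    the cheapest member of their set given their neighbor's state.
    """
    states = sorted({s for cell in column if cell for s in cell}) or [0]
    internal = [n for n in tree.adj if n not in tree.leaves and tree.adj[n]]
    leaf_ids = list(tree.present_leaves())

    def dist(x, y):
        if ordered:
            return abs(x - y)
        return 0 if x == y else 1

    best = float("inf")
    for assign in itertools.product(states, repeat=len(internal)):
        amap = dict(zip(internal, assign))
        cost = 0
        for u, v in tree.edges():
            if u not in tree.leaves and v not in tree.leaves:
                cost += dist(amap[u], amap[v])
        for leaf in leaf_ids:
            (nb,) = tree.adj[leaf]
            cell = column[leaf]
            if cell is not None:
                cost += min(dist(s, amap[nb]) for s in cell)
        best = min(best, cost)
    return int(best)


def exhaustive_min_length(matrix) -> float:
    """Exact best tree length over all topologies (ntax <= 7)."""
    from clawmorph.parsimony import _fast_length
    from clawmorph.trees import all_unrooted_topologies

    return float(
        min(
            _fast_length(t, matrix)
            for t in all_unrooted_topologies(matrix.ntax, matrix.taxa)
        )
    )


def welch_oracle(a, b):
    """Hand-computed Welch statistic and Welch-Satterthwaite df."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df
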