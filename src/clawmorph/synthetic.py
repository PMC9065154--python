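"""Synthetic claw-shape, lever, and character-matrix generators.

Every stage of the pipeline is testable without specimen data: claws are
built from two concentric circular arcs (dorsal and ventral margins) whose
geometry is controlled by a handful of interpretable parameters, lever
measurements are derived from the exact (noiseless) geometry, and discrete
character matrices are evolved along a known tree so searches can be judged
against ground truth.

Circular arcs were chosen over more anatomical outline families (e.g.
logarithmic spirals) because the lever geometry stays analytic: the
generated DFT equals ``tubercle_prominence`` exactly, and elongation maps
monotonically to the tip-chord/proximal-height ratio the parameter states.

Group presets emulate the basal-vs-derived therizinosaur contrast: short
strongly curved claws with prominent flexor tubercles ("basal") versus
elongate weakly curved claws with reduced tubercles ("derived").
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .landmarks import (
    CladeGroup,
    Digit,
    LandmarkConfiguration,
    LandmarkDataset,
    LeverMeasurements,
    SliderTable,
)
from .parsimony import CharacterMatrix
from .trees import UnrootedTree

__all__ = [
    "SyntheticClawParams",
    "BASAL_PRESET",
    "DERIVED_PRESET",
    "claw_sliders",
    "generate_claw",
    "generate_claw_dataset",
    "random_binary_tree",
    "generate_character_matrix",
]

# landmark layout of a generated claw (16 points)
#   0 tip                      (fixed)
#   1 proximodorsal lip        (fixed)
#   2 proximoventral process   (fixed)
#   3 flexor tubercle apex     (fixed)
#   4-10 dorsal-margin semi-landmarks, lip -> tip
#   11-15 ventral-margin semi-landmarks, tubercle -> tip
N_LANDMARKS = 16
_DORSAL_SEMIS = list(range(4, 11))
_VENTRAL_SEMIS = list(range(11, 16))
# ventral-margin arc fractions of the tubercle base (apex midway between)
_TUBERCLE_S = (0.08, 0.28)
_VENTRAL_SEMI_S = (0.40, 0.55, 0.70, 0.82, 0.92)


@dataclass(frozen=True)
class SyntheticClawParams:
    """Generative parameters for one claw population.

    curvature
        arc angle subtended by the dorsal outline, degrees.
    elongation
        tip-chord / proximal-height ratio (dimensionless, > ~0.5).
    tubercle_prominence
        flexor-tubercle height over base-segment length (= generated DFT).
    articular_depth
        proximal extension of the ventral process, as a fraction of the
        proximal height.
    landmark_noise_sd
        isotropic Gaussian noise added per landmark, in units of the
        (unit-radius) outline — effectively Procrustes units.
    param_jitter
        relative SD of per-specimen lognormal jitter applied to curvature,
        elongation and tubercle prominence (individual variation).
    """

    n_per_group: int = 10
    curvature: float = 120.0
    elongation: float = 2.0
    tubercle_prominence: float = 0.2
    articular_depth: float = 0.15
    landmark_noise_sd: float = 0.01
    param_jitter: float = 0.08
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for name in ("curvature", "elongation"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.curvature < 180:
            raise ValueError("curvature must lie in (0, 180) degrees")
        if self.tubercle_prominence < 0:
            raise ValueError("tubercle_prominence must be non-negative")
        if self.landmark_noise_sd < 0 or self.param_jitter < 0:
            raise ValueError("noise parameters must be non-negative")


BASAL_PRESET = SyntheticClawParams(
    curvature=140.0, elongation=1.6, tubercle_prominence=0.30, seed=0
)
DERIVED_PRESET = SyntheticClawParams(
    curvature=100.0, elongation=2.6, tubercle_prominence=0.12, seed=1
)


def claw_sliders() -> SliderTable:
    """Slider table matching the generated 16-landmark scheme (12 sliders)."""
    rows = []
    dorsal_chain = [1] + _DORSAL_SEMIS + [0]
    for i in range(1, len(dorsal_chain) - 1):
        rows.append((dorsal_chain[i - 1], dorsal_chain[i], dorsal_chain[i + 1]))
    ventral_chain = [3] + _VENTRAL_SEMIS + [0]
    for i in range(1, len(ventral_chain) - 1):
        rows.append(
            (ventral_chain[i - 1], ventral_chain[i], ventral_chain[i + 1])
        )
    table = SliderTable(tuple(rows))
    table.validate(N_LANDMARKS)
    return table


def minimum_elongation(curvature: float) -> float:
    """Smallest tip-chord/proximal-height ratio a valid outline allows.

    At the limit the ventral margin collapses onto the arc center
    (proximal height 1); below it the outline would self-intersect.
    """
    return math.sqrt(1.25 - math.cos(math.radians(curvature)))


def _solve_proximal_height(curvature_rad: float, elongation: float) -> float:
    """Proximal height h in (0, 1) with tip-chord / h = elongation."""

    def objective(h):
        m = 1.0 - h / 2.0  # proximal-edge midpoint radius
        chord = math.sqrt(1.0 + m * m - 2.0 * m * math.cos(curvature_rad))
        return chord - elongation * h

    lo, hi = 1e-6, 1.0 - 1e-6
    if objective(hi) > 0:
        raise ValueError(
            "invalid claw parameters: elongation too small for this "
            "curvature (outline would self-intersect)"
        )
    return float(brentq(objective, lo, hi))


def _claw_geometry(params: SyntheticClawParams) -> dict:
    """Exact outline geometry (no noise) in the unit-dorsal-radius frame."""
    kappa = math.radians(params.curvature)
    h = _solve_proximal_height(kappa, params.elongation)
    r = 1.0 - h  # ventral proximal radius

    alpha_prox = math.pi / 2 + kappa / 2
    alpha_tip = math.pi / 2 - kappa / 2

    def dorsal(t):  # t in [0, 1], 0 = proximal lip, 1 = tip
        alpha = alpha_prox - t * kappa
        return np.array([math.cos(alpha), math.sin(alpha)])

    def ventral(s):  # s in [0, 1], 0 = proximoventral, 1 = tip; linear taper
        alpha = alpha_prox - s * kappa
        rho = r + (1.0 - r) * s
        return rho * np.array([math.cos(alpha), math.sin(alpha)])

    tip = dorsal(1.0)
    lip = dorsal(0.0)
    pv = ventral(0.0)
    # ventral process extends proximally by articular_depth * h along the
    # local tangent (direction of increasing alpha)
    alpha0 = alpha_prox
    tangent_prox = np.array([-math.sin(alpha0), math.cos(alpha0)])
    pv = pv + params.articular_depth * h * tangent_prox

    s1, s2 = _TUBERCLE_S
    b1, b2 = ventral(s1), ventral(s2)
    base = b2 - b1
    b_len = float(np.linalg.norm(base))
    mid = (b1 + b2) / 2.0
    normal = np.array([-base[1], base[0]]) / b_len
    if np.dot(normal, mid) > 0:  # point away from the arc center (outward)
        normal = -normal
    apex = mid + params.tubercle_prominence * b_len * normal

    coords = np.zeros((N_LANDMARKS, 2))
    coords[0] = tip
    coords[1] = lip
    coords[2] = pv
    coords[3] = apex
    for j, idx in enumerate(_DORSAL_SEMIS):
        t = (j + 1) / (len(_DORSAL_SEMIS) + 1)
        coords[idx] = dorsal(t)
    for idx, s in zip(_VENTRAL_SEMIS, _VENTRAL_SEMI_S):
        coords[idx] = ventral(s)

    # lever geometry: the fulcrum is the center of the proximal articular
    # facet (midpoint of the proximal edge), the output acts at the tip,
    # and the input force follows the flexor tendon, approximated by the
    # ventral-margin tangent just proximal to the tubercle, pulling
    # proximoventrally
    fulcrum = (lip + ventral(0.0)) / 2.0
    lever = tip - fulcrum
    a = float(np.linalg.norm(lever))
    d_vec = apex - fulcrum
    d = float(np.linalg.norm(d_vec))
    delta = _deg_angle(d_vec, lever)
    alpha_t = alpha_prox - s1 * kappa
    tendon = np.array([math.sin(alpha_t), -math.cos(alpha_t)])  # distal dir
    # input torque about the fulcrum is |F| d sin(phi) with phi the angle
    # between the (proximally pulling) tendon and the fulcrum->apex line;
    # the lever convention splits phi as theta + delta about the lever line
    phi = _deg_angle(-tendon, d_vec)
    theta = phi - delta
    return {
        "coords": coords,
        "a": a,
        "d": d,
        "theta": theta,
        "delta": delta,
        "h": params.tubercle_prominence * b_len,
        "b": b_len,
        "proximal_height": h,
    }


def _deg_angle(u, v) -> float:
    c = float(
        np.clip(
            np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1
        )
    )
    return math.degrees(math.acos(c))


def _jittered(params: SyntheticClawParams, rng: np.random.Generator
              ) -> SyntheticClawParams:
    if params.param_jitter == 0:
        return params
    factors = np.exp(rng.normal(0.0, params.param_jitter, size=3))
    curv = min(float(params.curvature * factors[0]), 179.0)
    elong = float(params.elongation * factors[1])
    # jittered draws stay inside the valid outline region
    elong = max(elong, 1.02 * minimum_elongation(curv))
    return replace(
        params,
        curvature=curv,
        elongation=elong,
        tubercle_prominence=float(params.tubercle_prominence * factors[2]),
    )


def generate_claw(params: SyntheticClawParams, specimen_seed: int,
                  specimen_id: str = "claw",
                  clade_group: CladeGroup = CladeGroup.unknown,
                  digit: Digit = Digit.unknown,
                  jitter: bool = False
                  ) -> tuple[LandmarkConfiguration, LeverMeasurements, dict]:
    """Generate one claw: landmarks (noisy), levers (exact), true params.

    Deterministic in ``(params, specimen_seed)``; with zero prominence the
    generated DFT is exactly zero.
    """
    rng = np.random.default_rng(specimen_seed)
    used = _jittered(params, rng) if jitter else params
    geom = _claw_geometry(used)
    coords = geom["coords"].copy()
    if params.landmark_noise_sd > 0:
        coords += rng.normal(0.0, params.landmark_noise_sd, coords.shape)
    config = LandmarkConfiguration(
        specimen_id=specimen_id,
        coords=coords,
        taxon=specimen_id,
        digit=digit,
        clade_group=clade_group,
    )
    theta, delta = geom["theta"], geom["delta"]
    levers = LeverMeasurements(
        specimen_id=specimen_id,
        a=geom["a"], d=geom["d"], theta=theta, delta=delta,
        h=geom["h"], b=geom["b"],
        digit=digit, clade_group=clade_group,
    )
    truth = {
        "curvature": used.curvature,
        "elongation": used.elongation,
        "tubercle_prominence": used.tubercle_prominence,
        "proximal_height": geom["proximal_height"],
    }
    return config, levers, truth


def generate_claw_dataset(
    params_basal: SyntheticClawParams = BASAL_PRESET,
    params_derived: SyntheticClawParams = DERIVED_PRESET,
    jitter: bool = True,
) -> tuple[LandmarkDataset, list[LeverMeasurements], dict]:
    """Pooled two-group dataset emulating the basal-vs-derived contrast.

    Returns the landmark dataset, the per-claw lever measurements, and a
    ground-truth dict (per-specimen true parameters and group labels).
    Specimen seeds derive from each group's ``seed``, so identical
    parameter sets (including seed) yield identical groups.
    """
    configs: list[LandmarkConfiguration] = []
    levers: list[LeverMeasurements] = []
    truth: dict[str, dict] = {}
    groups = (
        ("basal", params_basal, CladeGroup.non_therizinosaurid),
        ("derived", params_derived, CladeGroup.therizinosaurid),
    )
    for label, params, clade in groups:
        base_seed = np.random.SeedSequence(params.seed)
        child_seeds = base_seed.spawn(params.n_per_group)
        for i, child in enumerate(child_seeds):
            sid = f"{label}_{i:02d}"
            seed_int = int(child.generate_state(1)[0] % (2**31))
            config, lever, t = generate_claw(
                params, seed_int, specimen_id=sid, clade_group=clade,
                jitter=jitter,
            )
            configs.append(config)
            levers.append(lever)
            truth[sid] = {"group": label, **t}
    return LandmarkDataset(configs), levers, truth


# ---------------------------------------------------------------------------
# Character matrices on known trees


def random_binary_tree(taxa: list[str], seed: int | None = None
                       ) -> UnrootedTree:
    """Uniform-ish random unrooted binary tree by random sequential addition."""
    import random as _random

    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    rng = _random.Random(seed)
    tree = UnrootedTree.from_triplet(taxa, leaves=(0, 1, 2))
    for leaf in range(3, len(taxa)):
        edge = rng.choice(tree.edges())
        tree.insert_leaf_on_edge(leaf, edge)
    return tree


def generate_character_matrix(
    tree: UnrootedTree,
    nchar: int,
    change_prob: float = 0.1,
    ordered_fraction: float = 0.25,
    missing_prob: float = 0.3,
    seed: int | None = None,
    max_state: int = 3,
    exactly_one_change: bool = False,
) -> tuple[CharacterMatrix, UnrootedTree, np.ndarray]:
    """Evolve a fossil-like discrete matrix along a known binary tree.

    Each character starts in state 0 at an arbitrary root and changes on
    each branch with probability ``change_prob`` (unordered: uniform other
    state up to ``max_state``; ordered: +/-1 step, clamped).  Cells are then
    masked to missing with ``missing_prob``.  Returns the matrix, the true
    tree, and the per-character true change counts.

    ``exactly_one_change`` replaces the stochastic sprinkling with a
    homoplasy-free construction: every character changes exactly once, on
    one uniformly chosen branch (``change_prob`` is then ignored).  On such
    matrices the true tree is always most parsimonious with S = nchar and
    ensemble CI = RI = 1, which is what recovery experiments need as
    ground truth.
    """
    if not 0 <= change_prob <= 1 or not 0 <= missing_prob <= 1:
        raise ValueError("probabilities must lie in [0, 1]")
    if not tree.is_binary():
        raise ValueError("true tree must be binary")
    rng = np.random.default_rng(seed)
    ordered = rng.random(nchar) < ordered_fraction
    order, parent = tree.postorder()
    preorder = list(reversed(order))
    root = preorder[0]
    n_leaves = tree.n_leaves

    states = {node: np.zeros(nchar, dtype=int) for node in tree.adj}
    true_changes = np.zeros(nchar, dtype=int)
    if exactly_one_change:
        non_root = preorder[1:]
        change_node = {
            j: non_root[rng.integers(len(non_root))] for j in range(nchar)
        }
        for node in preorder[1:]:
            par_states = states[parent[node]]
            new_states = par_states.copy()
            for j in range(nchar):
                if change_node[j] == node:
                    new_states[j] = par_states[j] + 1  # single 0 -> 1 origin
                    true_changes[j] += 1
            states[node] = new_states
        return _mask_and_pack(tree, states, nchar, ordered, missing_prob,
                              rng, true_changes)
    for node in preorder[1:]:
        par_states = states[parent[node]]
        change = rng.random(nchar) < change_prob
        new_states = par_states.copy()
        for j in np.flatnonzero(change):
            if ordered[j]:
                step = 1 if rng.random() < 0.5 else -1
                cand = par_states[j] + step
                if not 0 <= cand <= max_state:
                    cand = par_states[j] - step
                new_states[j] = cand
            else:
                choices = [s for s in range(max_state + 1)
                           if s != par_states[j]]
                new_states[j] = choices[rng.integers(len(choices))]
            if new_states[j] != par_states[j]:
                true_changes[j] += 1
        states[node] = new_states

    return _mask_and_pack(tree, states, nchar, ordered, missing_prob, rng,
                          true_changes)


def _mask_and_pack(tree, states, nchar, ordered, missing_prob, rng,
                   true_changes):
    cells: list[list[frozenset | None]] = []
    for leaf in range(tree.n_leaves):
        row: list[frozenset | None] = []
        for j in range(nchar):
            if rng.random() < missing_prob:
                row.append(None)
            else:
                row.append(frozenset([int(states[leaf][j])]))
        cells.append(row)
    matrix = CharacterMatrix(
        list(tree.taxa), cells, ordered,
        np.ones(nchar, dtype=bool), np.ones(nchar),
    )
    return matrix, tree, true_changes


def write_ground_truth(truth: dict, tree: UnrootedTree | None,
                       true_changes, path: str | Path) -> None:
    """Persist generator ground truth as JSON (tree as Newick)."""
    payload = {"specimens": truth}
    if tree is not None:
        payload["true_tree_newick"] = tree.newick()
    if true_changes is not None:
        payload["true_changes"] = [int(c) for c in true_changes]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
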