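"""Morphological maximum parsimony.

Discrete character matrices (TNT xread or NEXUS) are scored on unrooted
binary trees by minimum state changes: Fitch set operations for unordered
characters and a Sankoff dynamic program with linear (additive) costs for
ordered characters — exact for polymorphic cells, which may realize any of
their member states at no cost.  Missing ('?') and inapplicable ('-') cells
carry no information.  Heuristic search follows the classic recipe: random
addition sequence Wagner builds, then NNI/SPR/TBR branch swapping holding a
fixed number of equally parsimonious trees per replicate, pooled and
deduplicated across replicates.

The ensemble consistency index CI = M/S and retention index
RI = (G - S)/(G - M) use per-character minima M (observed states minus one,
or the observed range when ordered) and star-tree maxima G; uninformative
characters are included in the sums.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .trees import UnrootedTree, all_unrooted_topologies

__all__ = [
    "CharacterMatrix",
    "ParsimonyScore",
    "read_matrix",
    "parse_tnt",
    "parse_nexus",
    "write_tnt",
    "character_length",
    "tree_length",
    "wagner_build",
    "branch_swap_search",
    "ParsimonySearch",
]

_MISSING = None
_STATE_SYMBOLS = "0123456789ABCDEFGHIJKLMNOPQRSTUV"


@dataclass
class CharacterMatrix:
    """Discrete morphological character matrix.

    ``cells[i][j]`` is a frozenset of integer states (singleton for a plain
    cell, larger for polymorphism) or ``None`` for missing/inapplicable.
    ``ordered``, ``active`` and ``weights`` are per-character arrays;
    excluded characters never contribute to any score.
    """

    taxa: list[str]
    cells: list[list[frozenset | None]]
    ordered: np.ndarray
    active: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.ordered = np.asarray(self.ordered, dtype=bool)
        self.active = np.asarray(self.active, dtype=bool)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.taxa) != len(self.cells):
            raise ValueError("one row of cells per taxon required")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = [t for t in self.taxa if self.taxa.count(t) > 1]
            raise ValueError(f"duplicate taxa: {sorted(set(dupes))}")
        nchar = self.nchar
        for taxon, row in zip(self.taxa, self.cells):
            if len(row) != nchar:
                raise ValueError(
                    f"taxon {taxon!r}: row length {len(row)} != nchar {nchar}"
                )
        for arr, name in ((self.ordered, "ordered"), (self.active, "active"),
                          (self.weights, "weights")):
            if arr.shape != (nchar,):
                raise ValueError(f"{name} flags must have length nchar")

    @property
    def ntax(self) -> int:
        return len(self.taxa)

    @property
    def nchar(self) -> int:
        return len(self.cells[0]) if self.cells else 0

    @classmethod
    def from_strings(cls, taxa, rows, ordered_1based=(), excluded_1based=(),
                     weights=None) -> "CharacterMatrix":
        """Build from per-taxon state strings ('?' missing, '-' inapplicable,
        '[01]' or '(01)' polymorphic); character lists are 1-based."""
        cells = [_parse_row(r, taxon) for taxon, r in zip(taxa, rows)]
        nchar = len(cells[0]) if cells else 0
        ordered = np.zeros(nchar, dtype=bool)
        active = np.ones(nchar, dtype=bool)
        for c in ordered_1based:
            ordered[int(c) - 1] = True
        for c in excluded_1based:
            active[int(c) - 1] = False
        w = np.ones(nchar) if weights is None else np.asarray(weights, float)
        return cls(list(taxa), cells, ordered, active, w)

    def column(self, j: int) -> list[frozenset | None]:
        return [row[j] for row in self.cells]

    def subset_taxa(self, names: list[str]) -> "CharacterMatrix":
        index = {t: i for i, t in enumerate(self.taxa)}
        rows = [self.cells[index[n]] for n in names]
        return CharacterMatrix(list(names), rows, self.ordered.copy(),
                               self.active.copy(), self.weights.copy())


def _parse_row(row: str, taxon: str) -> list[frozenset | None]:
    cells: list[frozenset | None] = []
    i = 0
    while i < len(row):
        ch = row[i]
        if ch in "?":
            cells.append(_MISSING)
            i += 1
        elif ch == "-":
            cells.append(_MISSING)  # inapplicable scored as missing
            i += 1
        elif ch in "[(":
            close = "]" if ch == "[" else ")"
            j = row.find(close, i)
            if j < 0:
                raise ValueError(
                    f"taxon {taxon!r}: unclosed polymorphism at column {i + 1}"
                )
            states = frozenset(
                _STATE_SYMBOLS.index(s) for s in row[i + 1:j].replace(" ", "")
            )
            if not states:
                raise ValueError(
                    f"taxon {taxon!r}: empty polymorphism at column {i + 1}"
                )
            cells.append(states)
            i = j + 1
        elif ch.upper() in _STATE_SYMBOLS:
            cells.append(frozenset([_STATE_SYMBOLS.index(ch.upper())]))
            i += 1
        elif ch.isspace():
            i += 1
        else:
            raise ValueError(
                f"taxon {taxon!r}: unknown state symbol {ch!r} at column {i + 1}"
            )
    return cells


# ---------------------------------------------------------------------------
# File formats


def read_matrix(path: str | Path, format: str | None = None,
                ordered: list[int] | None = None,
                excluded: list[int] | None = None,
                tnt_zero_based: bool = True) -> CharacterMatrix:
    """Read a character matrix from TNT xread or NEXUS.

    ``format`` is inferred from the extension when omitted ('.tnt'/'.tre' ->
    tnt, '.nex'/'.nexus' -> nexus).  ``ordered`` and ``excluded`` are
    1-based sidecar overrides applied after any in-file ccode/ASSUMPTIONS
    settings.  TNT ccode numbers are 0-based on disk by convention
    (``tnt_zero_based``); NEXUS is always 1-based.
    """
    path = Path(path)
    if format is None:
        format = ("nexus" if path.suffix.lower() in (".nex", ".nexus")
                  else "tnt")
    text = path.read_text()
    if format == "tnt":
        matrix = parse_tnt(text, zero_based_ccode=tnt_zero_based)
    elif format == "nexus":
        matrix = parse_nexus(text)
    else:
        raise ValueError(f"unknown matrix format {format!r}")
    if ordered:
        matrix.ordered[:] = False
        for c in ordered:
            matrix.ordered[c - 1] = True
    if excluded:
        for c in excluded:
            matrix.active[c - 1] = False
    return matrix


def parse_tnt(text: str, zero_based_ccode: bool = True) -> CharacterMatrix:
    """Parse a TNT xread file with optional ccode block."""
    # strip 'comments' in quotes after xread
    m = re.search(r"xread\s*(?:'[^']*'\s*)?(\d+)\s+(\d+)", text, re.I)
    if not m:
        raise ValueError("no xread block found")
    nchar, ntax = int(m.group(1)), int(m.group(2))
    rest = text[m.end():]
    end = rest.find(";")
    if end < 0:
        raise ValueError("unterminated xread block")
    block = rest[:end]
    taxa: list[str] = []
    rows: dict[str, str] = {}
    for line in block.splitlines():
        line = line.strip()
        if not line or line.startswith("'") or line.startswith("&"):
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise ValueError(f"malformed xread row: {line!r}")
        name, states = parts
        if name not in rows:
            taxa.append(name)
            rows[name] = ""
        rows[name] += states.replace(" ", "")
    if len(taxa) != ntax:
        raise ValueError(f"xread header says {ntax} taxa, found {len(taxa)}")
    cells = [_parse_row(rows[t], t) for t in taxa]
    for t, row in zip(taxa, cells):
        if len(row) != nchar:
            raise ValueError(
                f"taxon {t!r}: {len(row)} characters, header says {nchar}"
            )
    ordered = np.zeros(nchar, dtype=bool)
    active = np.ones(nchar, dtype=bool)
    weights = np.ones(nchar)
    offset = 0 if zero_based_ccode else 1
    for cm in re.finditer(r"ccode\s+([^;]*);", text, re.I):
        _apply_ccode(cm.group(1), ordered, active, weights, offset, nchar)
    matrix = CharacterMatrix(taxa, cells, ordered, active, weights)
    return matrix


def _apply_ccode(body: str, ordered, active, weights, offset, nchar):
    tokens = body.split()
    mode = None
    for tok in tokens:
        if tok in "+-[]":
            mode = tok
        elif tok.startswith("/"):
            mode = ("w", float(tok[1:]))
        else:
            lo, _, hi = tok.partition("..")
            idx = range(int(lo) - offset,
                        (int(hi) if hi else int(lo)) - offset + 1)
            for i in idx:
                if not 0 <= i < nchar:
                    raise ValueError(f"ccode index {i + offset} out of range")
                if mode == "+":
                    ordered[i] = True
                elif mode == "-":
                    ordered[i] = False
                elif mode == "[":
                    active[i] = True
                elif mode == "]":
                    active[i] = False
                elif isinstance(mode, tuple):
                    weights[i] = mode[1]


def parse_nexus(text: str) -> CharacterMatrix:
    """Parse a NEXUS CHARACTERS/DATA block (plus ord/exset ASSUMPTIONS)."""
    stripped = re.sub(r"\[[^\]]*\]", " ", text)  # nexus comments
    m = re.search(r"ntax\s*=\s*(\d+)", stripped, re.I)
    n = re.search(r"nchar\s*=\s*(\d+)", stripped, re.I)
    if not m or not n:
        raise ValueError("NEXUS DIMENSIONS with ntax/nchar required")
    ntax, nchar = int(m.group(1)), int(n.group(1))
    missing = "?"
    gap = "-"
    fmt = re.search(r"format\s+([^;]*);", stripped, re.I)
    if fmt:
        fm = re.search(r"missing\s*=\s*(\S)", fmt.group(1), re.I)
        gp = re.search(r"gap\s*=\s*(\S)", fmt.group(1), re.I)
        if fm:
            missing = fm.group(1)
        if gp:
            gap = gp.group(1)
    mat = re.search(r"matrix(.*?);", stripped, re.I | re.S)
    if not mat:
        raise ValueError("no MATRIX block found")
    taxa: list[str] = []
    rows: dict[str, str] = {}
    for line in mat.group(1).splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("'"):
            j = line.find("'", 1)
            name, states = line[1:j], line[j + 1:]
        else:
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise ValueError(f"malformed matrix row: {line!r}")
            name, states = parts
        if name not in rows:
            taxa.append(name)
            rows[name] = ""
        rows[name] += states.replace(" ", "")
    if len(taxa) != ntax:
        raise ValueError(f"DIMENSIONS says {ntax} taxa, found {len(taxa)}")
    norm_rows = []
    for t in taxa:
        row = rows[t].replace(missing, "?")
        if gap != "-":
            row = row.replace(gap, "-")
        norm_rows.append(row)
    cells = [_parse_row(r, t) for t, r in zip(taxa, norm_rows)]
    for t, row in zip(taxa, cells):
        if len(row) != nchar:
            raise ValueError(
                f"taxon {t!r}: {len(row)} characters, DIMENSIONS says {nchar}"
            )
    ordered = np.zeros(nchar, dtype=bool)
    active = np.ones(nchar, dtype=bool)
    for am in re.finditer(r"typeset[^=;]*=\s*([^;]*);", stripped, re.I):
        for part in am.group(1).split(","):
            kind, _, nums = part.partition(":")
            if kind.strip().lower() in ("ord", "wagner"):
                for i in _expand_nexus_list(nums, nchar):
                    ordered[i - 1] = True
    for em in re.finditer(r"exset[^=;]*=\s*([^;]*);", stripped, re.I):
        for i in _expand_nexus_list(em.group(1), nchar):
            active[i - 1] = False
    return CharacterMatrix(taxa, cells, ordered, active, np.ones(nchar))


def _expand_nexus_list(nums: str, nchar: int):
    out = []
    for tok in nums.split():
        lo, _, hi = tok.partition("-")
        if hi:
            out.extend(range(int(lo), int(hi) + 1))
        elif tok.strip() == ".":
            out.append(nchar)
        else:
            out.append(int(lo))
    return out


def write_tnt(matrix: CharacterMatrix, path: str | Path,
              zero_based_ccode: bool = True) -> None:
    path = Path(path)
    lines = ["xread", f"{matrix.nchar} {matrix.ntax}"]
    for taxon, row in zip(matrix.taxa, matrix.cells):
        chunks = []
        for cell in row:
            if cell is None:
                chunks.append("?")
            elif len(cell) == 1:
                chunks.append(_STATE_SYMBOLS[next(iter(cell))])
            else:
                chunks.append(
                    "[" + "".join(_STATE_SYMBOLS[s] for s in sorted(cell)) + "]"
                )
        lines.append(f"{taxon.replace(' ', '_')} {''.join(chunks)}")
    lines.append(";")
    off = 0 if zero_based_ccode else 1
    if matrix.ordered.any():
        nums = " ".join(str(i + off) for i in np.flatnonzero(matrix.ordered))
        lines.append(f"ccode + {nums};")
    if not matrix.active.all():
        nums = " ".join(str(i + off) for i in np.flatnonzero(~matrix.active))
        lines.append(f"ccode ] {nums};")
    lines.append("proc /;")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Tree length


_BIG = 1e9


def character_length(tree: UnrootedTree, column, ordered: bool = False,
                     taxa: list[str] | None = None) -> int:
    """Minimum state changes of one character on a binary tree.

    ``column`` is a per-taxon list of frozensets/None aligned with
    ``tree.taxa``; missing leaves take the full observed state set.
    """
    matrix = CharacterMatrix(
        tree.taxa if taxa is None else taxa,
        [[cell] for cell in column],
        np.array([ordered]), np.array([True]), np.array([1.0]),
    )
    return int(_lengths_on_tree(tree, matrix)[0])


def _lengths_on_tree(tree: UnrootedTree, matrix: CharacterMatrix
                     ) -> np.ndarray:
    """Per-character minimum steps on ``tree`` (all characters, unweighted)."""
    present = tree.present_leaves()
    order, parent = tree.postorder(min(present))
    root = order[-1]
    nchar = matrix.nchar
    lengths = np.zeros(nchar)
    unord = np.flatnonzero(~matrix.ordered)
    orded = np.flatnonzero(matrix.ordered)

    if unord.size:
        lengths[unord] = _fitch_lengths(tree, matrix, unord, order, parent,
                                        root)
    if orded.size:
        lengths[orded] = _sankoff_lengths(tree, matrix, orded, order, parent,
                                          root)
    return lengths


def _leaf_masks(matrix: CharacterMatrix, cols: np.ndarray) -> np.ndarray:
    """Bitmask (ntax, ncols) of observed state sets; missing = all observed."""
    full = np.zeros(cols.size, dtype=np.int64)
    masks = np.zeros((matrix.ntax, cols.size), dtype=np.int64)
    for jj, j in enumerate(cols):
        for i in range(matrix.ntax):
            cell = matrix.cells[i][j]
            if cell is not None:
                bits = 0
                for s in cell:
                    bits |= 1 << s
                masks[i, jj] = bits
                full[jj] |= bits
        if full[jj] == 0:
            full[jj] = 1  # all-missing character: arbitrary single state
    for jj in range(cols.size):
        missing_rows = masks[:, jj] == 0
        masks[missing_rows, jj] = full[jj]
    return masks


def _fitch_lengths(tree, matrix, cols, order, parent, root) -> np.ndarray:
    masks = _leaf_masks(matrix, cols)
    state: dict[int, np.ndarray] = {}
    taxon_of = {i: i for i in range(matrix.ntax)}
    steps = np.zeros(cols.size)
    for node in order:
        if node in tree.leaves:
            state[node] = masks[taxon_of[node]].copy()
            continue
        kids = [nb for nb in tree.adj[node] if nb != parent[node]]
        acc = state[kids[0]]
        for kid in kids[1:]:
            inter = acc & state[kid]
            union = acc | state[kid]
            add = inter == 0
            steps += add
            acc = np.where(add, union, inter)
        state[node] = acc
    if root in tree.leaves and len(order) > 1:
        # rooted at a leaf: the loop scored the child subtree; add the
        # root leaf's own mismatch against its child's state set
        child = next(iter(tree.adj[root]))
        steps += (state[root] & state[child]) == 0
    return steps


def _sankoff_lengths(tree, matrix, cols, order, parent, root) -> np.ndarray:
    nstates = 1
    for j in cols:
        for i in range(matrix.ntax):
            cell = matrix.cells[i][j]
            if cell:
                nstates = max(nstates, max(cell) + 1)
    dist = np.abs(
        np.arange(nstates)[:, None] - np.arange(nstates)[None, :]
    ).astype(float)
    cost: dict[int, np.ndarray] = {}

    def leaf_cost(taxon: int) -> np.ndarray:
        c = np.full((cols.size, nstates), _BIG)
        for jj, j in enumerate(cols):
            cell = matrix.cells[taxon][j]
            if cell is None:
                c[jj, :] = 0.0
            else:
                for s in cell:
                    c[jj, s] = 0.0
        return c

    for node in order:
        if node in tree.leaves:
            cost[node] = leaf_cost(node)
            continue
        kids = [nb for nb in tree.adj[node] if nb != parent[node]]
        total = np.zeros((cols.size, nstates))
        for kid in kids:
            # min over child state s' of cost[kid][s'] + |s - s'|
            total += (cost[kid][:, None, :] + dist[None, :, :]).min(axis=2)
        cost[node] = total
    if root in tree.leaves and len(order) > 1:
        child = next(iter(tree.adj[root]))
        final = cost[root] + (cost[child][:, None, :]
                              + dist[None, :, :]).min(axis=2)
        return final.min(axis=1)
    return cost[root].min(axis=1)


@dataclass
class ParsimonyScore:
    """Tree length with ensemble homoplasy indices.

    length
        S, weighted sum of character lengths over active characters.
    min_steps, max_steps
        M (best possible on any tree) and G (star-tree maximum).
    ci, ri
        CI = M/S, RI = (G-S)/(G-M); CI is 1 by convention when S = 0
        and RI is 1 when G = M (both flagged by ``degenerate``).
    """

    length: float
    min_steps: float
    max_steps: float
    ci: float
    ri: float
    degenerate: bool = False


def _char_min_steps(matrix: CharacterMatrix, j: int) -> float:
    observed = [c for c in matrix.column(j) if c is not None]
    if not observed:
        return 0.0
    if matrix.ordered[j]:
        # a state every cell can realize cheaply: range of forced states
        lo = max(min(c) for c in observed)
        hi = min(max(c) for c in observed)
        return float(max(0, lo - hi)) if lo > hi else 0.0
    # each polymorphic cell may realize any member state, so M is one less
    # than the minimum number of states hitting every cell (exact: singleton
    # states are forced, then brute-force cover of the rest — state counts
    # in morphological matrices are tiny)
    singles = {next(iter(c)) for c in observed if len(c) == 1}
    uncovered = [c for c in observed if not (c & singles)]
    if not uncovered:
        return float(max(0, len(singles) - 1))
    import itertools

    pool = sorted(frozenset().union(*uncovered))
    for size in range(1, len(pool) + 1):
        for combo in itertools.combinations(pool, size):
            chosen = set(combo)
            if all(c & chosen for c in uncovered):
                return float(len(singles) + size - 1)
    return float(max(0, len(singles) - 1))  # unreachable


def _char_max_steps(matrix: CharacterMatrix, j: int) -> float:
    observed = [c for c in matrix.column(j) if c is not None]
    if not observed:
        return 0.0
    if matrix.ordered[j]:
        smax = max(max(c) for c in observed)
        best = min(
            sum(min(abs(x - s) for x in c) for c in observed)
            for s in range(smax + 1)
        )
        return float(best)
    union = frozenset().union(*observed)
    best = min(sum(1 for c in observed if s not in c) for s in union)
    return float(best)


def tree_length(tree: UnrootedTree, matrix: CharacterMatrix
                ) -> ParsimonyScore:
    """Score a tree: S, M, G, CI and RI over active characters."""
    missing_rows = [t for t in (tree.taxa[i] for i in tree.present_leaves())
                    if t not in matrix.taxa]
    if missing_rows:
        raise ValueError(f"tree leaves without matrix rows: {missing_rows}")
    present_names = [tree.taxa[i] for i in tree.present_leaves()]
    sub = matrix.subset_taxa(present_names)
    # re-index the tree onto the subset's taxon order
    work = _reindex_tree(tree, present_names)
    per_char = _lengths_on_tree(work, sub)
    active = matrix.active
    w = matrix.weights
    s = float(np.sum(per_char * w * active))
    m = sum(_char_min_steps(sub, j) * w[j] for j in np.flatnonzero(active))
    g = sum(_char_max_steps(sub, j) * w[j] for j in np.flatnonzero(active))
    degenerate = False
    if s == 0:
        ci, degenerate = 1.0, True
    else:
        ci = m / s
    if g == m:
        ri, degenerate = 1.0, True
    else:
        ri = (g - s) / (g - m)
    return ParsimonyScore(length=s, min_steps=float(m), max_steps=float(g),
                          ci=float(ci), ri=float(ri), degenerate=degenerate)


def _reindex_tree(tree: UnrootedTree, names: list[str]) -> UnrootedTree:
    """Relabel tree leaves to match a new taxon ordering."""
    if names == tree.taxa:
        return tree
    old_index = {t: i for i, t in enumerate(tree.taxa)}
    mapping = {}
    out = UnrootedTree(names)
    out._next_node = len(names)
    for node in tree.adj:
        if node < len(tree.taxa) and tree.adj[node]:
            mapping[node] = names.index(tree.taxa[node])
    for node in tree.adj:
        if node not in mapping and tree.adj[node]:
            mapping[node] = out.new_node()
    for u, v in tree.edges():
        if u in mapping and v in mapping:
            out.add_edge(mapping[u], mapping[v])
    return out


def _fast_length(tree: UnrootedTree, matrix: CharacterMatrix) -> float:
    """Weighted S only (search hot path); assumes tree.taxa == matrix.taxa."""
    per_char = _lengths_on_tree(tree, matrix)
    return float(np.sum(per_char * matrix.weights * matrix.active))


# ---------------------------------------------------------------------------
# Search


def wagner_build(matrix: CharacterMatrix,
                 addition_order: list[int] | None = None,
                 seed: int | None = None,
                 rng: random.Random | None = None) -> UnrootedTree:
    """Stepwise-addition Wagner tree.

    Taxa are inserted in ``addition_order`` (default: seeded random
    permutation), each on the branch minimizing total length; ties are
    broken by a seeded uniform choice.
    """
    n = matrix.ntax
    if n < 3:
        raise ValueError("Wagner build requires at least 3 taxa")
    rng = rng if rng is not None else random.Random(seed)
    if addition_order is None:
        addition_order = list(range(n))
        rng.shuffle(addition_order)
    first = addition_order[:3]
    tree = UnrootedTree.from_triplet(matrix.taxa, leaves=tuple(first))
    for leaf in addition_order[3:]:
        best_len = np.inf
        best_edges = []
        for edge in tree.edges():
            trial = tree.copy()
            trial.insert_leaf_on_edge(leaf, edge)
            length = _fast_length(trial, matrix)
            if length < best_len - 1e-9:
                best_len = length
                best_edges = [edge]
            elif length <= best_len + 1e-9:
                best_edges.append(edge)
        tree.insert_leaf_on_edge(leaf, rng.choice(best_edges))
    return tree


def _nni_neighbors(tree: UnrootedTree):
    for u, v in tree.edges():
        if u in tree.leaves or v in tree.leaves:
            continue
        u_subs = [x for x in tree.adj[u] if x != v]
        v_subs = [x for x in tree.adj[v] if x != u]
        for vx in v_subs:
            for ux in u_subs[1:]:
                t2 = tree.copy()
                t2.remove_edge(u, ux)
                t2.remove_edge(v, vx)
                t2.add_edge(u, vx)
                t2.add_edge(v, ux)
                yield t2
            # one swap with u_subs[0] covers the second NNI arrangement
        t2 = tree.copy()
        t2.remove_edge(u, u_subs[0])
        t2.remove_edge(v, v_subs[0])
        t2.add_edge(u, v_subs[0])
        t2.add_edge(v, u_subs[0])
        yield t2


def _split_at_edge(tree: UnrootedTree, edge):
    """Return (component_of_u, component_of_v) node sets after cutting edge."""
    u, v = edge
    comp_u = set()
    stack = [u]
    blocked = {v}
    while stack:
        node = stack.pop()
        if node in comp_u:
            continue
        comp_u.add(node)
        for nb in tree.adj[node]:
            if nb not in blocked:
                stack.append(nb)
    comp_v = set(n for n in tree.adj if tree.adj[n]) - comp_u
    return comp_u, comp_v


def _spr_neighbors(tree: UnrootedTree):
    """Subtree pruning-regrafting neighborhood."""
    for cut in tree.edges():
        for prune_side, keep_root in ((cut[0], cut[1]), (cut[1], cut[0])):
            comp_p, _ = _split_at_edge(tree, (prune_side, keep_root))
            if len([x for x in comp_p if x in tree.leaves]) == 0:
                continue
            base = tree.copy()
            base.remove_edge(prune_side, keep_root)
            # suppress the degree-2 node left on the kept side
            if keep_root not in base.leaves and base.degree(keep_root) == 2:
                a, b = base.adj[keep_root]
                base.remove_edge(keep_root, a)
                base.remove_edge(keep_root, b)
                del base.adj[keep_root]
                base.add_edge(a, b)
                removed = keep_root
            else:
                removed = None
            kept_nodes = set(
                n for n in base.adj if base.adj[n] or n in base.leaves
            ) - comp_p
            kept_edges = [
                (a, b) for a, b in base.edges()
                if a in kept_nodes and b in kept_nodes
            ]
            if len(kept_edges) < 2:
                continue
            for a, b in kept_edges:
                t2 = base.copy()
                mid = t2.new_node()
                t2.remove_edge(a, b)
                t2.add_edge(a, mid)
                t2.add_edge(mid, b)
                t2.add_edge(mid, prune_side)
                yield t2


def _tbr_neighbors(tree: UnrootedTree):
    """Tree bisection-reconnection: cut an internal edge, reconnect any
    edge pair across the two components."""
    for cut in tree.edges():
        u, v = cut
        comp_u, comp_v = _split_at_edge(tree, cut)
        leaves_u = [x for x in comp_u if x in tree.leaves]
        leaves_v = [x for x in comp_v if x in tree.leaves]
        if not leaves_u or not leaves_v:
            continue
        base = tree.copy()
        base.remove_edge(u, v)
        for side_root, comp in ((u, comp_u), (v, comp_v)):
            if side_root not in base.leaves and base.degree(side_root) == 2:
                a, b = tuple(base.adj[side_root])
                base.remove_edge(side_root, a)
                base.remove_edge(side_root, b)
                del base.adj[side_root]
                base.add_edge(a, b)
                comp.discard(side_root)
        def comp_edges(comp):
            return [(a, b) for a, b in base.edges()
                    if a in comp and b in comp]

        def attach_points(comp, root_candidates):
            pts = comp_edges(comp)
            if pts:
                return [("edge", e) for e in pts]
            # single node component (one leaf)
            (lone,) = [x for x in comp if base.adj.get(x) is not None
                       and x in tree.leaves] or [next(iter(comp))]
            return [("node", lone)]

        for kind_a, pa in attach_points(comp_u, u):
            for kind_b, pb in attach_points(comp_v, v):
                t2 = base.copy()
                if kind_a == "edge":
                    a1, a2 = pa
                    na = t2.new_node()
                    t2.remove_edge(a1, a2)
                    t2.add_edge(a1, na)
                    t2.add_edge(na, a2)
                else:
                    na = pa
                if kind_b == "edge":
                    b1, b2 = pb
                    nb = t2.new_node()
                    t2.remove_edge(b1, b2)
                    t2.add_edge(b1, nb)
                    t2.add_edge(nb, b2)
                else:
                    nb = pb
                t2.add_edge(na, nb)
                yield t2


_NEIGHBORHOODS = {
    "nni": _nni_neighbors,
    "spr": _spr_neighbors,
    "tbr": _tbr_neighbors,
}


def branch_swap_search(start_trees, matrix: CharacterMatrix,
                       strategy: str = "tbr", hold: int = 10,
                       max_rounds: int = 50,
                       seed: int | None = None) -> tuple[list, float]:
    """Hill-climb each start tree through the chosen swap neighborhood.

    Keeps up to ``hold`` distinct equally best trees per replicate, pools
    and deduplicates across replicates, and returns
    ``(best_trees, best_length)`` at the overall minimum length found.
    """
    strategy = strategy.lower()
    if strategy not in _NEIGHBORHOODS:
        raise ValueError(f"unknown swap strategy {strategy!r}")
    neighbors = _NEIGHBORHOODS[strategy]
    pooled: dict[frozenset, UnrootedTree] = {}
    pooled_len = np.inf
    for start in start_trees:
        best = {start.topology_key(): start.copy()}
        best_len = _fast_length(start, matrix)
        swapped: set[frozenset] = set()
        for _ in range(max_rounds):
            improved = False
            for key in list(best):
                if key in swapped:
                    continue
                swapped.add(key)
                for cand in neighbors(best[key]):
                    length = _fast_length(cand, matrix)
                    if length < best_len - 1e-9:
                        best = {cand.topology_key(): cand}
                        best_len = length
                        swapped = set()
                        improved = True
                        break
                    if length <= best_len + 1e-9 and len(best) < hold:
                        ckey = cand.topology_key()
                        if ckey not in best:
                            best[ckey] = cand
                if improved:
                    break
            if not improved and swapped >= set(best):
                break
        if best_len < pooled_len - 1e-9:
            pooled = dict(best)
            pooled_len = best_len
        elif abs(best_len - pooled_len) <= 1e-9:
            pooled.update(best)
    return list(pooled.values()), float(pooled_len)


class ParsimonySearch(BaseEstimator):
    """Heuristic maximum-parsimony search estimator.

    Random-addition Wagner builds followed by branch swapping; ``fit``
    stores the pooled most parsimonious trees, their length, and the
    ensemble CI/RI.

    Parameters
    ----------
    n_replicates : addition-sequence replicates.
    hold : equally best trees kept per replicate.
    strategy : "tbr", "spr" or "nni".
    random_state : seed for addition orders and tie-breaking.

    Attributes (fitted)
    -------------------
    best_trees_ : list of UnrootedTree at the best length.
    best_length_ : float
    score_ : ParsimonyScore of the first best tree.
    """

    def __init__(self, n_replicates: int = 100, hold: int = 10,
                 strategy: str = "tbr", max_rounds: int = 50,
                 random_state: int | None = None):
        self.n_replicates = n_replicates
        self.hold = hold
        self.strategy = strategy
        self.max_rounds = max_rounds
        self.random_state = random_state

    def fit(self, X: CharacterMatrix, y=None):
        matrix = X
        rng = random.Random(self.random_state)
        pooled: dict[frozenset, UnrootedTree] = {}
        pooled_len = np.inf
        for _ in range(self.n_replicates):
            start = wagner_build(matrix, rng=rng)
            trees, length = branch_swap_search(
                [start], matrix, strategy=self.strategy, hold=self.hold,
                max_rounds=self.max_rounds,
            )
            if length < pooled_len - 1e-9:
                pooled = {t.topology_key(): t for t in trees}
                pooled_len = length
            elif abs(length - pooled_len) <= 1e-9:
                for t in trees:
                    pooled.setdefault(t.topology_key(), t)
        self.best_trees_ = list(pooled.values())
        self.best_length_ = float(pooled_len)
        self.score_ = tree_length(self.best_trees_[0], matrix)
        return self

    def exhaustive_best_length(self, matrix: CharacterMatrix) -> float:
        """Exact minimum length by exhaustive topology enumeration (small n)."""
        best = np.inf
        for tree in all_unrooted_topologies(matrix.ntax, matrix.taxa):
            best = min(best, _fast_length(tree, matrix))
        return float(best)
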