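"""Unrooted phylogenetic trees: topology, bipartitions, Newick, consensus.

Trees are unrooted with leaves bijective to taxon names; internal nodes
have degree >= 3 (degree-2 nodes are suppressed on construction edits).
Topologies are compared through their sets of non-trivial bipartitions, the
currency of the strict and majority-rule consensus operators.
"""

from __future__ import annotations

from collections import Counter

__all__ = [
    "UnrootedTree",
    "strict_consensus",
    "majority_rule_consensus",
    "parse_newick",
    "all_unrooted_topologies",
]


class UnrootedTree:
    """Mutable unrooted tree over integer nodes; leaves 0..n_leaves-1.

    ``taxa`` maps leaf index -> taxon name.  ``support`` optionally maps a
    bipartition (frozenset of leaf indices, the side without leaf 0) to a
    clade frequency, for consensus output.
    """

    def __init__(self, taxa: list[str]):
        self.taxa = list(taxa)
        self.adj: dict[int, set[int]] = {i: set() for i in range(len(taxa))}
        self._next_node = len(taxa)
        self.support: dict[frozenset, float] = {}

    # -- construction ------------------------------------------------------

    @classmethod
    def star(cls, taxa: list[str]) -> "UnrootedTree":
        tree = cls(taxa)
        hub = tree.new_node()
        for leaf in range(len(taxa)):
            tree.add_edge(leaf, hub)
        return tree

    @classmethod
    def from_triplet(cls, taxa: list[str], leaves=(0, 1, 2)) -> "UnrootedTree":
        """The unique unrooted tree on three of the taxa."""
        tree = cls(taxa)
        hub = tree.new_node()
        for leaf in leaves:
            tree.add_edge(leaf, hub)
        return tree

    def new_node(self) -> int:
        node = self._next_node
        self._next_node += 1
        self.adj[node] = set()
        return node

    def add_edge(self, u: int, v: int) -> None:
        self.adj[u].add(v)
        self.adj[v].add(u)

    def remove_edge(self, u: int, v: int) -> None:
        self.adj[u].discard(v)
        self.adj[v].discard(u)

    def copy(self) -> "UnrootedTree":
        other = UnrootedTree(self.taxa)
        other.adj = {k: set(v) for k, v in self.adj.items()}
        other._next_node = self._next_node
        other.support = dict(self.support)
        return other

    @property
    def n_leaves(self) -> int:
        return len(self.taxa)

    @property
    def leaves(self) -> range:
        return range(len(self.taxa))

    def nodes(self):
        return self.adj.keys()

    def edges(self) -> list[tuple[int, int]]:
        return [(u, v) for u in self.adj for v in self.adj[u] if u < v]

    def present_leaves(self) -> list[int]:
        return [i for i in self.leaves if self.adj[i]]

    def degree(self, node: int) -> int:
        return len(self.adj[node])

    # -- edits -------------------------------------------------------------

    def insert_leaf_on_edge(self, leaf: int, edge: tuple[int, int]) -> int:
        """Split ``edge`` with a new node and hang ``leaf`` from it."""
        u, v = edge
        self.remove_edge(u, v)
        mid = self.new_node()
        self.add_edge(u, mid)
        self.add_edge(mid, v)
        self.add_edge(leaf, mid)
        return mid

    def remove_leaf(self, leaf: int) -> None:
        """Detach a leaf and suppress the degree-2 node it leaves behind."""
        (attach,) = self.adj[leaf]
        self.remove_edge(leaf, attach)
        if self.degree(attach) == 2:
            a, b = self.adj[attach]
            self.remove_edge(attach, a)
            self.remove_edge(attach, b)
            del self.adj[attach]
            self.add_edge(a, b)

    def suppress_degree_two(self) -> None:
        changed = True
        while changed:
            changed = False
            for node in list(self.adj):
                if node not in self.leaves and self.degree(node) == 2:
                    a, b = self.adj[node]
                    self.remove_edge(node, a)
                    self.remove_edge(node, b)
                    del self.adj[node]
                    self.add_edge(a, b)
                    changed = True

    # -- structure queries -------------------------------------------------

    def postorder(self, root: int | None = None):
        """Iterative postorder; returns (order, parent) with ``order`` a list
        of nodes, children before parents, rooted at ``root`` (default: leaf
        with smallest index present)."""
        if root is None:
            root = min(self.present_leaves())
        parent = {root: None}
        order = []
        stack = [root]
        while stack:
            node = stack.pop()
            order.append(node)
            for nb in self.adj[node]:
                if nb != parent[node]:
                    parent[nb] = node
                    stack.append(nb)
        order.reverse()
        return order, parent

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each canonicalized as the leaf side not
        containing the smallest present leaf."""
        present = self.present_leaves()
        if len(present) < 4:
            return set()
        anchor = min(present)
        order, parent = self.postorder(anchor)
        below: dict[int, frozenset] = {}
        splits: set[frozenset] = set()
        all_leaves = frozenset(present)
        for node in order:
            if node in self.leaves:
                below[node] = frozenset([node])
            else:
                kids = [nb for nb in self.adj[node] if nb != parent[node]]
                below[node] = frozenset().union(*(below[k] for k in kids))
            if parent[node] is not None:
                side = below[node]
                if 2 <= len(side) <= len(present) - 2:
                    splits.add(side if anchor not in side
                               else all_leaves - side)
        return splits

    def topology_key(self) -> frozenset:
        """Canonical hashable key: leaf set plus bipartition set."""
        return frozenset(
            {frozenset(self.present_leaves())} | self.bipartitions()
        )

    def is_binary(self) -> bool:
        return all(
            self.degree(n) == 3
            for n in self.adj if n not in self.leaves and self.adj[n]
        )

    # -- newick ------------------------------------------------------------

    def newick(self, with_support: bool = False) -> str:
        present = self.present_leaves()
        if len(present) == 1:
            return f"{self.taxa[present[0]]};"
        root = next(
            (n for n in self.adj if n not in self.leaves and self.adj[n]),
            present[0],
        )
        order, parent = self.postorder(root)
        below: dict[int, frozenset] = {}
        label: dict[int, str] = {}
        for node in order:
            if node in self.leaves:
                below[node] = frozenset([node])
                label[node] = _quote_name(self.taxa[node])
            else:
                kids = [nb for nb in self.adj[node] if nb != parent[node]]
                below[node] = frozenset().union(*(below[k] for k in kids))
                inner = ",".join(label[k] for k in kids)
                sup = ""
                if with_support and parent[node] is not None:
                    side = below[node]
                    anchor = min(present)
                    key = (side if anchor not in side
                           else frozenset(present) - side)
                    if key in self.support:
                        sup = f"{self.support[key]:g}"
                label[node] = f"({inner}){sup}"
        return label[root] + ";"


def _quote_name(name: str) -> str:
    if any(ch in name for ch in " (),:;[]'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def parse_newick(text: str, taxa: list[str] | None = None) -> UnrootedTree:
    """Parse a Newick string into an UnrootedTree (branch lengths ignored).

    If ``taxa`` is given, leaf names must come from it (order defines leaf
    indices); otherwise taxa are taken in order of appearance.
    """
    import dendropy

    dt = dendropy.Tree.get(data=text, schema="newick")
    names = [lf.taxon.label for lf in dt.leaf_node_iter()]
    if taxa is None:
        taxa = names
    index = {name: i for i, name in enumerate(taxa)}
    missing = [n for n in names if n not in index]
    if missing:
        raise ValueError(f"unknown taxa in newick: {missing}")
    tree = UnrootedTree(taxa)
    node_map: dict = {}
    for node in dt.preorder_node_iter():
        if node.is_leaf():
            node_map[node] = index[node.taxon.label]
        else:
            node_map[node] = tree.new_node()
        if node.parent_node is not None:
            tree.add_edge(node_map[node.parent_node], node_map[node])
    tree.suppress_degree_two()
    return tree


def all_unrooted_topologies(n: int, taxa: list[str]):
    """Yield every unrooted binary topology on the first n taxa.

    (2n-5)!! trees; usable as an exhaustive oracle up to n ~ 8.
    """
    base = UnrootedTree.from_triplet(taxa, leaves=(0, 1, 2))
    stack = [(base, 3)]
    while stack:
        tree, nxt = stack.pop()
        if nxt == n:
            yield tree
            continue
        for edge in tree.edges():
            t2 = tree.copy()
            t2.insert_leaf_on_edge(nxt, edge)
            stack.append((t2, nxt + 1))


# ---------------------------------------------------------------------------
# Consensus


def _check_leaf_sets(trees: list[UnrootedTree]) -> frozenset:
    if not trees:
        raise ValueError("consensus of an empty tree set")
    leaf_set = frozenset(trees[0].present_leaves())
    for t in trees[1:]:
        if frozenset(t.present_leaves()) != leaf_set:
            raise ValueError("consensus requires identical leaf sets")
        if t.taxa != trees[0].taxa:
            raise ValueError("consensus requires identical taxon indexing")
    return leaf_set


def _build_from_clades(taxa, leaf_set, clades, freqs) -> UnrootedTree:
    """Assemble a tree from nested clades (sides not containing the anchor)."""
    tree = UnrootedTree(taxa)
    root = tree.new_node()
    ordered = sorted(clades, key=len, reverse=True)
    clade_node = {}
    parent_clade: dict[frozenset, frozenset | None] = {}
    for clade in ordered:
        best = None
        for other in ordered:
            if other is clade or len(other) <= len(clade):
                continue
            if clade <= other and (best is None or len(other) < len(best)):
                best = other
        parent_clade[clade] = best
    for clade in ordered:
        node = tree.new_node()
        clade_node[clade] = node
        up = parent_clade[clade]
        tree.add_edge(node, clade_node[up] if up is not None else root)
        tree.support[clade] = freqs[clade]
    for leaf in sorted(leaf_set):
        best = None
        for clade in ordered:
            if leaf in clade and (best is None or len(clade) < len(best)):
                best = clade
        tree.add_edge(leaf, clade_node[best] if best is not None else root)
    tree.suppress_degree_two()
    return tree


def strict_consensus(trees: list[UnrootedTree]) -> UnrootedTree:
    """Tree containing exactly the bipartitions shared by every input."""
    leaf_set = _check_leaf_sets(trees)
    common = set.intersection(*(set(t.bipartitions()) for t in trees))
    return _build_from_clades(
        trees[0].taxa, leaf_set, common, {c: 1.0 for c in common}
    )


def majority_rule_consensus(trees: list[UnrootedTree],
                            threshold: float = 0.5) -> UnrootedTree:
    """Tree of bipartitions occurring in a strict majority (> threshold).

    Clade frequencies are recorded in ``support`` and printed as internal
    node labels by ``newick(with_support=True)``.  With unanimous input the
    result equals the strict consensus; a clade in exactly half of an even
    tree set is excluded.
    """
    if not 0.5 <= threshold < 1.0:
        raise ValueError("threshold must lie in [0.5, 1)")
    leaf_set = _check_leaf_sets(trees)
    counts: Counter = Counter()
    for t in trees:
        counts.update(t.bipartitions())
    n = len(trees)
    keep = {c: k / n for c, k in counts.items() if k / n > threshold}
    return _build_from_clades(trees[0].taxa, leaf_set, set(keep), keep)
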