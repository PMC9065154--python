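import pytest

import clawmorph as cm
from clawmorph.parsimony import (
    parse_tnt,
    read_matrix,
    write_tnt,
)
from clawmorph.trees import UnrootedTree, parse_newick

from .oracles import brute_force_character_length

TAXA4 = ["a", "b", "c", "d"]


def _two_leaf_tree():
    t = UnrootedTree(["a", "b"])
    t.add_edge(0, 1)
    return t


class TestMatrixIO:
    TNT_TOY = """xread
'toy matrix'
3 4
a 010
b 0?0
c [01]11
d 1-1
;
ccode + 1;
ccode ] 2;
proc /;
"""

    def test_tnt_toy_parse(self, tmp_path):
        p = tmp_path / "toy.tnt"
        p.write_text(self.TNT_TOY)
        m = read_matrix(p)
        assert m.ntax == 4 and m.nchar == 3
        assert m.taxa == TAXA4
        assert m.cells[2][0] == frozenset({0, 1})  # [01] polymorphism
        assert m.cells[1][1] is None  # '?' missing
        assert m.cells[3][1] is None  # '-' scored as missing
        # ccode is 0-based on disk: character index 1 -> second character
        assert m.ordered.tolist() == [False, True, False]
        assert m.active.tolist() == [True, True, False]

    def test_tnt_one_based_flag(self, tmp_path):
        p = tmp_path / "toy.tnt"
        p.write_text(self.TNT_TOY)
        m = read_matrix(p, tnt_zero_based=False)
        assert m.ordered.tolist() == [True, False, False]

    def test_sidecar_overrides(self, tmp_path):
        p = tmp_path / "toy.tnt"
        p.write_text(self.TNT_TOY)
        m = read_matrix(p, ordered=[3], excluded=[1])
        assert m.ordered.tolist() == [False, False, True]
        assert m.active.tolist() == [False, True, False]

    def test_nexus_equivalence(self, tmp_path):
        nexus = """#NEXUS
BEGIN DATA;
DIMENSIONS NTAX=4 NCHAR=3;
FORMAT MISSING=? GAP=-;
MATRIX
a 010
b 0?0
c (01)11
d 1-1
;
END;
BEGIN ASSUMPTIONS;
TYPESET * UNTITLED = ord: 2;
EXSET * UNTITLED = 3;
END;
"""
        p = tmp_path / "toy.nex"
        p.write_text(nexus)
        m = read_matrix(p)
        tnt = parse_tnt(self.TNT_TOY)
        assert m.taxa == tnt.taxa
        assert m.cells == tnt.cells
        assert m.ordered.tolist() == tnt.ordered.tolist()
        assert m.active.tolist() == tnt.active.tolist()

    def test_tnt_round_trip(self, tmp_path):
        tree = cm.random_binary_tree([f"x{i}" for i in range(6)], 1)
        m, _, _ = cm.generate_character_matrix(tree, 12, seed=3)
        m.ordered[2] = True
        m.active[5] = False
        p = tmp_path / "rt.tnt"
        write_tnt(m, p)
        back = read_matrix(p)
        assert back.taxa == m.taxa
        assert back.cells == m.cells
        assert back.ordered.tolist() == m.ordered.tolist()
        assert back.active.tolist() == m.active.tolist()

    def test_malformed_matrices_rejected(self):
        with pytest.raises(ValueError, match="header says"):
            parse_tnt("xread\n3 2\na 010\nb 01\n;\n")
        with pytest.raises(ValueError, match="characters"):
            parse_tnt("xread\n3 2\na 010\nb 01\n;\n".replace("b 01", "b 0100"))
        with pytest.raises(ValueError, match="unknown state symbol"):
            cm.CharacterMatrix.from_strings(["a"], ["0!1"])
        with pytest.raises(ValueError, match="duplicate"):
            cm.CharacterMatrix.from_strings(["a", "a"], ["0", "1"])


class TestCharacterLength:
    def test_single_origin_vs_forced_homoplasy(self):
        col = [frozenset([s]) for s in (0, 0, 1, 1)]
        matched = parse_newick("((a,b),(c,d));", TAXA4)
        mismatched = parse_newick("((a,c),(b,d));", TAXA4)
        assert cm.character_length(matched, col) == 1
        assert cm.character_length(mismatched, col) == 2

    def test_additive_step_count_on_two_leaves(self):
        tree = _two_leaf_tree()
        col = [frozenset([0]), frozenset([2])]
        assert cm.character_length(tree, col, ordered=True) == 2
        assert cm.character_length(tree, col, ordered=False) == 1

    def test_missing_and_polymorphism_cost_nothing_extra(self):
        tree = parse_newick("((a,b),(c,d));", TAXA4)
        col = [frozenset([0]), None, frozenset([0, 1]), frozenset([1])]
        assert cm.character_length(tree, col) == 1

    def test_matches_exhaustive_oracle_on_random_cases(self, rng):
        mismatches = 0
        for trial in range(50):
            n = int(rng.integers(4, 7))
            taxa = [f"t{i}" for i in range(n)]
            tree = cm.random_binary_tree(taxa, seed=trial)
            col = []
            for _ in range(n):
                r = rng.random()
                if r < 0.15:
                    col.append(None)
                elif r < 0.3:
                    col.append(
                        frozenset(
                            rng.choice(4, size=2, replace=False).tolist()
                        )
                    )
                else:
                    col.append(frozenset([int(rng.integers(0, 4))]))
            for ordered in (False, True):
                mine = cm.character_length(tree, col, ordered=ordered)
                oracle = brute_force_character_length(tree, col, ordered)
                if mine != oracle:
                    mismatches += 1
        assert mismatches == 0


class TestTreeLength:
    def test_invariant_matrix_scores_zero_with_flag(self):
        tree = parse_newick("((a,b),(c,d));", TAXA4)
        m = cm.CharacterMatrix.from_strings(TAXA4, ["00", "00", "00", "00"])
        score = cm.tree_length(tree, m)
        assert score.length == 0
        assert score.ci == 1.0 and score.degenerate

    def test_worked_identity_binary_character(self):
        tree = parse_newick("((a,c),(b,d));", TAXA4)
        m = cm.CharacterMatrix.from_strings(TAXA4, ["0", "0", "1", "1"])
        score = cm.tree_length(tree, m)
        assert (score.length, score.min_steps, score.max_steps) == (2, 1, 2)
        assert score.ci == 0.5
        assert score.ri == 0.0

    def test_bounds_hold_on_random_trees(self, rng):
        taxa = [f"t{i}" for i in range(7)]
        true = cm.random_binary_tree(taxa, seed=5)
        m, _, _ = cm.generate_character_matrix(
            true, 20, change_prob=0.3, seed=11
        )
        for rep in range(5):
            t = cm.random_binary_tree(taxa, seed=100 + rep)
            sc = cm.tree_length(t, m)
            assert sc.min_steps <= sc.length <= sc.max_steps
            assert 0 < sc.ci <= 1
            assert 0 <= sc.ri <= 1

    def test_invariant_to_rerooting_and_taxon_order(self):
        taxa = [f"t{i}" for i in range(6)]
        tree = cm.random_binary_tree(taxa, seed=2)
        m, _, _ = cm.generate_character_matrix(tree, 15, seed=9)
        base = cm.tree_length(tree, m).length
        # same topology expressed from different newick rootings
        nwk = tree.newick()
        t2 = parse_newick(nwk, taxa)
        assert cm.tree_length(t2, m).length == base
        # shuffle matrix taxon order
        perm = [3, 1, 5, 0, 4, 2]
        m2 = m.subset_taxa([taxa[i] for i in perm])
        assert cm.tree_length(tree, m2).length == base

    def test_excluded_characters_never_contribute(self):
        tree = parse_newick("((a,b),(c,d));", TAXA4)
        m = cm.CharacterMatrix.from_strings(
            TAXA4, ["01", "01", "10", "10"], excluded_1based=[2]
        )
        assert cm.tree_length(tree, m).length == 1

    def test_leaf_without_row_rejected(self):
        tree = parse_newick("((a,b),(c,e));", ["a", "b", "c", "e"])
        m = cm.CharacterMatrix.from_strings(TAXA4, ["0", "0", "1", "1"])
        with pytest.raises(ValueError, match="without matrix rows"):
            cm.tree_length(tree, m)
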