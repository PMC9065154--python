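import pytest

import clawmorph as cm
from clawmorph.parsimony import ParsimonySearch, branch_swap_search, wagner_build
from clawmorph.trees import (
    majority_rule_consensus,
    parse_newick,
    strict_consensus,
)

from .oracles import exhaustive_min_length

TAXA4 = ["a", "b", "c", "d"]


class TestWagnerBuild:
    def test_three_taxa_unique_tree(self):
        m = cm.CharacterMatrix.from_strings(["a", "b", "c"], ["0", "1", "1"])
        tree = wagner_build(m, seed=0)
        assert sorted(tree.present_leaves()) == [0, 1, 2]
        assert tree.bipartitions() == set()

    def test_congruent_characters_recover_split(self):
        m = cm.CharacterMatrix.from_strings(
            TAXA4, ["0000", "0000", "1111", "1111"]
        )
        expected = parse_newick("((a,b),(c,d));", TAXA4).bipartitions()
        for order in ([0, 1, 2, 3], [3, 1, 0, 2], [2, 0, 3, 1]):
            tree = wagner_build(m, addition_order=order, seed=1)
            assert tree.bipartitions() == expected

    def test_seed_determinism(self):
        tree = cm.random_binary_tree([f"t{i}" for i in range(8)], seed=4)
        m, _, _ = cm.generate_character_matrix(tree, 20, seed=4)
        a = wagner_build(m, seed=77)
        b = wagner_build(m, seed=77)
        assert a.topology_key() == b.topology_key()


class TestBranchSwap:
    def test_optimal_start_unchanged(self):
        taxa = [f"t{i}" for i in range(5)]
        true = cm.random_binary_tree(taxa, seed=8)
        m, _, _ = cm.generate_character_matrix(
            true, 30, missing_prob=0.0, seed=8, exactly_one_change=True
        )
        trees, length = branch_swap_search([true], m, strategy="tbr", hold=5)
        assert length == cm.tree_length(true, m).length
        assert any(t.bipartitions() == true.bipartitions() for t in trees)

    @pytest.mark.parametrize("strategy", ["nni", "spr", "tbr"])
    def test_reaches_exhaustive_minimum(self, strategy):
        taxa = [f"t{i}" for i in range(6)]
        true = cm.random_binary_tree(taxa, seed=3)
        m, _, _ = cm.generate_character_matrix(
            true, 10, change_prob=0.25, missing_prob=0.1, seed=5
        )
        exact = exhaustive_min_length(m)
        search = ParsimonySearch(
            n_replicates=10, hold=10, strategy=strategy, random_state=0
        ).fit(m)
        assert search.best_length_ == exact

    def test_hold_one_retains_single_tree_per_replicate(self):
        m = cm.CharacterMatrix.from_strings(
            TAXA4, ["0", "0", "1", "1"]
        )
        start = wagner_build(m, seed=0)
        trees, _ = branch_swap_search([start], m, strategy="tbr", hold=1)
        assert len(trees) == 1

    def test_replicates_pool_and_deduplicate(self):
        taxa = [f"t{i}" for i in range(6)]
        true = cm.random_binary_tree(taxa, seed=13)
        m, _, _ = cm.generate_character_matrix(true, 8, seed=13)
        s = ParsimonySearch(n_replicates=6, hold=10, random_state=1).fit(m)
        keys = [t.topology_key() for t in s.best_trees_]
        assert len(keys) == len(set(keys))
        lengths = {cm.tree_length(t, m).length for t in s.best_trees_}
        assert lengths == {s.best_length_}


class TestRecovery:
    def test_no_homoplasy_recovers_truth_with_perfect_indices(self):
        taxa = [f"t{i}" for i in range(8)]
        true = cm.random_binary_tree(taxa, seed=21)
        m, _, changes = cm.generate_character_matrix(
            true, 60, missing_prob=0.0, seed=21, exactly_one_change=True
        )
        s = ParsimonySearch(n_replicates=2, hold=5, random_state=0).fit(m)
        assert s.best_length_ == changes.sum()
        assert cm.tree_length(true, m).length == s.best_length_
        cons = strict_consensus(s.best_trees_)
        assert cons.bipartitions() <= true.bipartitions()
        assert s.score_.ci == 1.0
        assert s.score_.ri == 1.0


class TestConsensus:
    def test_identical_trees_consensus_is_that_tree(self):
        t = parse_newick("((a,b),(c,d),e);", list("abcde"))
        cons = strict_consensus([t.copy(), t.copy(), t.copy()])
        assert cons.bipartitions() == t.bipartitions()

    def test_conflict_collapses_to_star(self):
        t1 = parse_newick("((a,b),c,d);", TAXA4)
        t2 = parse_newick("((a,c),b,d);", TAXA4)
        cons = strict_consensus([t1, t2])
        assert cons.bipartitions() == set()

    def test_star_is_absorbing(self):
        t1 = parse_newick("((a,b),(c,d),e);", list("abcde"))
        star = cm.UnrootedTree.star(list("abcde"))
        cons = strict_consensus([t1, star])
        assert cons.bipartitions() == set()

    def test_majority_frequency_annotation(self):
        trees = [
            parse_newick("((a,b),(c,d),e);", list("abcde")),
            parse_newick("((a,b),(c,e),d);", list("abcde")),
            parse_newick("((a,c),(b,d),e);", list("abcde")),
        ]
        cons = majority_rule_consensus(trees)
        ab = frozenset({2, 3, 4})  # side not containing leaf 0
        assert ab in cons.bipartitions()
        assert cons.support[ab] == pytest.approx(2 / 3)

    def test_unanimous_majority_equals_strict(self):
        trees = [
            parse_newick("((a,b),(c,d),e);", list("abcde")) for _ in range(4)
        ]
        assert (
            majority_rule_consensus(trees).bipartitions()
            == strict_consensus(trees).bipartitions()
        )

    def test_exact_half_excluded(self):
        trees = [
            parse_newick("((a,b),(c,d));", TAXA4),
            parse_newick("((a,c),(b,d));", TAXA4),
        ]
        assert majority_rule_consensus(trees).bipartitions() == set()

    def test_idempotent_and_order_invariant(self):
        trees = [
            parse_newick("((a,b),(c,d),e);", list("abcde")),
            parse_newick("((a,b),c,(d,e));", list("abcde")),
            parse_newick("((a,b),(c,e),d);", list("abcde")),
        ]
        cons1 = majority_rule_consensus(trees)
        cons2 = majority_rule_consensus(trees[::-1])
        assert cons1.bipartitions() == cons2.bipartitions()
        again = strict_consensus([cons1.copy(), cons1.copy()])
        assert again.bipartitions() == cons1.bipartitions()

    def test_leaf_set_mismatch_rejected(self):
        t1 = parse_newick("((a,b),(c,d));", TAXA4)
        t2 = parse_newick("((a,b),(c,e));", ["a", "b", "c", "e"])
        with pytest.raises(ValueError, match="identical"):
            strict_consensus([t1, t2])

    def test_against_dendropy_consensus(self):
        import dendropy

        taxa = [f"t{i}" for i in range(7)]
        trees = [cm.random_binary_tree(taxa, seed=s) for s in range(9)]
        mine = majority_rule_consensus(trees, threshold=0.5)
        tns = dendropy.TaxonNamespace()
        dtrees = dendropy.TreeList(
            [
                dendropy.Tree.get(
                    data=t.newick(), schema="newick",
                    taxon_namespace=tns,
                )
                for t in trees
            ]
        )
        dcons = dtrees.consensus(min_freq=0.5)
        dcons_mine = parse_newick(
            dcons.as_string(schema="newick").replace("[&R] ", ""), taxa
        )
        assert mine.bipartitions() == dcons_mine.bipartitions()


class TestNewick:
    def test_round_trip_topology(self):
        taxa = [f"t{i}" for i in range(9)]
        tree = cm.random_binary_tree(taxa, seed=17)
        back = parse_newick(tree.newick(), taxa)
        assert back.bipartitions() == tree.bipartitions()

    def test_quoting_awkward_names(self):
        taxa = ["Nothronychus graffami", "B(issekty)", "plain"]
        tree = cm.UnrootedTree.from_triplet(taxa)
        back = parse_newick(tree.newick(), taxa)
        assert sorted(back.present_leaves()) == [0, 1, 2]
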