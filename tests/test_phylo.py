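import dendropy
import numpy as np
import pytest

from _oracles import (
    brute_force_parsimony,
    enumerate_unrooted,
    tree_to_newick,
    unrooted_splits,
)
from biogap import phylo
from biogap.phylo import MISSING, MRPMatrix
from biogap.synthetic_data import random_unit_tree


def random_newick(rng, labels):
    return phylo.write_newick(random_unit_tree(list(labels), rng))


class TestNewickIO:
    def test_small_tree_structure(self):
        t = phylo.read_newick("((A,B),C);")
        assert sorted(phylo.tip_labels(t)) == ["A", "B", "C"]
        assert sum(1 for n in t.preorder_internal_node_iter()) == 2

    def test_round_trip_identity_on_random_trees(self, rng):
        labels = [f"t{i}" for i in range(12)]
        for _ in range(100):
            nwk = random_newick(rng, labels)
            again = phylo.write_newick(phylo.read_newick(nwk))
            assert unrooted_splits(nwk, labels) == unrooted_splits(again, labels)

    def test_unlabeled_internal_nodes_accepted(self):
        t = phylo.read_newick("((A,B)x,(C,D));")
        assert len(phylo.tip_labels(t)) == 4

    def test_malformed_raises(self):
        with pytest.raises(ValueError, match="malformed"):
            phylo.read_newick("((A,B,C;")


class TestPrune:
    def test_simple_prune(self):
        t = phylo.prune_to_taxa(phylo.read_newick("((A,B),C);"), {"A", "B"})
        assert sorted(phylo.tip_labels(t)) == ["A", "B"]

    def test_prune_to_all_is_identity(self):
        nwk = "((A,B),(C,D));"
        t = phylo.prune_to_taxa(phylo.read_newick(nwk), {"A", "B", "C", "D"})
        labels = ["A", "B", "C", "D"]
        assert unrooted_splits(phylo.write_newick(t), labels) == unrooted_splits(
            nwk, labels
        )

    def test_pruned_topology_is_restriction_of_original(self, rng):
        labels = [f"t{i}" for i in range(10)]
        for _ in range(10):
            nwk = random_newick(rng, labels)
            keep = sorted(rng.choice(labels, size=6, replace=False))
            pruned = phylo.prune_to_taxa(phylo.read_newick(nwk), keep)
            got = unrooted_splits(phylo.write_newick(pruned), keep)
            keep_set = set(keep)
            restricted = set()
            for side in unrooted_splits(nwk, labels):
                s = frozenset(side & keep_set)
                o = frozenset(keep_set - s)
                if 1 < len(s) < len(keep) - 1:
                    restricted.add(min(s, o, key=sorted))
            assert got == frozenset(restricted)

    def test_no_overlap_rejected(self):
        with pytest.raises(ValueError):
            phylo.prune_to_taxa(phylo.read_newick("((A,B),C);"), {"X"})


class TestMRPEncode:
    def test_single_tree_single_character(self):
        m = phylo.mrp_encode([phylo.read_newick("((A,B),C);")])
        assert m.taxa == ["A", "B", "C"]
        assert m.matrix.T.tolist() == [[1, 1, 0]]

    def test_two_trees_question_marks(self):
        m = phylo.mrp_encode(
            [phylo.read_newick("((A,B),C);"), phylo.read_newick("((B,C),D);")]
        )
        assert m.taxa == ["A", "B", "C", "D"]
        cols = m.matrix.T.tolist()
        assert cols[0] == [1, 1, 0, MISSING]
        assert cols[1] == [MISSING, 1, 1, 0]

    def test_star_tree_contributes_nothing(self):
        m = phylo.mrp_encode([phylo.read_newick("(A,B,C,D);")])
        assert m.n_chars == 0

    def test_every_character_has_both_states(self, rng):
        trees = [
            phylo.read_newick(random_newick(rng, [f"t{i}" for i in range(8)]))
            for _ in range(5)
        ]
        m = phylo.mrp_encode(trees)
        for j in range(m.n_chars):
            col = m.matrix[:, j]
            assert (col == 1).any() and (col == 0).any()

    def test_export_formats_parse(self):
        m = phylo.mrp_encode([phylo.read_newick("((A,B),C);")])
        assert "3 1" in m.as_phylip()
        assert "#NEXUS" in m.as_nexus()


class TestFitchScore:
    def test_hand_examples(self):
        m = MRPMatrix(taxa=["A", "B", "C"], matrix=np.array([[1], [1], [0]], np.int8))
        assert phylo.fitch_score(phylo.read_newick("((A,B),C);"), m) == 1
        assert phylo.fitch_score(phylo.read_newick("((A,C),B);"), m) == 1

    def test_constant_column_costs_nothing(self):
        m = MRPMatrix(
            taxa=["A", "B", "C"], matrix=np.array([[1], [1], [MISSING]], np.int8)
        )
        assert phylo.fitch_score(phylo.read_newick("((A,B),C);"), m) == 0

    def test_matches_brute_force_on_small_trees(self, rng):
        # every unrooted 5-taxon topology x random characters with '?'
        labels = [f"x{i}" for i in range(5)]
        for tree_struct in enumerate_unrooted(5):
            nwk = tree_to_newick(tree_struct, labels)
            dtree = phylo.read_newick(nwk)
            chars = rng.choice([0, 1, MISSING], size=(5, 20), p=[0.4, 0.4, 0.2])
            m = MRPMatrix(taxa=labels, matrix=chars.astype(np.int8))
            got = phylo.fitch_score(dtree, m)
            want = sum(
                brute_force_parsimony(
                    tree_struct,
                    {
                        i: (None if chars[i, j] == MISSING else int(chars[i, j]))
                        for i in range(5)
                    },
                )
                for j in range(20)
            )
            assert got == want


class TestRatchet:
    def model_matrix(self):
        model = "(((A,B),(C,D)),(E,F));"
        subs = [
            phylo.prune_to_taxa(phylo.read_newick(model), s)
            for s in [
                {"A", "B", "C", "E"},
                {"C", "D", "E", "F"},
                {"A", "B", "D", "F"},
                {"A", "C", "D", "E", "F"},
            ]
        ]
        return model, phylo.mrp_encode(subs)

    def test_recovers_model_tree(self):
        model, m = self.model_matrix()
        res = phylo.ratchet_search(m, iterations=10, seed=5)
        labels = m.taxa
        assert unrooted_splits(phylo.write_newick(res.tree), labels) == unrooted_splits(
            model, labels
        )

    def test_result_is_nni_local_optimum(self):
        from biogap.phylo import (
            _dendropy_to_search,
            _nni_neighbors,
            _score_search,
            _state_masks,
        )

        _, m = self.model_matrix()
        res = phylo.ratchet_search(m, iterations=5, seed=1)
        masks = _state_masks(m.matrix)
        w = np.ones(m.n_chars)
        stree = _dendropy_to_search(res.tree, m.taxa)
        s0 = _score_search(stree, masks, w)
        assert s0 == res.score
        for nb in _nni_neighbors(stree):
            assert _score_search(nb, masks, w) >= s0

    def test_deterministic_under_seed(self):
        _, m = self.model_matrix()
        a = phylo.ratchet_search(m, iterations=8, seed=42)
        b = phylo.ratchet_search(m, iterations=8, seed=42)
        assert phylo.write_newick(a.tree) == phylo.write_newick(b.tree)
        assert a.score == b.score
        assert a.log == b.log

    def test_never_worse_than_start_and_log_monotone(self, rng):
        taxa = [f"t{i}" for i in range(8)]
        trees = [phylo.read_newick(random_newick(rng, taxa)) for _ in range(4)]
        m = phylo.mrp_encode(trees)
        res = phylo.ratchet_search(m, iterations=15, seed=3)
        scores = [s for _, s in res.log]
        assert all(b <= a + 1e-12 for a, b in zip(scores, scores[1:]))
        assert res.score == scores[-1]

    def test_bad_inputs(self):
        _, m = self.model_matrix()
        with pytest.raises(ValueError):
            phylo.ratchet_search(m, iterations=0, seed=1)


class TestFaithPD:
    def test_pair_on_toy_tree(self, toy_tree):
        assert phylo.faith_pd(toy_tree, {"A", "B"}) == 3.0

    def test_all_tips_equals_total_length(self, toy_tree):
        total = sum(
            n.edge.length
            for n in toy_tree.preorder_node_iter()
            if n.parent_node is not None
        )
        assert phylo.faith_pd(toy_tree, {"A", "B", "C"}) == total

    def test_empty_set(self, toy_tree):
        assert phylo.faith_pd(toy_tree, set()) == 0.0

    def test_monotone_under_inclusion(self, rng):
        labels = [f"t{i}" for i in range(10)]
        tree = random_unit_tree(labels, rng)
        subset = set()
        prev = 0.0
        for lbl in labels:
            subset.add(lbl)
            pd_val = phylo.faith_pd(tree, subset)
            assert pd_val >= prev
            prev = pd_val

    def test_unknown_species_rejected(self, toy_tree):
        with pytest.raises(ValueError):
            phylo.faith_pd(toy_tree, {"Z"})


class TestPWE:
    def test_worked_example(self, toy_tree, toy_ranges):
        cells = phylo.pwe(toy_tree, toy_ranges)
        assert cells.to_dict() == pytest.approx({1: 2.0, 2: 1.5, 3: 0.5})

    def test_conservation_of_branch_length(self, rng):
        labels = [f"t{i}" for i in range(12)]
        tree = random_unit_tree(labels, rng)
        ranges = {
            lbl: frozenset(rng.choice(30, size=rng.integers(1, 6), replace=False).tolist())
            for lbl in labels
        }
        cells = phylo.pwe(tree, ranges)
        br = phylo.branch_ranges(tree, ranges)
        assert cells.sum() == pytest.approx(br.total_recorded_length, abs=1e-9)

    def test_single_recorded_species(self):
        # only A has records: its tip branch is the sole contributor
        tree = phylo.unit_branch_lengths(phylo.read_newick("(A,B);"))
        cells = phylo.pwe(tree, {"A": frozenset({7})})
        assert cells.to_dict() == pytest.approx({7: 1.0})

    def test_lineage_protection_toy(self, toy_tree, toy_ranges):
        lp = phylo.lineage_protection(toy_tree, toy_ranges, {1})
        assert lp.length_proportion == pytest.approx(0.75)
        assert lp.count_proportion == pytest.approx(0.75)

    def test_lineage_protection_extremes(self, toy_tree, toy_ranges):
        all_cells = {1, 2, 3}
        assert phylo.lineage_protection(toy_tree, toy_ranges, all_cells).length_proportion == 1.0
        assert phylo.lineage_protection(toy_tree, toy_ranges, set()).length_proportion == 0.0
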