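import itertools

import numpy as np
import pytest

from clonebench.metrics import (classify_mutation_pairs,
                                collapse_same_label_clades,
                                count_detected_ancestral, map_clones,
                                ordering_error_rate, rf_distance,
                                snv_assignment_error, treevec_distance)
from clonebench.phylo import (ClonePhylogeny, GenotypeMatrix,
                              SampleComposition, generate_random_dataset,
                              genotypes_from_tree)
from clonebench.trees import parse_newick

from conftest import (classify_pairs_bruteforce, random_clone_phylogeny,
                      random_labeled_tree, rf_bruteforce, treevec_bruteforce)


class TestClassifyMutationPairs:
    def test_example_tree_categories(self, example_tree):
        pairs = classify_mutation_pairs(example_tree)
        assert pairs[frozenset(("C", "D"))] == "concurrent"
        assert pairs[frozenset(("A", "B"))] == "sequential"
        assert pairs[frozenset(("E", "F"))] == "parallel"

    def test_same_branch_concurrent(self):
        tree = ClonePhylogeny("Normal", {"A": "Normal"},
                              {"A": frozenset({"m1", "m2"})})
        assert classify_mutation_pairs(tree)[frozenset(("m1", "m2"))] == \
            "concurrent"

    def test_partitions_all_pairs(self):
        tree = random_clone_phylogeny(np.random.default_rng(1), 6)
        pairs = classify_mutation_pairs(tree)
        n = len(tree.snvs)
        assert len(pairs) == n * (n - 1) // 2

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce(self, seed):
        tree = random_clone_phylogeny(np.random.default_rng(seed), 6)
        assert classify_mutation_pairs(tree) == classify_pairs_bruteforce(tree)


class TestOrderingErrorRate:
    def test_identical_trees_zero(self, example_tree):
        pairs = classify_mutation_pairs(example_tree)
        for cat in ("concurrent", "sequential", "parallel"):
            assert ordering_error_rate(pairs, pairs, cat) == 0.0

    def test_star_inference_sequential_undefined(self):
        truth = ClonePhylogeny("Normal", {"A": "Normal", "B": "A"},
                               {"A": frozenset({"x"}), "B": frozenset({"y"})})
        star = ClonePhylogeny("Normal", {"A": "Normal", "B": "Normal"},
                              {"A": frozenset({"x"}), "B": frozenset({"y"})})
        tp = classify_mutation_pairs(truth)
        ip = classify_mutation_pairs(star)
        assert ordering_error_rate(tp, ip, "sequential") is None
        # truth lacks parallel pairs -> miss term 0; the one inferred
        # parallel pair is false -> rate 1/2
        assert ordering_error_rate(tp, ip, "parallel") == 0.5

    def test_concurrent_two_of_three_plus_spurious(self):
        # truth: 3 concurrent pairs (a,b,c on one branch); inference keeps
        # (a,b) and (a,c) concurrent, moves c's pairing with b apart and
        # adds a spurious concurrent pair (d,e)
        truth = ClonePhylogeny("Normal", {"X": "Normal", "Y": "X"},
                               {"X": frozenset({"a", "b", "c"}),
                                "Y": frozenset({"d", "e"})})
        tp = classify_mutation_pairs(truth)
        ip = {frozenset(("a", "b")): "concurrent",
              frozenset(("a", "c")): "concurrent",
              frozenset(("b", "c")): "sequential",
              frozenset(("d", "e")): "concurrent"}
        # truth has 4 concurrent pairs: (a,b),(a,c),(b,c),(d,e); inferred
        # misses (b,c): miss 1/4; inferred concurrent: 3, all also true ->
        # false 0/3
        assert ordering_error_rate(tp, ip, "concurrent") == \
            pytest.approx(0.5 * (1 / 4))

    def test_unassigned_counts_as_missing(self, example_tree):
        tp = classify_mutation_pairs(example_tree)
        # inferred tree lacking SNVs entirely: all true pairs unassigned
        ip = {}
        assert ordering_error_rate(tp, ip, "concurrent") is None

    def test_relabeling_invariance(self):
        tree = random_clone_phylogeny(np.random.default_rng(3), 6)
        relabel = {s: f"z{s}" for s in tree.snvs}
        renamed = ClonePhylogeny(
            tree.root_id, tree.parent_of,
            {n: frozenset(relabel[s] for s in ss)
             for n, ss in tree.branch_mutations.items()})
        tp1 = classify_mutation_pairs(tree)
        tp2 = classify_mutation_pairs(renamed)
        for cat in ("concurrent", "sequential", "parallel"):
            assert ordering_error_rate(tp1, tp1, cat) == \
                ordering_error_rate(tp2, tp2, cat)


class TestMapClones:
    def test_identity_mapping(self):
        _, g, _ = generate_random_dataset(6, 2, seed=2)
        m = map_clones(g, g)
        assert all(m.mapping[c] == c for c in g.clone_ids)
        assert all(d == 0 for d in m.distance.values())

    def test_surplus_inferred_clone_attached_to_nearest(self):
        true = GenotypeMatrix(("t1", "t2"), ("m1", "m2", "m3"),
                              [[1, 0, 0], [1, 1, 0]])
        inf = GenotypeMatrix(("i1", "i2", "i3"), ("m1", "m2", "m3"),
                             [[1, 0, 0], [1, 1, 0], [1, 1, 1]])
        m = map_clones(true, inf)
        assert m.mapping["i3"] == "t2"
        assert m.distance["i3"] == 1

    def test_single_pair_always_mapped(self):
        true = GenotypeMatrix(("t",), ("m1", "m2"), [[1, 1]])
        inf = GenotypeMatrix(("i",), ("m1", "m2"), [[0, 0]])
        m = map_clones(true, inf)
        assert m.mapping["i"] == "t" and m.distance["i"] == 2

    def test_empty_inferred_rejected(self):
        true = GenotypeMatrix(("t",), ("m1",), [[1]])
        empty = GenotypeMatrix((), ("m1",), np.zeros((0, 1)))
        with pytest.raises(ValueError):
            map_clones(true, empty)

    def test_missing_snvs_treated_as_absent(self):
        true = GenotypeMatrix(("t",), ("m1", "m2"), [[1, 1]])
        inf = GenotypeMatrix(("i",), ("m1",), [[1]])
        m = map_clones(true, inf)
        assert m.distance["i"] == 1


class TestSnvAssignmentError:
    def test_perfect_zero(self):
        _, g, _ = generate_random_dataset(5, 2, seed=9)
        m = map_clones(g, g)
        assert snv_assignment_error(g, g, m) == 0.0

    def test_two_flips_over_three_clones(self):
        true = GenotypeMatrix(("a", "b", "c"), ("m1", "m2", "m3"),
                              [[1, 0, 0], [1, 1, 0], [1, 1, 1]])
        inf = GenotypeMatrix(("a", "b", "c"), ("m1", "m2", "m3"),
                             [[1, 0, 0], [1, 1, 0], [1, 0, 0]])
        # force the identity mapping to isolate the error count
        from clonebench.metrics import CloneMapping
        m = CloneMapping(mapping={c: c for c in "abc"},
                         primary={c: c for c in "abc"})
        assert snv_assignment_error(true, inf, m) == pytest.approx(2 / 3)

    def test_column_permutation_invariance(self):
        true = GenotypeMatrix(("a", "b"), ("m1", "m2"), [[1, 0], [1, 1]])
        inf = GenotypeMatrix(("a", "b"), ("m1", "m2"), [[0, 0], [1, 1]])
        perm_true = GenotypeMatrix(("a", "b"), ("m2", "m1"), [[0, 1], [1, 1]])
        perm_inf = GenotypeMatrix(("a", "b"), ("m2", "m1"), [[0, 0], [1, 1]])
        m1 = map_clones(true, inf)
        m2 = map_clones(perm_true, perm_inf)
        assert snv_assignment_error(true, inf, m1) == \
            snv_assignment_error(perm_true, perm_inf, m2)


class TestTreeVec:
    def test_identical_trees_zero(self):
        t = parse_newick("((A,B),(C,D));")
        assert treevec_distance(t, t) == 0.0

    def test_four_tip_example_matches_oracle(self):
        t1 = parse_newick("((A,B),(C,D));")
        t2 = parse_newick("(((A,B),C),D);")
        assert treevec_distance(t1, t2) == pytest.approx(
            treevec_bruteforce(t1, t2))

    def test_duplicate_label_cherry_collapses(self):
        dup = parse_newick("((X,X),Y);")
        single = parse_newick("(X,Y);")
        assert treevec_distance(dup, single) == 0.0

    def test_collapse_same_label_clades(self):
        t = collapse_same_label_clades(parse_newick("((X,X),(Y,Z));"))
        assert sorted(t.labels.values()) == ["X", "Y", "Z"]

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        a = random_labeled_tree(rng, "ABCDE")
        b = random_labeled_tree(rng, "ABCDE")
        assert treevec_distance(a, b) == treevec_distance(b, a)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_oracle_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        labels = list("ABCDEFGH")[:int(rng.integers(3, 9))]
        a = random_labeled_tree(rng, labels)
        b = random_labeled_tree(rng, labels)
        assert treevec_distance(a, b) == pytest.approx(treevec_bruteforce(a, b))


class TestRfDistance:
    def test_identical_trees_zero(self):
        t = parse_newick("((A,B),(C,(D,E)));")
        assert rf_distance(t, t) == 0.0

    def test_nni_matches_bruteforce(self):
        t1 = parse_newick("(((A,B),C),(D,E));")
        t2 = parse_newick("(((A,C),B),(D,E));")
        assert rf_distance(t1, t2) == pytest.approx(rf_bruteforce(t1, t2))

    def test_reversed_caterpillars_maximal(self):
        t1 = parse_newick("((((A,B),C),D),E);")
        t2 = parse_newick("((((E,D),C),B),A);")
        assert rf_distance(t1, t2) == 1.0
        assert rf_bruteforce(t1, t2) == 1.0

    def test_label_mismatch_rejected(self):
        t1 = parse_newick("(A,B);")
        t2 = parse_newick("(A,C);")
        with pytest.raises(ValueError, match="label"):
            rf_distance(t1, t2)

    def test_bounded_unit_interval(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            a = random_labeled_tree(rng, "ABCDEF")
            b = random_labeled_tree(rng, "ABCDEF")
            d = rf_distance(a, b)
            assert 0.0 <= d <= 1.0
            assert d == rf_distance(b, a)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_random_trees(self, seed):
        rng = np.random.default_rng(100 + seed)
        labels = list("ABCDEFGH")[:int(rng.integers(3, 9))]
        a = random_labeled_tree(rng, labels)
        b = random_labeled_tree(rng, labels)
        assert rf_distance(a, b) == pytest.approx(rf_bruteforce(a, b))


class TestCountDetectedAncestral:
    def _dataset(self):
        tree, genotypes, comp = generate_random_dataset(9, 4, seed=33)
        return tree, genotypes, comp

    def test_perfect_inference_finds_all(self):
        tree, genotypes, comp = self._dataset()
        m = map_clones(genotypes, genotypes)
        from clonebench.metrics import true_ancestral_clones
        expected = len(true_ancestral_clones(tree, comp))
        assert count_detected_ancestral(tree, comp, m) == expected

    def test_deleting_k_ancestors_reduces_count_by_k(self):
        tree, genotypes, comp = self._dataset()
        from clonebench.metrics import true_ancestral_clones
        ancestral = true_ancestral_clones(tree, comp)
        assert len(ancestral) >= 2
        k = 2
        keep = [i for i, c in enumerate(genotypes.clone_ids)
                if c not in ancestral[:k]]
        pruned = GenotypeMatrix(
            tuple(genotypes.clone_ids[i] for i in keep), genotypes.snv_ids,
            genotypes.values[keep])
        m = map_clones(genotypes, pruned)
        assert count_detected_ancestral(tree, comp, m) == len(ancestral) - k

    def test_no_internal_genotypes_zero(self):
        tree, genotypes, comp = self._dataset()
        tips = set(tree.tips)
        keep = [i for i, c in enumerate(genotypes.clone_ids) if c in tips]
        only_tips = GenotypeMatrix(
            tuple(genotypes.clone_ids[i] for i in keep), genotypes.snv_ids,
            genotypes.values[keep])
        m = map_clones(genotypes, only_tips)
        assert count_detected_ancestral(tree, comp, m) == 0
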