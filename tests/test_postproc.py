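import numpy as np
import pytest

from clonebench.phylo import (ClonePhylogeny, GenotypeMatrix,
                              SampleComposition, generate_random_dataset,
                              genotypes_from_tree)
from clonebench.postproc import (NonIdentifiableWarning,
                                 detect_degenerate_topology,
                                 discard_rare_clones,
                                 estimate_clone_frequencies,
                                 filter_spurious_ancestors)
from clonebench.readcounts import ReadCountTable, regenerate_at_depth


def noiseless_reads(genotypes, composition, total=128000):
    """Exact read counts: V has denominator dividing ``total``."""
    from clonebench.readcounts import expected_vaf_neutral
    v = expected_vaf_neutral(composition, genotypes)
    total_reads = np.full(v.shape, total, dtype=np.int64)
    mutant = np.round(v * total).astype(np.int64)
    assert np.allclose(mutant / total, v, atol=1e-12), "inexact construction"
    return ReadCountTable(composition.sample_ids, genotypes.snv_ids,
                          mutant, total_reads)


class TestEstimateCloneFrequencies:
    def _full_rank_truth(self, seed=0):
        tree, genotypes, _ = generate_random_dataset(6, 1, seed=seed)
        clones = tuple(c for c in genotypes.clone_ids if c != "Normal")
        keep = [i for i, c in enumerate(genotypes.clone_ids) if c != "Normal"]
        g = GenotypeMatrix(clones, genotypes.snv_ids, genotypes.values[keep])
        # every clone present: frequencies in multiples of 1/64
        rng = np.random.default_rng(seed)
        w = rng.integers(1, 10, len(clones))
        w = np.round(64 * w / w.sum()).astype(int)
        w[0] += 64 - w.sum()
        f = w / 64.0
        comp = SampleComposition(("S1",), clones, f[None, :])
        return g, comp

    def test_noiseless_recovery(self):
        g, comp = self._full_rank_truth(seed=1)
        reads = noiseless_reads(g, comp)
        est = estimate_clone_frequencies(g, reads)
        assert np.abs(est.frequencies - comp.frequencies).max() < 1e-6

    def test_single_clone_quarter_vaf(self):
        g = GenotypeMatrix(("A",), ("m1", "m2"), [[1, 1]])
        comp = SampleComposition(("S1",), ("A",), [[0.5]])
        reads = noiseless_reads(g, comp, total=1000)
        est = estimate_clone_frequencies(g, reads)
        assert est.frequencies[0, 0] == pytest.approx(0.5, abs=1e-6)

    def test_low_total_snv_excluded(self):
        g = GenotypeMatrix(("A",), ("m1", "m2"), [[1, 1]])
        comp = SampleComposition(("S1",), ("A",), [[1.0]])
        # m1 informative; m2 has only 30 total reads with a wild VAF of 1.0
        # that would drag the estimate up if it were (wrongly) included
        reads = ReadCountTable(("S1",), ("m1", "m2"),
                               [[500, 30]], [[1000, 30]])
        est = estimate_clone_frequencies(g, reads, min_total=50)
        assert est.frequencies[0, 0] == pytest.approx(1.0, abs=1e-6)

    def test_no_surviving_snvs_rejected(self):
        g = GenotypeMatrix(("A",), ("m1",), [[1]])
        comp = SampleComposition(("S1",), ("A",), [[1.0]])
        reads = ReadCountTable(("S1",), ("m1",), [[1]], [[10]])
        with pytest.raises(ValueError, match="filter"):
            estimate_clone_frequencies(g, reads)

    def test_rank_deficient_warns(self):
        g = GenotypeMatrix(("A", "B"), ("m1",), [[1], [1]])
        reads = ReadCountTable(("S1",), ("m1",), [[250]], [[1000]])
        with pytest.warns(NonIdentifiableWarning):
            estimate_clone_frequencies(g, reads)

    def test_noisy_recovery_within_tolerance(self):
        g, comp = self._full_rank_truth(seed=3)
        errs = []
        for rep in range(10):
            reads = regenerate_at_depth(g, comp, 100, seed=rep)
            est = estimate_clone_frequencies(g, reads)
            errs.append(np.abs(est.frequencies - comp.frequencies).mean())
        assert np.mean(errs) < 0.05


def ancestor_descendant_setup(shared_vaf, unique_vaf, n_each=20, depth=1000,
                              seed=0):
    tree = ClonePhylogeny(
        "Normal", {"P": "Normal", "C": "P"},
        {"P": frozenset(f"s{i}" for i in range(n_each)),
         "C": frozenset(f"u{i}" for i in range(n_each))})
    genotypes = genotypes_from_tree(tree)
    keep = [i for i, c in enumerate(genotypes.clone_ids) if c != "Normal"]
    g = GenotypeMatrix(tuple(genotypes.clone_ids[i] for i in keep),
                       genotypes.snv_ids, genotypes.values[keep])
    comp = SampleComposition(("S1",), ("P", "C"), [[0.4, 0.6]])
    rng = np.random.default_rng(seed)
    shared = sorted(f"s{i}" for i in range(n_each))
    vafs = {}
    for s in genotypes.snv_ids:
        base = shared_vaf if str(s).startswith("s") else unique_vaf
        vafs[s] = np.clip(base + rng.normal(0, 0.02), 0.01, 0.99)
    total = np.full((1, len(genotypes.snv_ids)), depth, dtype=np.int64)
    mutant = np.array([[rng.binomial(depth, vafs[s])
                        for s in genotypes.snv_ids]])
    reads = ReadCountTable(("S1",), genotypes.snv_ids, mutant, total)
    return tree, g, comp, reads


class TestFilterSpuriousAncestors:
    def test_separated_groups_retain_ancestor(self):
        tree, g, comp, reads = ancestor_descendant_setup(0.45, 0.15, seed=5)
        filtered, removals = filter_spurious_ancestors(tree, g, comp, reads)
        assert removals == []
        assert "P" in filtered.clone_ids

    def test_null_groups_remove_ancestor(self):
        # same distribution for both groups: expect removal (p > 0.05 with
        # probability ~0.95); use a seed where that typical outcome holds
        tree, g, comp, reads = ancestor_descendant_setup(0.30, 0.30, seed=1)
        filtered, removals = filter_spurious_ancestors(tree, g, comp, reads)
        assert len(removals) == 1
        assert "P" not in filtered.clone_ids
        # frequency mass reassigned to the descendant
        assert filtered.frequencies.sum() == pytest.approx(1.0)

    def test_ancestor_without_coexisting_descendant_untouched(self):
        tree, g, _, reads = ancestor_descendant_setup(0.3, 0.3, seed=2)
        comp = SampleComposition(("S1",), ("P", "C"), [[1.0, 0.0]])
        filtered, removals = filter_spurious_ancestors(tree, g, comp, reads)
        assert removals == []

    def test_too_few_snvs_skips_test(self):
        tree, g, comp, reads = ancestor_descendant_setup(0.3, 0.3, n_each=1,
                                                         seed=3)
        filtered, removals = filter_spurious_ancestors(tree, g, comp, reads)
        assert removals == []
        assert "P" in filtered.clone_ids

    def test_idempotent(self):
        tree, g, comp, reads = ancestor_descendant_setup(0.45, 0.15, seed=7)
        once, _ = filter_spurious_ancestors(tree, g, comp, reads)
        twice, _ = filter_spurious_ancestors(tree, g, once, reads)
        assert np.array_equal(once.frequencies, twice.frequencies)


class TestDiscardRareClones:
    def test_below_threshold_removed(self):
        comp = SampleComposition(("S1",), ("A", "B"), [[0.015, 0.985]])
        out = discard_rare_clones(comp)
        assert out.clone_ids == ("B",)
        assert out.frequencies[0, 0] == pytest.approx(1.0)

    def test_all_above_identity(self):
        comp = SampleComposition(("S1",), ("A", "B"), [[0.5, 0.5]])
        out = discard_rare_clones(comp)
        assert np.array_equal(out.frequencies, comp.frequencies)

    def test_boundary_is_strict(self):
        comp = SampleComposition(("S1",), ("A", "B"), [[0.02, 0.98]])
        out = discard_rare_clones(comp)
        assert "A" in out.clone_ids

    def test_all_discarded_rejected(self):
        comp = SampleComposition(("S1",), ("A", "B"), [[0.01, 0.01]])
        with pytest.raises(ValueError, match="discarded"):
            discard_rare_clones(comp)

    def test_idempotent(self):
        comp = SampleComposition(("S1", "S2"), ("A", "B", "C"),
                                 [[0.01, 0.5, 0.49], [0.3, 0.3, 0.4]])
        once = discard_rare_clones(comp)
        twice = discard_rare_clones(once)
        assert once.clone_ids == twice.clone_ids
        assert np.allclose(once.frequencies, twice.frequencies)


class TestDetectDegenerateTopology:
    def test_star(self):
        star = ClonePhylogeny(
            "Normal", {"A": "Normal", "B": "Normal", "C": "Normal"},
            {"A": frozenset({"m1"}), "B": frozenset({"m2"}),
             "C": frozenset({"m3"})})
        assert detect_degenerate_topology(star) == "star"

    def test_line(self):
        line = ClonePhylogeny(
            "Normal", {"A": "Normal", "B": "A", "C": "B"},
            {"A": frozenset({"m1"}), "B": frozenset({"m2"}),
             "C": frozenset({"m3"})})
        assert detect_degenerate_topology(line) == "line"

    def test_ok(self, example_tree):
        assert detect_degenerate_topology(example_tree) == "ok"
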