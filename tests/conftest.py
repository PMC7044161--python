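"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from clonebench.phylo import ClonePhylogeny
from clonebench.trees import LabeledTree


@pytest.fixture
def chain_tree() -> ClonePhylogeny:
    """Normal -> A(m1) -> B(m2)."""
    return ClonePhylogeny(
        "Normal", {"A": "Normal", "B": "A"},
        {"Normal": frozenset(), "A": frozenset({"m1"}), "B": frozenset({"m2"})})


@pytest.fixture
def example_tree() -> ClonePhylogeny:
    """Tree with all three pair categories.

    Branches: c1 carries A; c2 (child of c1) carries B, C, D; c3 and c4
    (siblings under c1) carry E and F.  So (C, D) is concurrent, (A, B)
    sequential, (E, F) parallel.
    """
    return ClonePhylogeny(
        "Normal",
        {"c1": "Normal", "c2": "c1", "c3": "c1", "c4": "c1"},
        {"Normal": frozenset(), "c1": frozenset({"A"}),
         "c2": frozenset({"B", "C", "D"}), "c3": frozenset({"E"}),
         "c4": frozenset({"F"})})


# ---------------------------------------------------------------------------
# random generators used by oracle-equivalence tests


def random_clone_phylogeny(rng: np.random.Generator, n_nodes: int,
                           max_muts: int = 3) -> ClonePhylogeny:
    """Random rooted clone tree; every branch carries >= 1 mutation."""
    parent = {}
    muts = {"Normal": frozenset()}
    counter = 0
    nodes = ["Normal"]
    for i in range(n_nodes):
        name = f"n{i}"
        parent[name] = nodes[rng.integers(len(nodes))]
        k = int(rng.integers(1, max_muts + 1))
        muts[name] = frozenset(f"m{counter + j}" for j in range(k))
        counter += k
        nodes.append(name)
    return ClonePhylogeny("Normal", parent, muts)


def random_labeled_tree(rng: np.random.Generator, labels) -> LabeledTree:
    """Random rooted multifurcating tree with the given tip labels."""
    labels = list(labels)
    counter = [0]

    def new():
        counter[0] += 1
        return counter[0] - 1

    root = new()
    parent: dict = {}
    internal = [root]
    tip_nodes = []
    for lbl in labels:
        t = new()
        host = internal[rng.integers(len(internal))]
        if rng.random() < 0.5 and len(internal) < len(labels) - 1:
            mid = new()
            parent[mid] = host
            internal.append(mid)
            host = mid
        parent[t] = host
        tip_nodes.append(t)
    # ensure no internal node is childless: demote such nodes into tips with
    # a synthetic unique label? simpler: reattach childless internals' tips
    tree_labels = dict(zip(tip_nodes, labels))
    changed = True
    while changed:
        changed = False
        kids: dict = {}
        for c, p in parent.items():
            kids.setdefault(p, []).append(c)
        for n in list(internal):
            if n not in kids and n != root:
                parent.pop(n)
                internal.remove(n)
                changed = True
    return LabeledTree(root, parent, tree_labels)


# ---------------------------------------------------------------------------
# oracles (kept deliberately naive and independent of the implementations)


def classify_pairs_bruteforce(tree: ClonePhylogeny) -> dict:
    """O(n^2) classification via an explicit ancestor table."""
    nodes = tree.nodes
    is_anc = {(a, b): tree.is_ancestor(a, b)
              for a in nodes for b in nodes}
    branch_of = {}
    for n in nodes:
        for s in tree.branch_mutations.get(n, frozenset()):
            branch_of[s] = n
    out = {}
    for a, b in itertools.combinations(sorted(branch_of, key=str), 2):
        na, nb = branch_of[a], branch_of[b]
        if na == nb:
            out[frozenset((a, b))] = "concurrent"
        elif is_anc[(na, nb)] or is_anc[(nb, na)]:
            out[frozenset((a, b))] = "sequential"
        else:
            out[frozenset((a, b))] = "parallel"
    return out


def rf_bruteforce(t1: LabeledTree, t2: LabeledTree) -> float:
    """RF via exhaustive enumeration of label subsets."""
    labels = sorted(t1.tipset(t1.root))
    assert labels == sorted(t2.tipset(t2.root))

    def clades(tree: LabeledTree) -> set:
        found = set()
        for r in range(2, len(labels)):
            for subset in itertools.combinations(labels, r):
                target = frozenset(subset)
                group = [t for t in tree.tips
                         if tree.labels.get(t, str(t)) in target]
                node = tree.mrca(group)
                if tree.tipset(node) == target:
                    found.add(target)
        return found

    c1, c2 = clades(t1), clades(t2)
    total = len(c1) + len(c2)
    return len(c1 ^ c2) / total if total else 0.0


def treevec_bruteforce(t1: LabeledTree, t2: LabeledTree) -> float:
    """Naive per-pair root-to-MRCA depth vectors (after collapsing handled
    implicitly by the group-MRCA rule)."""
    def depth_of_pair(tree: LabeledTree, a: str, b: str) -> int:
        groups = tree.label_tips()
        if a not in groups or b not in groups:
            return 0
        tips = groups[a] + groups[b]
        # MRCA by repeated pairwise path intersection
        paths = [set(tree.root_path(t)) for t in tips]
        common = set.intersection(*paths)
        node = max(common, key=tree.depth)
        return tree.depth(node)

    labels = sorted(set(t1.label_tips()) | set(t2.label_tips()))
    sq = 0.0
    for a, b in itertools.combinations(labels, 2):
        sq += (depth_of_pair(t1, a, b) - depth_of_pair(t2, a, b)) ** 2
    return float(np.sqrt(sq))
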