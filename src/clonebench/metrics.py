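"""Scoring of inferred clone genotypes and phylogenies against truth.

Implements mutation-pair ordering error rates (concurrent / sequential /
parallel), greedy genotype-based clone mapping, per-clone SNV assignment
error, a duplicate-label-aware tree-vector distance, rooted Robinson–Foulds
with best-match tip pruning, and ancestral-clone detection counts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .phylo import ClonePhylogeny, GenotypeMatrix, SampleComposition
from .trees import LabeledTree

__all__ = [
    "CATEGORIES",
    "CloneMapping",
    "EvaluationReport",
    "classify_mutation_pairs",
    "ordering_error_rate",
    "map_clones",
    "snv_assignment_error",
    "collapse_same_label_clades",
    "treevec_distance",
    "rf_distance",
    "count_detected_ancestral",
]

CATEGORIES = ("concurrent", "sequential", "parallel")


def classify_mutation_pairs(tree: ClonePhylogeny) -> dict:
    """Classify every unordered SNV pair in a mutational tree.

    Pairs on one branch are *concurrent*; pairs on ancestor/descendant
    branches (any number of intervening branches) are *sequential*; pairs on
    diverged lineages are *parallel*.  Returns a mapping
    ``frozenset({a, b}) -> category`` covering all C(n, 2) pairs.
    """
    branch_of = tree.snv_branch()
    snvs = sorted(branch_of, key=str)
    # precompute ancestor sets of each branch-carrying node
    anc = {n: set(tree.root_path(n)[:-1]) for n in set(branch_of.values())}
    out: dict = {}
    for a, b in itertools.combinations(snvs, 2):
        na, nb = branch_of[a], branch_of[b]
        if na == nb:
            cat = "concurrent"
        elif na in anc[nb] or nb in anc[na]:
            cat = "sequential"
        else:
            cat = "parallel"
        out[frozenset((a, b))] = cat
    return out


def ordering_error_rate(true_pairs: Mapping, inferred_pairs: Mapping,
                        category: str):
    """Average of the missed-pair and false-pair proportions for a category.

    Missed: true pairs of the category not reproduced with the same
    category in the inferred tree (pairs over SNVs absent from the inferred
    tree count as unassigned, hence missed).  False: inferred pairs of the
    category that are not true pairs of it.  When the inferred tree has no
    pairs at all in a category that the truth does have, the rate is
    undefined (``None``) — the method-failure signal; a category empty in
    both trees scores 0.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    true_cat = [p for p, c in true_pairs.items() if c == category]
    inf_cat = [p for p, c in inferred_pairs.items() if c == category]
    if not inf_cat and true_cat:
        return None
    miss = sum(1 for p in true_cat if inferred_pairs.get(p) != category)
    miss_prop = miss / len(true_cat) if true_cat else 0.0
    false = sum(1 for p in inf_cat if true_pairs.get(p) != category)
    false_prop = false / len(inf_cat) if inf_cat else 0.0
    return 0.5 * (miss_prop + false_prop)


# ---------------------------------------------------------------------------
# clone mapping


@dataclass(frozen=True)
class CloneMapping:
    """Assignment of inferred clones to true clones.

    ``primary`` is the one-to-one greedy pairing (used for tip pruning);
    ``mapping`` extends it so that every inferred clone is assigned (many-
    to-one allowed); ``distance`` holds the Hamming distance of each
    inferred clone to its image.
    """

    mapping: Mapping  # inferred -> true
    primary: Mapping  # true -> inferred (one-to-one subset)
    distance: Mapping = field(default_factory=dict)  # inferred -> int


def _hamming_table(true_genotypes: GenotypeMatrix,
                   inferred_genotypes: GenotypeMatrix):
    """Distances over the union SNV universe; absent columns count as 0."""
    universe = sorted(set(true_genotypes.snv_ids) | set(inferred_genotypes.snv_ids),
                      key=str)

    def expand(g: GenotypeMatrix) -> np.ndarray:
        out = np.zeros((len(g.clone_ids), len(universe)), dtype=np.int8)
        col = {s: j for j, s in enumerate(universe)}
        for j, s in enumerate(g.snv_ids):
            out[:, col[s]] = g.values[:, j]
        return out

    T = expand(true_genotypes)
    I = expand(inferred_genotypes)
    return np.abs(T[:, None, :] - I[None, :, :]).sum(axis=2)


def map_clones(true_genotypes: GenotypeMatrix,
               inferred_genotypes: GenotypeMatrix) -> CloneMapping:
    """Two-step greedy mapping of inferred clones onto true clones.

    Step 1 pairs (true, inferred) couples in ascending Hamming-distance
    order, each clone used at most once; step 2 attaches every remaining
    inferred clone to its nearest true clone.  Ties break on
    (distance, true id, inferred id).
    """
    if not inferred_genotypes.clone_ids:
        raise ValueError("inferred genotype matrix has no clones")
    D = _hamming_table(true_genotypes, inferred_genotypes)
    trues = true_genotypes.clone_ids
    infs = inferred_genotypes.clone_ids
    order = sorted(
        ((int(D[i, j]), str(t), str(f), t, f)
         for (i, t), (j, f) in itertools.product(enumerate(trues),
                                                 enumerate(infs))),
    )
    primary: dict = {}
    used_inf: set = set()
    for d, _, _, t, f in order:
        if t in primary or f in used_inf:
            continue
        primary[t] = f
        used_inf.add(f)
    mapping = {f: t for t, f in primary.items()}
    ti = {t: i for i, t in enumerate(trues)}
    fi = {f: j for j, f in enumerate(infs)}
    for f in infs:
        if f in mapping:
            continue
        j = fi[f]
        best = min(trues, key=lambda t: (int(D[ti[t], j]), str(t)))
        mapping[f] = best
    distance = {f: int(D[ti[mapping[f]], fi[f]]) for f in infs}
    return CloneMapping(mapping=mapping, primary=primary, distance=distance)


def snv_assignment_error(true_genotypes: GenotypeMatrix,
                         inferred_genotypes: GenotypeMatrix,
                         mapping: CloneMapping) -> float:
    """Average Hamming distance between inferred clones and their images."""
    D = _hamming_table(true_genotypes, inferred_genotypes)
    ti = {t: i for i, t in enumerate(true_genotypes.clone_ids)}
    total = 0
    for j, f in enumerate(inferred_genotypes.clone_ids):
        total += int(D[ti[mapping.mapping[f]], j])
    return total / len(inferred_genotypes.clone_ids)


# ---------------------------------------------------------------------------
# tree distances


def collapse_same_label_clades(tree: LabeledTree) -> LabeledTree:
    """Replace each maximal clade whose tips all share one label by a tip."""
    parent = dict(tree.parent)
    labels = dict(tree.labels)
    for node in tree.nodes:
        if node in labels or node not in parent and node != tree.root:
            continue
        tipset = tree.tipset(node)
        if len(tipset) == 1 and tree.children(node):
            # check maximality: parent clade must be mixed (or node is root)
            up = parent.get(node)
            if node != tree.root and up is not None and len(tree.tipset(up)) == 1:
                continue
            # drop the whole clade below, turn node into a tip
            drop = []
            stack = list(tree.children(node))
            while stack:
                n = stack.pop()
                drop.append(n)
                stack.extend(tree.children(n))
            for n in drop:
                parent.pop(n, None)
                labels.pop(n, None)
            labels[node] = next(iter(tipset))
    return LabeledTree(tree.root, parent, labels)


def _label_pair_vector(tree: LabeledTree, label_pairs: Sequence) -> np.ndarray:
    """Root-to-MRCA edge counts for label pairs (0 for absent labels).

    A label carried by several tips is located at the MRCA of all its tips;
    a pair's entry is the depth of the MRCA of the union of both groups.
    """
    groups = tree.label_tips()
    vec = np.zeros(len(label_pairs))
    for i, (a, b) in enumerate(label_pairs):
        if a not in groups or b not in groups:
            continue
        vec[i] = tree.depth(tree.mrca(groups[a] + groups[b]))
    return vec


def treevec_distance(true_tree: LabeledTree, inferred_tree: LabeledTree) -> float:
    """Euclidean distance between root-to-MRCA depth vectors over label pairs.

    Monophyletic same-label clades are collapsed first; the vectors run
    over all unordered pairs of the union of both trees' labels, with a
    label absent from a tree contributing depth 0.
    """
    t1 = collapse_same_label_clades(true_tree)
    t2 = collapse_same_label_clades(inferred_tree)
    labels = sorted(set(t1.label_tips()) | set(t2.label_tips()))
    pairs = list(itertools.combinations(labels, 2))
    v1 = _label_pair_vector(t1, pairs)
    v2 = _label_pair_vector(t2, pairs)
    return float(math.sqrt(((v1 - v2) ** 2).sum()))


def _nontrivial_clades(tree: LabeledTree) -> set:
    all_tips = tree.tipset(tree.root)
    out = set()
    for n in tree.nodes:
        if not tree.children(n):
            continue
        ts = tree.tipset(n)
        if 1 < len(ts) < len(all_tips):
            out.add(ts)
    return out


def prune_to_primary(inferred_tree: LabeledTree, mapping: CloneMapping) -> LabeledTree:
    """Keep one tip per true clone: the primary-matched inferred tip.

    Tips are relabelled with the true clone they map to; tips whose
    inferred clone is not part of the one-to-one pairing are pruned, as are
    duplicate tips of a retained label (lexicographically smallest tip id
    wins).
    """
    retained_inferred = {str(f): str(t) for t, f in mapping.primary.items()}
    keep = []
    seen_labels = set()
    for tip in sorted(inferred_tree.tips):
        lbl = inferred_tree.labels.get(tip, str(tip))
        if lbl in retained_inferred and retained_inferred[lbl] not in seen_labels:
            keep.append(tip)
            seen_labels.add(retained_inferred[lbl])
    pruned = inferred_tree.keep_tips(keep)
    return pruned.relabel(retained_inferred)


def rf_distance(true_tree: LabeledTree, inferred_tree: LabeledTree,
                mapping: CloneMapping | None = None) -> float:
    """Normalized rooted Robinson–Foulds distance in [0, 1].

    The count of nontrivial clades differing between the trees, divided by
    the total number of nontrivial clades in both.  When ``mapping`` is
    given, the inferred tree is first pruned to one best-matching tip per
    true clone and relabelled (see :func:`prune_to_primary`).
    """
    if mapping is not None:
        inferred_tree = prune_to_primary(inferred_tree, mapping)
        keep = [t for t in sorted(true_tree.tips)
                if true_tree.labels.get(t, str(t))
                in set(inferred_tree.labels.values())]
        true_tree = true_tree.keep_tips(keep)
    l1 = sorted(true_tree.labels.values())
    l2 = sorted(inferred_tree.labels.values())
    if l1 != l2:
        raise ValueError(f"tip label sets differ: {l1} vs {l2}")
    c1 = _nontrivial_clades(true_tree)
    c2 = _nontrivial_clades(inferred_tree)
    total = len(c1) + len(c2)
    if total == 0:
        return 0.0
    return len(c1 ^ c2) / total


# ---------------------------------------------------------------------------
# ancestral clones


def count_detected_ancestral(true_tree: ClonePhylogeny,
                             true_composition: SampleComposition,
                             mapping: CloneMapping,
                             tolerance: int = 0) -> int:
    """Number of true ancestral clones recovered by the inference.

    Ancestral clones are internal (non-tip, non-germline) nodes of the true
    phylogeny present in at least one sample.  A clone counts as detected
    when some inferred clone maps to it with genotype distance at most
    ``tolerance`` (default: exact match).
    """
    tips = set(true_tree.tips)
    present = {
        c for i, c in enumerate(true_composition.clone_ids)
        if true_composition.frequencies[:, i].max() > 0
    }
    ancestral = [c for c in true_tree.nodes
                 if c != true_tree.root_id and c not in tips and c in present]
    detected = 0
    for t in ancestral:
        for f, image in mapping.mapping.items():
            if image == t and mapping.distance.get(f, 0) <= tolerance:
                detected += 1
                break
    return detected


def true_ancestral_clones(true_tree: ClonePhylogeny,
                          true_composition: SampleComposition) -> list:
    """Internal non-germline clones present in at least one sample."""
    tips = set(true_tree.tips)
    present = {
        c for i, c in enumerate(true_composition.clone_ids)
        if true_composition.frequencies[:, i].max() > 0
    }
    return [c for c in true_tree.nodes
            if c != true_tree.root_id and c not in tips and c in present]


@dataclass
class EvaluationReport:
    """All metrics for one (dataset, method) comparison."""

    ordering_error: dict  # category -> rate or None (undefined/failure)
    treevec: float | None = None
    rf: float | None = None
    snv_assignment_error: float | None = None
    ancestral_detected: int | None = None
    ancestral_true: int | None = None
    failure_flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "ordering_error": dict(self.ordering_error),
            "treevec": self.treevec,
            "rf": self.rf,
            "snv_assignment_error": self.snv_assignment_error,
            "ancestral_detected": self.ancestral_detected,
            "ancestral_true": self.ancestral_true,
            "failure_flags": list(self.failure_flags),
        }
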