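"""Clone phylogenies, genotype matrices and sample compositions.

A clone phylogeny is a rooted tree whose root is the germline (no somatic
mutations) and whose branches carry sets of SNVs acquired on the way to the
child node.  Under the infinite-sites assumption every SNV occurs on exactly
one branch, so the genotype of a clone is the union of the branch mutation
sets on its root path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClonePhylogeny",
    "GenotypeMatrix",
    "SampleComposition",
    "InfiniteSitesViolation",
    "PerfectPhylogenyViolation",
    "genotypes_from_tree",
    "tree_from_genotypes",
    "generate_random_dataset",
    "export_mutational_tree",
    "parse_mutational_tree",
]

GERMLINE = "Normal"


class InfiniteSitesViolation(ValueError):
    """An SNV appears on more than one branch."""


class PerfectPhylogenyViolation(ValueError):
    """A binary genotype matrix admits no perfect phylogeny.

    Carries the offending SNV pair as ``args[1]`` when known.
    """


@dataclass(frozen=True)
class ClonePhylogeny:
    """Rooted clone tree with mutation sets on branches.

    Parameters
    ----------
    root_id
        Identifier of the germline node.
    parent_of
        Mapping child node -> parent node.  The root has no entry.
    branch_mutations
        Mapping node -> SNVs acquired on the branch leading into the node.
        The root's set must be empty.
    clone_labels
        Optional mapping node -> labels of clones merged onto that node
        (duplicate genotypes collapse to a single node during
        reconstruction).  Nodes without an entry are labelled by their id.
    """

    root_id: str
    parent_of: Mapping[str, str]
    branch_mutations: Mapping[str, frozenset]
    clone_labels: Mapping[str, tuple] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "parent_of", dict(self.parent_of))
        object.__setattr__(
            self, "branch_mutations",
            {n: frozenset(s) for n, s in self.branch_mutations.items()},
        )
        object.__setattr__(self, "clone_labels", dict(self.clone_labels))
        self._validate()

    def _validate(self) -> None:
        if self.root_id in self.parent_of:
            raise ValueError(f"root {self.root_id!r} must not have a parent")
        if self.branch_mutations.get(self.root_id, frozenset()):
            raise ValueError("germline root must carry no branch mutations")
        # connectivity & acyclicity: every node must reach the root
        for node in self.parent_of:
            seen = {node}
            cur = node
            while cur != self.root_id:
                if cur not in self.parent_of:
                    raise ValueError(f"node {cur!r} is disconnected from the root")
                cur = self.parent_of[cur]
                if cur in seen:
                    raise ValueError(f"cycle through node {cur!r}")
                seen.add(cur)
        seen_snvs: dict = {}
        for node, snvs in self.branch_mutations.items():
            if node != self.root_id and node not in self.parent_of:
                raise ValueError(f"branch_mutations names unknown node {node!r}")
            for s in snvs:
                if s in seen_snvs:
                    raise InfiniteSitesViolation(
                        f"SNV {s!r} on branches {seen_snvs[s]!r} and {node!r}"
                    )
                seen_snvs[s] = node

    # -- structure helpers -------------------------------------------------

    @property
    def nodes(self) -> list:
        """All node ids, root first, children after parents, sorted siblings."""
        kids: dict = {}
        for c, p in self.parent_of.items():
            kids.setdefault(p, []).append(c)
        out = [self.root_id]
        stack = sorted(kids.get(self.root_id, []), reverse=True)
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(sorted(kids.get(n, []), reverse=True))
        return out

    def children(self, node) -> list:
        return sorted(c for c, p in self.parent_of.items() if p == node)

    @property
    def tips(self) -> list:
        parents = set(self.parent_of.values())
        return [n for n in self.nodes if n not in parents]

    def root_path(self, node) -> list:
        """Nodes from the root down to ``node`` inclusive."""
        path = [node]
        while node != self.root_id:
            node = self.parent_of[node]
            path.append(node)
        return path[::-1]

    def genotype(self, node) -> frozenset:
        """Union of branch mutation sets on the node's root path."""
        out: set = set()
        for n in self.root_path(node):
            out |= self.branch_mutations.get(n, frozenset())
        return frozenset(out)

    def is_ancestor(self, a, b) -> bool:
        """True iff ``a`` is a proper ancestor of ``b``."""
        return a != b and a in self.root_path(b)

    @property
    def snvs(self) -> frozenset:
        out: set = set()
        for s in self.branch_mutations.values():
            out |= s
        return frozenset(out)

    def snv_branch(self) -> dict:
        """Map SNV -> node whose incoming branch carries it."""
        return {s: n for n, ss in self.branch_mutations.items() for s in ss}

    def labels_of(self, node) -> tuple:
        return tuple(self.clone_labels.get(node, (node,)))

    def collapse_empty_branches(self) -> "ClonePhylogeny":
        """Remove non-root internal nodes whose branch carries no mutations.

        Children of a collapsed node are re-attached to its parent; clone
        labels of the collapsed node migrate to the parent.
        """
        parent = dict(self.parent_of)
        muts = dict(self.branch_mutations)
        labels = {n: list(self.labels_of(n)) for n in self.nodes}
        changed = True
        while changed:
            changed = False
            for node in list(parent):
                if muts.get(node, frozenset()):
                    continue
                kids = [c for c, p in parent.items() if p == node]
                if not kids:
                    continue  # keep mutation-free tips: they are real clones
                p = parent.pop(node)
                for c in kids:
                    parent[c] = p
                labels.setdefault(p, []).extend(labels.pop(node, []))
                muts.pop(node, None)
                changed = True
                break
        keep = {self.root_id} | set(parent)
        return ClonePhylogeny(
            root_id=self.root_id,
            parent_of=parent,
            branch_mutations={n: s for n, s in muts.items() if n in keep},
            clone_labels={n: tuple(v) for n, v in labels.items() if n in keep},
        )


@dataclass(frozen=True)
class GenotypeMatrix:
    """Binary clones x SNVs presence/absence matrix (1 = mutant)."""

    clone_ids: tuple
    snv_ids: tuple
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "clone_ids", tuple(self.clone_ids))
        object.__setattr__(self, "snv_ids", tuple(self.snv_ids))
        vals = np.asarray(self.values, dtype=np.int8)
        if vals.shape != (len(self.clone_ids), len(self.snv_ids)):
            raise ValueError("values shape does not match clone/SNV ids")
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("genotype entries must be 0 or 1")
        object.__setattr__(self, "values", vals)

    def row(self, clone) -> np.ndarray:
        return self.values[self.clone_ids.index(clone)]

    def mutation_set(self, clone) -> frozenset:
        r = self.row(clone)
        return frozenset(s for s, v in zip(self.snv_ids, r) if v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.clone_ids),
                            columns=list(self.snv_ids))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        return cls(tuple(df.index), tuple(df.columns), df.to_numpy())


@dataclass(frozen=True)
class SampleComposition:
    """Samples x clones frequency matrix; rows sum to at most 1.

    The per-sample normal-cell fraction is ``1 - row sum`` and equals 0 at
    100% tumor purity.
    """

    sample_ids: tuple
    clone_ids: tuple
    frequencies: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "clone_ids", tuple(self.clone_ids))
        freq = np.asarray(self.frequencies, dtype=float)
        if freq.shape != (len(self.sample_ids), len(self.clone_ids)):
            raise ValueError("frequencies shape does not match ids")
        if (freq < -1e-12).any():
            raise ValueError("frequencies must be non-negative")
        if (freq.sum(axis=1) > 1 + 1e-9).any():
            raise ValueError("sample frequencies must sum to at most 1")
        object.__setattr__(self, "frequencies", np.clip(freq, 0.0, 1.0))

    @property
    def normal_fraction(self) -> np.ndarray:
        return np.clip(1.0 - self.frequencies.sum(axis=1), 0.0, 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.frequencies, index=list(self.sample_ids),
                            columns=list(self.clone_ids))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampleComposition":
        return cls(tuple(df.index), tuple(df.columns), df.to_numpy())


# ---------------------------------------------------------------------------
# conversions


def genotypes_from_tree(tree: ClonePhylogeny,
                        snv_order: Sequence | None = None) -> GenotypeMatrix:
    """Genotype matrix of every clone in a phylogeny.

    The germline row is all zeros; entry (c, s) is 1 iff SNV ``s`` lies on
    the root path of clone ``c``.
    """
    snvs = list(snv_order) if snv_order is not None else sorted(tree.snvs)
    idx = {s: j for j, s in enumerate(snvs)}
    clones = tree.nodes
    vals = np.zeros((len(clones), len(snvs)), dtype=np.int8)
    geno = {tree.root_id: frozenset()}
    for i, node in enumerate(clones):
        if node != tree.root_id:
            geno[node] = geno[tree.parent_of[node]] | tree.branch_mutations.get(
                node, frozenset())
        for s in geno[node]:
            vals[i, idx[s]] = 1
    return GenotypeMatrix(tuple(clones), tuple(snvs), vals)


def _check_compatible(carriers: dict) -> None:
    """Pairwise-nesting test for rooted binary characters.

    Columns are compatible iff their carrier sets are nested or disjoint.
    """
    items = sorted(carriers.items(), key=lambda kv: str(kv[0]))
    for i in range(len(items)):
        si, ci = items[i]
        for j in range(i + 1, len(items)):
            sj, cj = items[j]
            inter = ci & cj
            if inter and not (ci <= cj or cj <= ci):
                raise PerfectPhylogenyViolation(
                    f"SNVs {si!r} and {sj!r} violate the perfect phylogeny "
                    "condition (carrier sets overlap without nesting)",
                    (si, sj),
                )


def tree_from_genotypes(genotypes: GenotypeMatrix,
                        root_id: str = GERMLINE) -> ClonePhylogeny:
    """Maximum-parsimony (perfect phylogeny) reconstruction from genotypes.

    The tree is rooted at an all-zero germline node.  Because each SNV is
    assumed to have arisen exactly once, SNVs with identical carrier sets
    are concurrent on one branch and the carrier sets of distinct branches
    must be nested or disjoint; otherwise a
    :class:`PerfectPhylogenyViolation` naming a conflicting SNV pair is
    raised.  Clones with identical genotypes are merged onto a single node
    whose ``clone_labels`` lists every contributing clone.  Internal nodes
    required by the character structure but matching no input clone are
    synthesised with ids ``anc1, anc2, ...``.
    """
    carriers: dict = {}
    for j, s in enumerate(genotypes.snv_ids):
        cs = frozenset(c for i, c in enumerate(genotypes.clone_ids)
                       if genotypes.values[i, j])
        if cs:
            carriers[s] = cs
    _check_compatible(carriers)

    # group concurrent SNVs (identical carrier sets) onto one branch
    groups: dict = {}
    for s, cs in carriers.items():
        groups.setdefault(cs, set()).add(s)
    # laminar family -> containment forest; larger sets are ancestors
    ordered = sorted(groups, key=lambda cs: (-len(cs), sorted(map(str, cs))))
    all_clones = frozenset(genotypes.clone_ids)
    parent_set: dict = {}
    for i, cs in enumerate(ordered):
        best = None
        for other in ordered[:i]:
            if cs < other and (best is None or len(other) < len(best)):
                best = other
        parent_set[cs] = best  # None -> attach to germline root

    # node naming: a carrier-set node is the clone whose genotype equals the
    # accumulated mutations at that node, else a synthetic ancestor
    genosets = {c: genotypes.mutation_set(c) for c in genotypes.clone_ids}
    accum: dict = {}
    for cs in ordered:
        up = parent_set[cs]
        accum[cs] = (accum[up] if up is not None else frozenset()) | groups[cs]

    by_geno: dict = {}
    for c in sorted(genosets, key=str):
        by_geno.setdefault(genosets[c], []).append(c)

    node_of: dict = {}
    counter = 0
    clone_labels: dict = {}
    for cs in ordered:
        labels = by_geno.get(accum[cs], [])
        if labels:
            name = str(labels[0])
        else:
            counter += 1
            name = f"anc{counter}"
        node_of[cs] = name
        if labels:
            clone_labels[name] = tuple(labels)

    parent_of: dict = {}
    branch_mutations: dict = {root_id: frozenset()}
    for cs in ordered:
        up = parent_set[cs]
        parent_of[node_of[cs]] = node_of[up] if up is not None else root_id
        branch_mutations[node_of[cs]] = frozenset(groups[cs])

    # clones whose genotype is empty (germline-identical) merge onto the root
    empties = by_geno.get(frozenset(), [])
    if empties:
        clone_labels[root_id] = tuple([root_id] + [str(c) for c in empties
                                                  if str(c) != root_id])
    return ClonePhylogeny(root_id, parent_of, branch_mutations, clone_labels)


# ---------------------------------------------------------------------------
# random dataset generation (localized-sampling design)


def _random_topology(rng: np.random.Generator, n_clones: int,
                     death_prob: float = 0.0) -> dict:
    """Yule-type split process: each step splits a uniformly chosen tip.

    Returns a child -> parent mapping over clones ``C1..Cn`` rooted at the
    germline.  With probability ``death_prob`` a step kills a random tip
    instead (never dropping below one tip).
    """
    parent: dict = {"C1": GERMLINE}
    tips = ["C1"]
    nxt = 2
    while len(parent) < n_clones:
        if death_prob and len(tips) > 1 and rng.random() < death_prob:
            dead = tips.pop(rng.integers(len(tips)))
            p = parent.pop(dead)
            if p != GERMLINE and p not in parent.values():
                tips.append(p)  # parent lost its last child, is a tip again
            continue
        tip = tips.pop(rng.integers(len(tips)))
        for _ in range(2):
            if len(parent) >= n_clones and tips:
                break
            child = f"C{nxt}"
            nxt += 1
            parent[child] = tip
            tips.append(child)
    return parent


def generate_random_dataset(
    n_clones: int,
    n_samples: int,
    mutations_per_branch_law=None,
    seed: int | None = None,
    death_prob: float = 0.0,
    snv_prefix: str = "M",
):
    """Random clone phylogeny with localized multi-sample compositions.

    A birth–death (Yule split with optional death) topology is drawn, each
    branch receives a random positive number of mutations, and every sample
    is populated with one tip clone plus all of its ancestral clones
    (localized sampling), with frequencies drawn from a symmetric
    Dirichlet(1) so each row sums to 1 (100% purity).

    Parameters
    ----------
    mutations_per_branch_law
        Callable ``rng -> positive int``; defaults to uniform on [1, 10].

    Returns
    -------
    (ClonePhylogeny, GenotypeMatrix, SampleComposition)
    """
    if n_clones < 2:
        raise ValueError("need at least 2 clones")
    if n_samples < 1:
        raise ValueError("need at least 1 sample")
    rng = np.random.default_rng(seed)
    if mutations_per_branch_law is None:
        mutations_per_branch_law = lambda r: int(r.integers(1, 11))

    parent_of = _random_topology(rng, n_clones, death_prob)
    counter = 0
    branch_mutations: dict = {GERMLINE: frozenset()}
    for node in sorted(parent_of):
        k = mutations_per_branch_law(rng)
        if k < 1:
            raise ValueError("mutations per branch must be positive")
        branch_mutations[node] = frozenset(
            f"{snv_prefix}{counter + i + 1}" for i in range(k))
        counter += k

    tree = ClonePhylogeny(GERMLINE, parent_of, branch_mutations)
    tips = tree.tips
    if n_samples > len(tips):
        raise ValueError(
            f"{n_samples} samples requested but the tree has {len(tips)} tips")
    chosen = [tips[i] for i in rng.choice(len(tips), n_samples, replace=False)]

    genotypes = genotypes_from_tree(tree)
    clone_ids = [n for n in tree.nodes if n != GERMLINE]
    freqs = np.zeros((n_samples, len(clone_ids)))
    for si, tip in enumerate(chosen):
        members = [n for n in tree.root_path(tip) if n != GERMLINE]
        w = rng.dirichlet(np.ones(len(members)))
        for m, f in zip(members, w):
            freqs[si, clone_ids.index(m)] = f
    comp = SampleComposition(
        tuple(f"S{i + 1}" for i in range(n_samples)), tuple(clone_ids), freqs)
    return tree, genotypes, comp


# ---------------------------------------------------------------------------
# mutational-tree export (input preparation for multi-label edit distance)


def export_mutational_tree(tree: ClonePhylogeny,
                           universe_of_snvs: Iterable) -> pd.DataFrame:
    """Tabular mutational tree with off-tree SNVs appended to the root.

    Any SNV in ``universe_of_snvs`` that is absent from the tree is listed
    on the root's mutation list so that both trees being compared carry the
    same mutation set.  Mutation-free internal branches are collapsed first.
    """
    universe = set(universe_of_snvs)
    missing_from_universe = tree.snvs - universe
    if missing_from_universe:
        raise ValueError(
            f"SNVs in tree but not in universe: {sorted(map(str, missing_from_universe))}")
    tree = tree.collapse_empty_branches()
    extra = sorted(universe - tree.snvs)
    rows = []
    for node in tree.nodes:
        muts = sorted(tree.branch_mutations.get(node, frozenset()))
        if node == tree.root_id:
            muts = extra + muts
            parent = "-"
        else:
            parent = tree.parent_of[node]
        rows.append({"node_id": node, "parent_id": parent,
                     "mutations": ",".join(str(m) for m in muts)})
    return pd.DataFrame(rows, columns=["node_id", "parent_id", "mutations"])


def parse_mutational_tree(df: pd.DataFrame) -> ClonePhylogeny:
    """Inverse of :func:`export_mutational_tree` (root extras stay on root)."""
    parent_of = {}
    branch_mutations = {}
    root = None
    for _, row in df.iterrows():
        node = row["node_id"]
        muts = frozenset(m for m in str(row["mutations"]).split(",")
                         if m and m != "nan")
        if row["parent_id"] == "-":
            root = node
            # SNVs listed on the root are off-tree placeholders, not branch
            # mutations; a germline branch set must stay empty
            branch_mutations[node] = frozenset()
        else:
            parent_of[node] = row["parent_id"]
            branch_mutations[node] = muts
    if root is None:
        raise ValueError("mutational tree table has no root row")
    return ClonePhylogeny(root, parent_of, branch_mutations)
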