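"""Copy-number gain/loss/LOH overlays on a clone phylogeny.

SNVs are packed onto abstract chromosomes (at most 30 per chromosome) and
tagged paternal or maternal.  Whole-haplotype events are placed on random
branches, interleaved at random with the branch's own mutations, and the
chromosomes are replayed along every clone's root path to obtain mutant and
wild-type copy counts per SNV per clone:

* gain — duplicate the affected chromosome copy;
* loss — delete the affected chromosome copy;
* LOH  — delete the affected copy and duplicate the other haplotype's copy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .phylo import ClonePhylogeny

__all__ = [
    "CnaEvent",
    "CopyStateTable",
    "HaplotypeAssignment",
    "assign_snvs_to_haplotypes",
    "place_cna_events",
    "evolve_copy_states",
]

log = logging.getLogger(__name__)

EVENT_TYPES = ("gain", "loss", "LOH")
HAPLOTYPES = ("paternal", "maternal")


@dataclass(frozen=True)
class CnaEvent:
    chromosome: int
    haplotype: str  # "paternal" | "maternal"
    event_type: str  # "gain" | "loss" | "LOH"
    branch: str  # node id whose incoming branch carries the event
    order_index: int  # position among events + mutations on that branch

    def __post_init__(self):
        if self.haplotype not in HAPLOTYPES:
            raise ValueError(f"bad haplotype {self.haplotype!r}")
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"bad event type {self.event_type!r}")


@dataclass(frozen=True)
class HaplotypeAssignment:
    """Per-SNV chromosome index and haplotype tag."""

    chromosome: Mapping
    haplotype: Mapping

    @property
    def n_chromosomes(self) -> int:
        return max(self.chromosome.values()) + 1 if self.chromosome else 0

    def snvs_on(self, chrom: int) -> list:
        return sorted(s for s, c in self.chromosome.items() if c == chrom)


@dataclass(frozen=True)
class CopyStateTable:
    """Mutant/wild copy counts per (clone, SNV).

    Copy-neutral states are (mutant, wild) = (1, 1) at mutated positions and
    (0, 2) elsewhere.
    """

    clone_ids: tuple
    snv_ids: tuple
    mutant_copies: np.ndarray
    wild_copies: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "clone_ids", tuple(self.clone_ids))
        object.__setattr__(self, "snv_ids", tuple(self.snv_ids))
        m = np.asarray(self.mutant_copies, dtype=np.int64)
        w = np.asarray(self.wild_copies, dtype=np.int64)
        shape = (len(self.clone_ids), len(self.snv_ids))
        if m.shape != shape or w.shape != shape:
            raise ValueError("copy matrices do not match clone/SNV ids")
        if (m < 0).any() or (w < 0).any():
            raise ValueError("copy counts must be non-negative")
        object.__setattr__(self, "mutant_copies", m)
        object.__setattr__(self, "wild_copies", w)

    @property
    def total_copies(self) -> np.ndarray:
        return self.mutant_copies + self.wild_copies

    @classmethod
    def copy_neutral(cls, genotypes) -> "CopyStateTable":
        """The diploid heterozygous table implied by a genotype matrix."""
        m = genotypes.values.astype(np.int64)
        return cls(genotypes.clone_ids, genotypes.snv_ids, m, 2 - m)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.clone_ids):
            for j, s in enumerate(self.snv_ids):
                rows.append((c, s, int(self.mutant_copies[i, j]),
                             int(self.wild_copies[i, j])))
        return pd.DataFrame(
            rows, columns=["clone_id", "snv_id", "mutant_copies", "wild_copies"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CopyStateTable":
        clones = tuple(dict.fromkeys(df["clone_id"]))
        snvs = tuple(dict.fromkeys(df["snv_id"]))
        m = np.zeros((len(clones), len(snvs)), dtype=np.int64)
        w = np.zeros_like(m)
        ci = {c: i for i, c in enumerate(clones)}
        sj = {s: j for j, s in enumerate(snvs)}
        for _, r in df.iterrows():
            m[ci[r["clone_id"]], sj[r["snv_id"]]] = r["mutant_copies"]
            w[ci[r["clone_id"]], sj[r["snv_id"]]] = r["wild_copies"]
        return cls(clones, snvs, m, w)


def assign_snvs_to_haplotypes(snv_ids: Sequence, per_chromosome_capacity: int = 30,
                              seed: int | None = None) -> HaplotypeAssignment:
    """Pack SNVs onto chromosomes of at most ``per_chromosome_capacity`` sites.

    SNVs are shuffled, split into consecutive chunks (sizes as equal as
    possible), and each SNV is tagged paternal or maternal uniformly at
    random.
    """
    snv_ids = list(snv_ids)
    if not snv_ids:
        raise ValueError("no SNVs to assign")
    rng = np.random.default_rng(seed)
    order = [snv_ids[i] for i in rng.permutation(len(snv_ids))]
    n_chrom = -(-len(order) // per_chromosome_capacity)
    # sizes as equal as possible, each <= capacity (89 -> 30, 30, 29)
    base, extra = divmod(len(order), n_chrom)
    chromosome: dict = {}
    pos = 0
    for c in range(n_chrom):
        size = base + (1 if c < extra else 0)
        for s in order[pos:pos + size]:
            chromosome[s] = c
        pos += size
    haplotype = {s: HAPLOTYPES[rng.integers(2)] for s in order}
    return HaplotypeAssignment(chromosome, haplotype)


def place_cna_events(tree: ClonePhylogeny, n_chromosomes: int,
                     events_per_chromosome_law=None,
                     seed: int | None = None) -> list:
    """Draw CNA events per chromosome and place them on random branches.

    ``events_per_chromosome_law`` is a callable ``rng -> int`` giving the
    number of events on one chromosome (default Poisson with mean 1).  Each
    event picks its type, affected haplotype, and branch uniformly; the
    within-branch ``order_index`` interleaves events with the branch's
    mutations at random (mutations occupy the remaining slots, in a random
    order drawn here as well — see :func:`evolve_copy_states`).
    """
    rng = np.random.default_rng(seed)
    if events_per_chromosome_law is None:
        events_per_chromosome_law = lambda r: int(r.poisson(1.0))
    branches = [n for n in tree.nodes if n != tree.root_id]
    if not branches:
        return []
    raw = []
    for chrom in range(n_chromosomes):
        for _ in range(events_per_chromosome_law(rng)):
            raw.append((
                chrom,
                HAPLOTYPES[rng.integers(2)],
                EVENT_TYPES[rng.integers(3)],
                branches[rng.integers(len(branches))],
            ))
    # interleave with mutations branch by branch
    events = []
    for branch in branches:
        mine = [e for e in raw if e[3] == branch]
        if not mine:
            continue
        n_slots = len(mine) + len(tree.branch_mutations.get(branch, frozenset()))
        slots = rng.permutation(n_slots)[:len(mine)]
        for (chrom, hap, etype, br), slot in zip(mine, sorted(slots)):
            events.append(CnaEvent(chrom, hap, etype, br, int(slot)))
    return events


def _mutation_order(tree: ClonePhylogeny, events: Iterable[CnaEvent],
                    seed_like: int) -> dict:
    """Assign within-branch slots to mutations, avoiding event slots."""
    taken: dict = {}
    for e in events:
        taken.setdefault(e.branch, set()).add(e.order_index)
    rng = np.random.default_rng(seed_like)
    out: dict = {}
    for branch in tree.nodes:
        muts = sorted(tree.branch_mutations.get(branch, frozenset()))
        if not muts:
            continue
        used = taken.get(branch, set())
        free = [i for i in range(len(muts) + len(used)) if i not in used]
        order = rng.permutation(len(muts))
        for m, slot in zip(muts, (free[i] for i in order)):
            out[(branch, m)] = slot
    return out


def evolve_copy_states(tree: ClonePhylogeny, events: Sequence[CnaEvent],
                       assignment: HaplotypeAssignment,
                       seed: int | None = 0) -> CopyStateTable:
    """Replay chromosomes along every root path and count copies per SNV.

    Each chromosome starts as one paternal and one maternal instance.  On a
    branch, its mutations and events fire in ``order_index`` order.  A
    mutation lands on the first surviving instance of its assigned
    haplotype; if none survives, the mutation is silently lost
    (mutant_copies stays 0, logged).  An event whose target haplotype has no
    surviving instance is a no-op (logged).  Gains duplicate a single
    instance, never double the whole complement.

    ``seed`` only drives the random within-branch order of mutations around
    the events' fixed slots.
    """
    missing = [s for s in tree.snvs if s not in assignment.chromosome]
    if missing:
        raise ValueError(f"assignment does not cover SNVs: {sorted(map(str, missing))}")
    mut_slots = _mutation_order(tree, events, 0 if seed is None else seed)
    events_by_branch: dict = {}
    for e in events:
        events_by_branch.setdefault(e.branch, []).append(e)

    snvs = sorted(tree.snvs, key=str)
    sj = {s: j for j, s in enumerate(snvs)}
    clones = tree.nodes
    n_chrom = max(assignment.n_chromosomes,
                  1 + max((e.chromosome for e in events), default=-1))
    mutant = np.zeros((len(clones), len(snvs)), dtype=np.int64)
    wild = np.zeros_like(mutant)

    # chromosome state: chrom -> list of instances, instance = (haplotype,
    # set of mutated SNVs carried); replayed depth-first with copy-on-branch
    def fresh_state():
        return {c: [("paternal", frozenset()), ("maternal", frozenset())]
                for c in range(n_chrom)}

    state_of = {tree.root_id: fresh_state()}
    for i, node in enumerate(clones):
        if node == tree.root_id:
            state = state_of[node]
        else:
            parent_state = state_of[tree.parent_of[node]]
            state = {c: list(insts) for c, insts in parent_state.items()}
            # schedule this branch's items by slot
            items = []
            for m in tree.branch_mutations.get(node, frozenset()):
                items.append((mut_slots[(node, m)], "mut", m))
            for e in events_by_branch.get(node, []):
                items.append((e.order_index, "cna", e))
            for _, kind, obj in sorted(items, key=lambda t: (t[0], t[1], str(t[2]))):
                if kind == "mut":
                    chrom = assignment.chromosome[obj]
                    hap = assignment.haplotype[obj]
                    insts = state[chrom]
                    hit = next((i for i, (h, _) in enumerate(insts) if h == hap),
                               None)
                    if hit is None:
                        log.info("mutation %s lost: haplotype %s of chromosome "
                                 "%d already deleted on branch %s", obj, hap,
                                 chrom, node)
                        continue
                    h, carried = insts[hit]
                    insts = list(insts)
                    insts[hit] = (h, carried | {obj})
                    state[chrom] = insts
                else:
                    state[obj.chromosome] = _apply_event(
                        state[obj.chromosome], obj)
            state_of[node] = state
        for chrom, insts in state.items():
            for s in assignment.snvs_on(chrom):
                if s not in sj:
                    continue
                mc = sum(1 for _, carried in insts if s in carried)
                mutant[i, sj[s]] = mc
                wild[i, sj[s]] = len(insts) - mc
    return CopyStateTable(tuple(clones), tuple(snvs), mutant, wild)


def _apply_event(instances: list, event: CnaEvent) -> list:
    """Apply one whole-chromosome event to a list of instances."""
    insts = list(instances)
    target = next((i for i, (h, _) in enumerate(insts)
                   if h == event.haplotype), None)
    if event.event_type == "gain":
        if target is None:
            log.info("gain no-op: %s", event)
            return insts
        insts.append(insts[target])
        return insts
    if event.event_type == "loss":
        if target is None:
            log.info("loss no-op: %s", event)
            return insts
        del insts[target]
        return insts
    # LOH: delete the affected copy, duplicate one copy of the other haplotype
    other_hap = "maternal" if event.haplotype == "paternal" else "paternal"
    if target is not None:
        del insts[target]
    else:
        log.info("LOH deletion no-op: %s", event)
    other = next((i for i, (h, _) in enumerate(insts) if h == other_hap), None)
    if other is not None:
        insts.append(insts[other])
    else:
        log.info("LOH duplication no-op: %s", event)
    return insts
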