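"""Post-processing for methods that emit genotypes without frequencies.

Covers constrained clone-frequency regression from observed VAFs
(``1/2 f M = V``), removal of spurious ancestral clones by comparing shared
vs descendant-unique SNV frequencies, discarding of low-frequency clones,
and detection of degenerate (star / line) inferred topologies.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable

import numpy as np
from scipy import optimize, stats

from .metrics import classify_mutation_pairs
from .phylo import ClonePhylogeny, GenotypeMatrix, SampleComposition
from .readcounts import ReadCountTable

__all__ = [
    "estimate_clone_frequencies",
    "filter_spurious_ancestors",
    "discard_rare_clones",
    "detect_degenerate_topology",
    "NonIdentifiableWarning",
]

log = logging.getLogger(__name__)


class NonIdentifiableWarning(UserWarning):
    """The genotype matrix is rank deficient; frequencies are not unique."""


def _solve_simplex_lsq(A: np.ndarray, v: np.ndarray) -> np.ndarray:
    """min ||A f - v||^2  s.t.  f >= 0, sum(f) <= 1."""
    n = A.shape[1]

    def objective(f):
        r = A @ f - v
        return 0.5 * float(r @ r), A.T @ (A @ f - v)

    constraints = [{"type": "ineq", "fun": lambda f: 1.0 - f.sum(),
                    "jac": lambda f: -np.ones(n)}]
    x0 = np.full(n, min(1.0 / n, 0.5))
    res = optimize.minimize(objective, x0, jac=True, method="SLSQP",
                            bounds=[(0.0, 1.0)] * n, constraints=constraints,
                            options={"maxiter": 500, "ftol": 1e-14})
    return np.clip(res.x, 0.0, 1.0)


def estimate_clone_frequencies(genotypes: GenotypeMatrix,
                               reads: ReadCountTable,
                               min_total: int = 50,
                               min_mutant: int = 2) -> SampleComposition:
    """Estimate clone frequencies from observed VAFs via ``1/2 f M = V``.

    Per sample, SNVs with total reads below ``min_total`` or mutant reads
    below ``min_mutant`` are excluded as unreliable, and the frequency row
    solves a non-negative least-squares problem with the row sum
    constrained to at most 1.
    """
    snv_pos = {s: j for j, s in enumerate(reads.snv_ids)}
    missing = [s for s in genotypes.snv_ids if s not in snv_pos]
    if missing:
        raise ValueError(f"reads lack SNVs: {sorted(map(str, missing))}")
    M = genotypes.values.astype(float)  # clones x snvs
    if np.linalg.matrix_rank(M) < len(genotypes.clone_ids):
        warnings.warn(
            "genotype matrix is rank deficient; estimated frequencies are "
            "not uniquely identifiable", NonIdentifiableWarning)
    cols = [snv_pos[s] for s in genotypes.snv_ids]
    freqs = np.zeros((len(reads.sample_ids), len(genotypes.clone_ids)))
    for i in range(len(reads.sample_ids)):
        total = reads.total_reads[i, cols]
        mutant = reads.mutant_reads[i, cols]
        ok = (total >= min_total) & (mutant >= min_mutant)
        if not ok.any():
            raise ValueError(
                f"no SNV passes the read filters in sample "
                f"{reads.sample_ids[i]!r}")
        v = mutant[ok] / total[ok]
        A = 0.5 * M[:, ok].T  # snvs x clones
        freqs[i] = _solve_simplex_lsq(A, v)
    return SampleComposition(reads.sample_ids, genotypes.clone_ids, freqs)


def filter_spurious_ancestors(tree: ClonePhylogeny,
                              genotypes: GenotypeMatrix,
                              composition: SampleComposition,
                              reads: ReadCountTable,
                              alpha: float = 0.05,
                              alternative: str = "greater"):
    """Drop ancestral clones whose presence is not supported by VAFs.

    Wherever an ancestor coexists with a descendant clone in a sample, the
    observed VAFs of their shared SNVs are expected to exceed those of the
    SNVs unique to the descendant.  A Welch t-test (one-sided by default)
    compares the groups; a non-significant difference (p > ``alpha``)
    removes the ancestor from that sample, reassigning its frequency to the
    nearest coexisting descendant.  Groups with fewer than two SNVs skip the
    test and retain the ancestor (logged).

    Returns ``(composition, removals)`` where removals is a list of
    ``(sample, ancestor, p_value)``.
    """
    snv_pos = {s: j for j, s in enumerate(reads.snv_ids)}
    ci = {c: i for i, c in enumerate(composition.clone_ids)}
    freq = composition.frequencies.copy()
    removals = []
    for si, sample in enumerate(composition.sample_ids):
        present = [c for c in composition.clone_ids if freq[si, ci[c]] > 0]
        for anc in sorted(present, key=str):
            if anc not in tree.parent_of and anc != tree.root_id:
                continue
            descendants = [d for d in present
                           if d != anc and tree.is_ancestor(anc, d)]
            if not descendants:
                continue
            # nearest coexisting descendant, ties lexicographic
            desc = min(descendants,
                       key=lambda d: (len(tree.root_path(d)), str(d)))
            anc_set = genotypes.mutation_set(anc)
            desc_set = genotypes.mutation_set(desc)
            shared = sorted(anc_set & desc_set, key=str)
            unique = sorted(desc_set - anc_set, key=str)
            if len(shared) < 2 or len(unique) < 2:
                log.info("skipping t-test for ancestor %s in sample %s: "
                         "too few SNVs", anc, sample)
                continue
            vaf = reads.vaf[si]
            x = vaf[[snv_pos[s] for s in shared]]
            y = vaf[[snv_pos[s] for s in unique]]
            t = stats.ttest_ind(x, y, equal_var=False, alternative=alternative)
            if t.pvalue > alpha:
                freq[si, ci[desc]] += freq[si, ci[anc]]
                freq[si, ci[anc]] = 0.0
                removals.append((sample, anc, float(t.pvalue)))
    keep = [i for i, c in enumerate(composition.clone_ids)
            if freq[:, i].max() > 0]
    new_comp = SampleComposition(
        composition.sample_ids,
        tuple(composition.clone_ids[i] for i in keep), freq[:, keep])
    return new_comp, removals


def discard_rare_clones(composition: SampleComposition,
                        threshold: float = 0.02) -> SampleComposition:
    """Zero out clone frequencies strictly below ``threshold``.

    A clone dropped from every sample is removed entirely; each affected
    row is re-normalized to its pre-filter sum (tumor purity preserved).
    """
    freq = composition.frequencies.copy()
    row_sums = freq.sum(axis=1)
    freq[freq < threshold] = 0.0
    new_sums = freq.sum(axis=1)
    if (new_sums == 0).any():
        bad = [composition.sample_ids[i] for i in np.where(new_sums == 0)[0]]
        raise ValueError(f"all clones discarded in samples: {bad}")
    freq *= (row_sums / new_sums)[:, None]
    keep = [i for i in range(freq.shape[1]) if freq[:, i].max() > 0]
    return SampleComposition(
        composition.sample_ids,
        tuple(composition.clone_ids[i] for i in keep), freq[:, keep])


def detect_degenerate_topology(tree: ClonePhylogeny) -> str:
    """Flag trees with no sequential pairs (star) or no parallel pairs (line).

    Such inferred phylogenies make the corresponding ordering error rates
    undefined and mark a method failure; healthy trees return ``"ok"``.
    """
    pairs = classify_mutation_pairs(tree)
    cats = set(pairs.values())
    if "sequential" not in cats:
        return "star"
    if "parallel" not in cats:
        return "line"
    return "ok"
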