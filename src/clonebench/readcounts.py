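"""Expected VAFs, expected depths, and the Poisson/Binomial read model.

Copy-neutral expected VAFs follow ``V = 1/2 * f @ M`` (clone frequencies
times binary genotypes, halved for heterozygosity).  CNA-aware VAFs replace
the 1/2 with the per-clone multiplier ``mutant_copies / total_copies``,
summed over clones weighted by frequency.  Observed counts draw the total
from a Poisson at the expected depth and the mutant count from a Binomial
at the expected VAF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cna import CopyStateTable
from .phylo import GenotypeMatrix, SampleComposition

__all__ = [
    "ReadCountTable",
    "expected_vaf_neutral",
    "expected_vaf_cna",
    "expected_depth_cna",
    "sample_read_counts",
    "regenerate_at_depth",
]


@dataclass(frozen=True)
class ReadCountTable:
    """Observed mutant/total reads per (sample, SNV), with the expectations
    that generated them."""

    sample_ids: tuple
    snv_ids: tuple
    mutant_reads: np.ndarray
    total_reads: np.ndarray
    expected_vaf: np.ndarray | None = None
    expected_depth: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "snv_ids", tuple(self.snv_ids))
        m = np.asarray(self.mutant_reads, dtype=np.int64)
        t = np.asarray(self.total_reads, dtype=np.int64)
        shape = (len(self.sample_ids), len(self.snv_ids))
        if m.shape != shape or t.shape != shape:
            raise ValueError("read matrices do not match sample/SNV ids")
        if (m < 0).any() or (t < 0).any() or (m > t).any():
            raise ValueError("need 0 <= mutant_reads <= total_reads")
        object.__setattr__(self, "mutant_reads", m)
        object.__setattr__(self, "total_reads", t)
        if self.expected_vaf is not None:
            v = np.asarray(self.expected_vaf, dtype=float)
            if (v < 0).any() or (v > 1).any():
                raise ValueError("expected VAF must lie in [0, 1]")
            object.__setattr__(self, "expected_vaf", v)
        if self.expected_depth is not None:
            object.__setattr__(
                self, "expected_depth",
                np.asarray(self.expected_depth, dtype=float))

    @property
    def vaf(self) -> np.ndarray:
        """Observed mutant fraction, NaN where total is 0."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total_reads > 0,
                            self.mutant_reads / np.maximum(self.total_reads, 1),
                            np.nan)

    def to_frame(self) -> pd.DataFrame:
        """Wide TSV dialect: one row per SNV, ``<sample>:ref``/``<sample>:alt``
        integer columns."""
        data = {"snv_id": list(self.snv_ids)}
        for i, s in enumerate(self.sample_ids):
            data[f"{s}:ref"] = (self.total_reads[i] - self.mutant_reads[i])
            data[f"{s}:alt"] = self.mutant_reads[i]
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReadCountTable":
        samples = []
        for col in df.columns:
            if col.endswith(":ref"):
                samples.append(col[:-4])
        snvs = tuple(df["snv_id"])
        ref = np.stack([df[f"{s}:ref"].to_numpy(dtype=np.int64) for s in samples])
        alt = np.stack([df[f"{s}:alt"].to_numpy(dtype=np.int64) for s in samples])
        return cls(tuple(samples), snvs, alt, ref + alt)


def _align_clones(composition: SampleComposition, clone_ids) -> np.ndarray:
    if set(composition.clone_ids) - set(clone_ids):
        missing = sorted(map(str, set(composition.clone_ids) - set(clone_ids)))
        raise ValueError(f"clones in composition without genotypes: {missing}")
    idx = [clone_ids.index(c) for c in composition.clone_ids]
    return np.asarray(idx, dtype=int)


def expected_vaf_neutral(composition: SampleComposition,
                         genotypes: GenotypeMatrix) -> np.ndarray:
    """``V = 1/2 * f @ M`` — samples x SNVs matrix with entries in [0, 1/2]."""
    idx = _align_clones(composition, genotypes.clone_ids)
    # written as f @ (M/2) so that the copy-neutral CNA path (multiplier
    # matrix equal to M/2) reduces to it bit for bit
    M = genotypes.values[idx].astype(float)
    return composition.frequencies @ (0.5 * M)


def expected_vaf_cna(composition: SampleComposition,
                     copy_states: CopyStateTable) -> np.ndarray:
    """CNA-aware expected VAF.

    Per clone the frequency is scaled by ``mutant_copies / total_copies``
    (e.g. two mutant and one wild copy give the multiplier 2/3 = 0.67) and
    the products are summed over clones.  A clone with zero total copies at
    a site contributes 0.
    """
    idx = _align_clones(composition, copy_states.clone_ids)
    total = copy_states.total_copies[idx].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mult = np.where(total > 0,
                        copy_states.mutant_copies[idx] / np.maximum(total, 1),
                        0.0)
    # guard against 1 + ulp when frequencies sum to exactly 1 at multiplier 1
    return np.clip(composition.frequencies @ mult, 0.0, 1.0)


def expected_depth_cna(composition: SampleComposition,
                       copy_states: CopyStateTable,
                       base_depth: float = 100.0) -> np.ndarray:
    """Copy-number-weighted expected total read count per (sample, SNV).

    Each clone contributes ``base_depth * frequency * total_copies / 2``;
    diploid normal cells contribute ``base_depth * normal_fraction``.
    """
    if base_depth <= 0:
        raise ValueError("base_depth must be positive")
    idx = _align_clones(composition, copy_states.clone_ids)
    total = copy_states.total_copies[idx].astype(float)
    depth = base_depth * composition.frequencies @ (total / 2.0)
    return depth + base_depth * composition.normal_fraction[:, None]


def sample_read_counts(expected_vaf: np.ndarray, expected_depth,
                       seed: int | None = None,
                       sample_ids=None, snv_ids=None) -> ReadCountTable:
    """Draw ``total ~ Poisson(depth)`` then ``mutant ~ Binomial(total, vaf)``."""
    vaf = np.asarray(expected_vaf, dtype=float)
    depth = np.broadcast_to(np.asarray(expected_depth, dtype=float), vaf.shape)
    if (vaf < 0).any() or (vaf > 1).any():
        raise ValueError("expected VAF must lie in [0, 1]")
    if (depth < 0).any():
        raise ValueError("expected depth must be non-negative")
    rng = np.random.default_rng(seed)
    total = rng.poisson(depth)
    mutant = rng.binomial(total, vaf)
    if sample_ids is None:
        sample_ids = tuple(f"S{i + 1}" for i in range(vaf.shape[0]))
    if snv_ids is None:
        snv_ids = tuple(f"M{j + 1}" for j in range(vaf.shape[1]))
    return ReadCountTable(tuple(sample_ids), tuple(snv_ids), mutant, total,
                          expected_vaf=vaf, expected_depth=np.array(depth))


def regenerate_at_depth(genotypes: GenotypeMatrix,
                        composition: SampleComposition,
                        depth: float, seed: int | None = None) -> ReadCountTable:
    """Re-emit read counts from known truth at a constant alternative depth
    (e.g. regenerate a 200x dataset at 50x)."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    vaf = expected_vaf_neutral(composition, genotypes)
    return sample_read_counts(vaf, np.full_like(vaf, float(depth)), seed=seed,
                              sample_ids=composition.sample_ids,
                              snv_ids=genotypes.snv_ids)
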