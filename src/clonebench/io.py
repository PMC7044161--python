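"""Readers and writers for the toolkit's TSV and Newick dialects.

All tables are plain tab-separated text.  Dialects:

* genotype TSV — rows clones, columns SNV ids, entries 0/1;
* composition TSV — rows samples, columns clones, fractions in [0, 1];
* read-count TSV — ``snv_id`` column then ``<sample>:ref`` / ``<sample>:alt``
  integer columns;
* copy-state TSV — ``clone_id, snv_id, mutant_copies, wild_copies``;
* mutational-tree TSV — ``node_id, parent_id, mutations`` (comma-separated
  list, root's parent is ``-``);
* Newick — rooted, multifurcating, duplicate tip labels allowed.
"""

from __future__ import annotations

import hashlib
import json
import os
from pathlib import Path

import pandas as pd

from .cna import CopyStateTable
from .phylo import (ClonePhylogeny, GenotypeMatrix, SampleComposition,
                    export_mutational_tree, parse_mutational_tree)
from .readcounts import ReadCountTable
from .trees import LabeledTree, parse_newick


class FormatError(ValueError):
    """A file does not conform to its dialect; names the offending row."""


def _atomic_write(path, text: str) -> None:
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


# -- genotype ---------------------------------------------------------------

def write_genotypes(genotypes: GenotypeMatrix, path) -> None:
    _atomic_write(path, genotypes.to_frame().to_csv(sep="\t",
                                                    index_label="clone_id"))


def read_genotypes(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="clone_id")
    for clone, row in df.iterrows():
        if not row.isin((0, 1)).all():
            raise FormatError(f"non-binary genotype entry in row {clone!r}")
    return GenotypeMatrix.from_frame(df.astype(int))


# -- composition ------------------------------------------------------------

def write_composition(composition: SampleComposition, path) -> None:
    _atomic_write(path, composition.to_frame().to_csv(
        sep="\t", index_label="sample_id", float_format="%.17g"))


def read_composition(path) -> SampleComposition:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    for sample, row in df.iterrows():
        if (row < 0).any():
            raise FormatError(f"negative frequency in row {sample!r}")
        if row.sum() > 1 + 1e-9:
            raise FormatError(f"frequencies sum beyond 1 in row {sample!r}")
    return SampleComposition.from_frame(df)


# -- read counts ------------------------------------------------------------

def write_read_counts(reads: ReadCountTable, path) -> None:
    _atomic_write(path, reads.to_frame().to_csv(sep="\t", index=False))


def read_read_counts(path) -> ReadCountTable:
    df = pd.read_csv(path, sep="\t")
    alt_cols = [c for c in df.columns if c.endswith(":alt")]
    for _, row in df.iterrows():
        for col in alt_cols:
            ref_col = col[:-4] + ":ref"
            if row[col] < 0 or row[ref_col] < 0:
                raise FormatError(
                    f"negative read count for SNV {row['snv_id']!r}")
    return ReadCountTable.from_frame(df)


# -- copy states ------------------------------------------------------------

def write_copy_states(states: CopyStateTable, path) -> None:
    _atomic_write(path, states.to_frame().to_csv(sep="\t", index=False))


def read_copy_states(path) -> CopyStateTable:
    return CopyStateTable.from_frame(pd.read_csv(path, sep="\t"))


# -- mutational tree --------------------------------------------------------

def write_mutational_tree(tree: ClonePhylogeny, path,
                          universe_of_snvs=None) -> None:
    universe = universe_of_snvs if universe_of_snvs is not None else tree.snvs
    df = export_mutational_tree(tree, universe)
    _atomic_write(path, df.to_csv(sep="\t", index=False))


def read_mutational_tree(path) -> ClonePhylogeny:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return parse_mutational_tree(df)


# -- newick -----------------------------------------------------------------

def write_newick(tree: LabeledTree, path) -> None:
    _atomic_write(path, tree.to_newick() + "\n")


def read_newick(path) -> LabeledTree:
    return parse_newick(Path(path).read_text())


# -- manifest ---------------------------------------------------------------

def write_manifest(out_dir, files, extra: dict | None = None) -> Path:
    """Record every output file with a sha256 content checksum."""
    out_dir = Path(out_dir)
    entries = {}
    for f in files:
        p = Path(f)
        entries[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {"files": entries}
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    _atomic_write(path, json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
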