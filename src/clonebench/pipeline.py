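"""End-to-end dataset recipes and truth-vs-inference evaluation.

``RunConfig`` bundles a scenario preset with its parameters and a master
seed; every stochastic step receives a child seed spawned deterministically
from the master, so a (config, seed) pair reproduces its bundle bit for
bit.  Presets:

* ``localized``   — random birth–death phylogeny, one tip clone plus its
  ancestors per sample, read counts at a constant depth;
* ``growth``      — 3D lattice tumor, sector sampling, SNV filter, clone
  calling, read counts at depth 100;
* ``cna-overlay`` — localized truth with whole-haplotype gain/loss/LOH
  events, CNA-aware VAFs and depths;
* ``depth-regen`` — localized truth re-sequenced at an alternative depth
  (50x by default).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as cbio
from .cna import assign_snvs_to_haplotypes, evolve_copy_states, place_cna_events
from .growth import call_clones, grow_tumor, sample_sectors, sampled_cells_frame
from .metrics import (CloneMapping, EvaluationReport, classify_mutation_pairs,
                      count_detected_ancestral, map_clones, ordering_error_rate,
                      rf_distance, snv_assignment_error, treevec_distance,
                      true_ancestral_clones, CATEGORIES)
from .phylo import (ClonePhylogeny, GenotypeMatrix, PerfectPhylogenyViolation,
                    SampleComposition, generate_random_dataset,
                    genotypes_from_tree, tree_from_genotypes)
from .postproc import detect_degenerate_topology
from .readcounts import (expected_depth_cna, expected_vaf_cna,
                         expected_vaf_neutral, regenerate_at_depth,
                         sample_read_counts)
from .trees import tip_tree_from_clone_phylogeny

log = logging.getLogger(__name__)

PRESETS = ("localized", "growth", "cna-overlay", "depth-regen")


@dataclass
class RunConfig:
    """Scenario preset, parameters, master seed and output directory."""

    preset: str
    seed: int = 0
    out_dir: str = "."
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.preset not in PRESETS:
            raise ValueError(f"preset must be one of {PRESETS}")

    def child_seeds(self, n: int) -> list:
        ss = np.random.SeedSequence(self.seed)
        return [int(s.generate_state(1)[0]) for s in ss.spawn(n)]

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(**yaml.safe_load(text))


def simulate(config: RunConfig) -> dict:
    """Generate a dataset bundle; returns the in-memory pieces and writes
    the truth + read-count files plus a checksum manifest to ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = dict(config.params)
    s_truth, s_cna, s_reads = config.child_seeds(3)

    copy_states = None
    events = None
    cells_df = None
    if config.preset == "growth":
        tumor = grow_tumor(
            p.get("model", "constant"), k=p.get("k", 10.0),
            rate=p.get("rate", 1.0), N=p.get("N", 10000),
            mutation_mean=p.get("mutation_mean", 1.0), seed=s_truth)
        sectors = sample_sectors(
            tumor, n_sectors=p.get("n_sectors", 8),
            cells_per_sector=p.get("cells_per_sector", 100), seed=s_cna)
        genotypes, composition, _ = call_clones(
            sectors, maf_threshold=p.get("maf_threshold", 0.05))
        tree = tree_from_genotypes(genotypes)
        cells_df = sampled_cells_frame(sectors)
        vaf = expected_vaf_neutral(composition, genotypes)
        depth = np.full_like(vaf, float(p.get("depth", 100)))
    else:
        tree, genotypes, composition = generate_random_dataset(
            n_clones=p.get("n_clones", 7),
            n_samples=p.get("n_samples", p.get("n_clones", 7) // 2 or 1),
            seed=s_truth)
        if config.preset == "cna-overlay":
            assignment = assign_snvs_to_haplotypes(
                sorted(tree.snvs), p.get("per_chromosome_capacity", 30),
                seed=s_cna)
            events = place_cna_events(
                tree, assignment.n_chromosomes, seed=s_cna)
            copy_states = evolve_copy_states(tree, events, assignment,
                                             seed=s_cna)
            vaf = expected_vaf_cna(composition, copy_states)
            depth = expected_depth_cna(composition, copy_states,
                                       base_depth=p.get("depth", 100))
        elif config.preset == "depth-regen":
            vaf = expected_vaf_neutral(composition, genotypes)
            depth = np.full_like(vaf, float(p.get("depth", 50)))
        else:  # localized
            vaf = expected_vaf_neutral(composition, genotypes)
            depth = np.full_like(vaf, float(p.get("depth", 100)))

    reads = sample_read_counts(vaf, depth, seed=s_reads,
                               sample_ids=composition.sample_ids,
                               snv_ids=genotypes.snv_ids)

    files = []

    def emit(name, writer, *args):
        path = out / name
        writer(*args, path)
        files.append(path)

    emit("true_tree.tsv", cbio.write_mutational_tree, tree)
    emit("true_genotypes.tsv", cbio.write_genotypes, genotypes)
    emit("true_composition.tsv", cbio.write_composition, composition)
    emit("reads.tsv", cbio.write_read_counts, reads)
    cbio.write_newick(tip_tree_from_clone_phylogeny(tree), out / "true_tree.nwk")
    files.append(out / "true_tree.nwk")
    if copy_states is not None:
        emit("copy_states.tsv", cbio.write_copy_states, copy_states)
        ev_rows = [dataclasses.asdict(e) for e in events]
        (out / "cna_events.tsv").write_text(
            "chromosome\thaplotype\tevent_type\tbranch\torder_index\n" +
            "".join(f"{e['chromosome']}\t{e['haplotype']}\t{e['event_type']}\t"
                    f"{e['branch']}\t{e['order_index']}\n" for e in ev_rows))
        files.append(out / "cna_events.tsv")
    if cells_df is not None:
        (out / "sampled_cells.tsv").write_text(
            cells_df.to_csv(sep="\t", index=False))
        files.append(out / "sampled_cells.tsv")
    (out / "config.yaml").write_text(config.to_yaml())
    files.append(out / "config.yaml")
    cbio.write_manifest(out, files, extra={"preset": config.preset,
                                          "seed": config.seed})
    return {"tree": tree, "genotypes": genotypes, "composition": composition,
            "reads": reads, "copy_states": copy_states, "events": events}


def _reconstruct_inferred_tree(genotypes: GenotypeMatrix):
    """Parsimony reconstruction, dropping conflicting SNVs if necessary.

    Method outputs need not admit a perfect phylogeny; conflicting SNV
    pairs are resolved by discarding the SNV carried by fewer clones (ties
    lexicographic) until reconstruction succeeds.  Dropped SNVs end up
    unassigned (missing from the inferred tree).
    """
    dropped = []
    current = genotypes
    while True:
        try:
            return tree_from_genotypes(current), dropped
        except PerfectPhylogenyViolation as e:
            a, b = e.args[1]
            carriers = {s: int(current.values[:, current.snv_ids.index(s)].sum())
                        for s in (a, b)}
            victim = min((a, b), key=lambda s: (carriers[s], str(s)))
            dropped.append(victim)
            keep = [j for j, s in enumerate(current.snv_ids) if s != victim]
            current = GenotypeMatrix(
                current.clone_ids,
                tuple(current.snv_ids[j] for j in keep),
                current.values[:, keep])


def evaluate(true_tree: ClonePhylogeny,
             true_genotypes: GenotypeMatrix,
             true_composition: SampleComposition | None,
             inferred_genotypes: GenotypeMatrix,
             inferred_tree: ClonePhylogeny | None = None) -> EvaluationReport:
    """Score an inferred clone set (and optionally its tree) against truth."""
    # drop explicit germline rows from genotype matrices before mapping
    def strip_germline(g: GenotypeMatrix) -> GenotypeMatrix:
        keep = [i for i, c in enumerate(g.clone_ids)
                if str(c) != true_tree.root_id]
        if len(keep) == len(g.clone_ids):
            return g
        return GenotypeMatrix(tuple(g.clone_ids[i] for i in keep),
                              g.snv_ids, g.values[keep])

    tg = strip_germline(true_genotypes)
    ig = strip_germline(inferred_genotypes)
    mapping = map_clones(tg, ig)
    flags = []
    dropped: list = []
    if inferred_tree is None:
        inferred_tree, dropped = _reconstruct_inferred_tree(inferred_genotypes)
        if dropped:
            flags.append(f"dropped {len(dropped)} conflicting SNVs during "
                         "inferred-tree reconstruction")

    true_pairs = classify_mutation_pairs(true_tree)
    inf_pairs = classify_mutation_pairs(inferred_tree)
    ordering = {}
    for cat in CATEGORIES:
        rate = ordering_error_rate(true_pairs, inf_pairs, cat)
        ordering[cat] = rate
        if rate is None:
            flags.append(f"no inferred {cat} pairs: rate undefined")
    shape = detect_degenerate_topology(inferred_tree)
    if shape != "ok":
        flags.append(f"degenerate inferred topology: {shape}")

    true_lt = tip_tree_from_clone_phylogeny(true_tree)
    label_map = {str(f): str(mapping.mapping[f]) for f in mapping.mapping}
    inf_lt = tip_tree_from_clone_phylogeny(inferred_tree,
                                           include_germline=True,
                                           label_map=label_map)
    tv = treevec_distance(true_lt, inf_lt)
    try:
        rf = rf_distance(true_lt,
                         tip_tree_from_clone_phylogeny(inferred_tree),
                         mapping)
    except ValueError as e:
        rf = None
        flags.append(f"RF undefined: {e}")

    err = snv_assignment_error(tg, ig, mapping)
    detected = true_total = None
    if true_composition is not None:
        detected = count_detected_ancestral(true_tree, true_composition, mapping)
        true_total = len(true_ancestral_clones(true_tree, true_composition))
    return EvaluationReport(
        ordering_error=ordering, treevec=tv, rf=rf,
        snv_assignment_error=err, ancestral_detected=detected,
        ancestral_true=true_total, failure_flags=flags)


def evaluate_files(truth_dir, inferred_genotypes_path,
                   inferred_tree_path=None, out_path=None) -> EvaluationReport:
    """File-level wrapper around :func:`evaluate`."""
    truth_dir = Path(truth_dir)
    tree = cbio.read_mutational_tree(truth_dir / "true_tree.tsv")
    genotypes = cbio.read_genotypes(truth_dir / "true_genotypes.tsv")
    comp_path = truth_dir / "true_composition.tsv"
    composition = cbio.read_composition(comp_path) if comp_path.exists() else None
    inferred = cbio.read_genotypes(inferred_genotypes_path)
    inferred_tree = (cbio.read_mutational_tree(inferred_tree_path)
                     if inferred_tree_path else None)
    report = evaluate(tree, genotypes, composition, inferred, inferred_tree)
    if out_path:
        Path(out_path).write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Simulate-mode entry point (the evaluate mode lives in
    :func:`evaluate_files`)."""
    return simulate(config)
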