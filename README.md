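# clonebench

Simulation and evaluation toolkit for benchmarking tumor clone-deconvolution
methods on multi-sample bulk-sequencing data.

The simulators generate read-count datasets from known clone phylogenies:

- **localized** — random birth–death clone phylogenies where every tumor
  sample contains one tip clone plus all of its ancestors;
- **growth** — agent-based 3D lattice tumor growth (constant / step / linear
  division models), sector sampling, SNV filtering and clone calling;
- **cna-overlay** — whole-haplotype copy-number gains, losses and LOH evolved
  along the phylogeny, with CNA-aware expected VAFs and depths;
- **depth-regen** — re-emission of a truth set at an alternative sequencing
  depth (e.g. 50x).

Observed counts follow a Poisson (total reads) / Binomial (mutant reads)
model. The evaluation suite scores an inferred clone set against the truth
with mutation-pair ordering error rates (concurrent / sequential /
parallel), a duplicate-label-aware tree-vector distance, rooted
Robinson–Foulds with best-match tip pruning, per-clone SNV assignment error
and ancestral-clone detection counts. Post-processing utilities cover
clone-frequency regression (`1/2 f M = V` with non-negativity and simplex
constraints), spurious-ancestor filtering by t-test, low-frequency clone
discard, and star/line degenerate-topology detection.

## Test

```bash
python -m pytest -q tests/
```

The suite includes property tests (hypothesis), oracle-equivalence checks
(naive brute-force implementations of every tree metric) and an acceptance
suite (`tests/test_acceptance.py`).

## CLI

```bash
# simulate a dataset bundle (truth + read counts + manifest)
clonebench simulate --preset localized --seed 1 --out out/dataset1
clonebench simulate --preset growth --seed 2 --out out/tg \
    --param model=constant --param N=10000

# score an inferred clone genotype matrix against the truth
clonebench evaluate --truth out/dataset1 \
    --inferred out/dataset1/true_genotypes.tsv --out report.json
```

All outputs are plain TSV / Newick / JSON; `manifest.json` lists every file
with a sha256 checksum, and a (preset, seed) pair reproduces its bundle
byte for byte.

## Layout

| module | contents |
| --- | --- |
| `clonebench.phylo` | clone phylogenies, genotype matrices, sample compositions, perfect-phylogeny reconstruction, random dataset generation, mutational-tree export |
| `clonebench.cna` | SNV→chromosome/haplotype assignment, CNA event placement, copy-state evolution |
| `clonebench.readcounts` | expected VAF/depth (neutral and CNA-aware), Poisson/Binomial read sampling, depth regeneration |
| `clonebench.growth` | lattice tumor growth, sector sampling, clone calling |
| `clonebench.metrics` | pair classification, ordering error rates, clone mapping, TreeVec, RF, ancestral-clone counts |
| `clonebench.postproc` | frequency regression, spurious-ancestor filter, rare-clone discard, degenerate-topology flag |
| `clonebench.trees`, `clonebench.io`, `clonebench.pipeline`, `clonebench.cli` | multi-label trees + Newick, TSV dialects, dataset recipes, CLI |
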