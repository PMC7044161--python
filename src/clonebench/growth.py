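"""Agent-based 3D lattice tumor growth with sector sampling and clone calling.

Cells occupy sites of a face-centred-cubic packing (the 12-neighbour 3D
analogue of a hexagonal lattice).  Division waiting times are gamma
distributed (shape ``k``, mean ``1/rate``) and three division models are
supported:

* ``constant`` — every cell divides at the base rate; an interior cell
  pushes a chain of neighbours outward along a random lattice direction;
* ``step`` — a cell divides only while it has at least one empty
  neighbour site;
* ``linear`` — the division rate is proportional to the fraction of empty
  neighbour sites (implemented by thinning: accept a firing with
  probability empty/12).

Each division hands the newly created daughter a Poisson-distributed set of
brand-new SNVs (infinite sites).  There is no cell death and no migration.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .phylo import GenotypeMatrix, SampleComposition

__all__ = [
    "LatticeTumor",
    "SampledCell",
    "NEIGHBOR_OFFSETS",
    "grow_tumor",
    "sample_sectors",
    "call_clones",
]

# face-centred cubic: sites with even coordinate sum, 12 nearest neighbours
NEIGHBOR_OFFSETS = tuple(
    (dx, dy, dz)
    for dx, dy, dz in [
        (1, 1, 0), (1, -1, 0), (-1, 1, 0), (-1, -1, 0),
        (1, 0, 1), (1, 0, -1), (-1, 0, 1), (-1, 0, -1),
        (0, 1, 1), (0, 1, -1), (0, -1, 1), (0, -1, -1),
    ]
)

MODELS = ("constant", "step", "linear")


class GrowthDeadlock(RuntimeError):
    """No eligible cell remains before the target population was reached."""


@dataclass
class LatticeTumor:
    """Result of a growth run.

    ``parent`` and ``new_mutations`` describe the full cell pedigree;
    ``positions`` maps every *extant* cell to its lattice coordinate.
    """

    model: str
    parent: Mapping[int, int]  # cell -> parent cell; founder maps to -1
    new_mutations: Mapping[int, tuple]  # cell -> SNVs gained at its birth
    positions: Mapping[int, tuple]  # extant cell -> (x, y, z)
    k: float = 10.0
    rate: float = 1.0
    _genotype_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_extant(self) -> int:
        return len(self.positions)

    def genotype(self, cell: int) -> frozenset:
        """All SNVs carried by a cell (union along its ancestry)."""
        if cell in self._genotype_cache:
            return self._genotype_cache[cell]
        chain = []
        cur = cell
        while cur != -1 and cur not in self._genotype_cache:
            chain.append(cur)
            cur = self.parent[cur]
        geno = self._genotype_cache.get(cur, frozenset())
        for c in reversed(chain):
            geno = geno | frozenset(self.new_mutations[c])
            self._genotype_cache[c] = geno
        return self._genotype_cache[cell]

    def n_divisions(self, cell: int) -> int:
        """Birth events separating a cell from the founder."""
        n = 0
        while self.parent[cell] != -1:
            cell = self.parent[cell]
            n += 1
        return n


@dataclass(frozen=True)
class SampledCell:
    cell_id: int
    sector: str
    coordinate: tuple
    mutations: frozenset


def _empty_neighbors(pos, occupancy):
    x, y, z = pos
    return [(x + dx, y + dy, z + dz) for dx, dy, dz in NEIGHBOR_OFFSETS
            if (x + dx, y + dy, z + dz) not in occupancy]


def grow_tumor(model: str, k: float = 10.0, rate: float = 1.0, N: int = 10000,
               mutation_mean: float = 1.0, seed: int | None = None) -> LatticeTumor:
    """Grow a tumor from a single founder to exactly ``N`` extant cells."""
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    if N < 2:
        raise ValueError("N must be at least 2")
    rng = np.random.default_rng(seed)

    parent = {0: -1}
    new_mutations = {0: ()}
    positions = {0: (0, 0, 0)}
    occupancy = {(0, 0, 0): 0}
    next_id = 1
    mut_counter = 0
    seq = 0  # heap tiebreaker

    def waiting():
        return rng.gamma(k, 1.0 / (k * rate))

    queue = [(waiting(), seq, 0)]
    while len(positions) < N:
        if not queue:
            raise GrowthDeadlock(
                f"no eligible cell left at population {len(positions)} "
                f"(target {N}, model {model!r})")
        t, _, cell = heapq.heappop(queue)
        pos = positions.get(cell)
        if pos is None:  # defensive; cells never die
            continue
        empty = _empty_neighbors(pos, occupancy)
        if model in ("step", "linear") and not empty:
            # fully surrounded; without death it stays surrounded forever
            continue
        if model == "linear" and rng.random() >= len(empty) / 12.0:
            seq += 1
            heapq.heappush(queue, (t + waiting(), seq, cell))
            continue

        if model == "constant":
            # push a chain of cells along a random lattice direction
            d = NEIGHBOR_OFFSETS[rng.integers(12)]
            chain = []
            cur = (pos[0] + d[0], pos[1] + d[1], pos[2] + d[2])
            while cur in occupancy:
                chain.append(cur)
                cur = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
            for site in reversed(chain):
                moved = occupancy.pop(site)
                dest = (site[0] + d[0], site[1] + d[1], site[2] + d[2])
                occupancy[dest] = moved
                positions[moved] = dest
            daughter_pos = (pos[0] + d[0], pos[1] + d[1], pos[2] + d[2])
        else:
            daughter_pos = empty[rng.integers(len(empty))]

        daughter = next_id
        next_id += 1
        n_new = rng.poisson(mutation_mean)
        muts = tuple(range(mut_counter, mut_counter + n_new))
        mut_counter += n_new
        parent[daughter] = cell
        new_mutations[daughter] = muts
        positions[daughter] = daughter_pos
        occupancy[daughter_pos] = daughter
        seq += 1
        heapq.heappush(queue, (t + waiting(), seq, cell))
        seq += 1
        heapq.heappush(queue, (t + waiting(), seq, daughter))

    return LatticeTumor(model=model, parent=parent, new_mutations=new_mutations,
                        positions=positions, k=k, rate=rate)


def sample_sectors(tumor: LatticeTumor, n_sectors: int = 8,
                   cells_per_sector: int = 100,
                   seed: int | None = None,
                   n_anchor_candidates: int = 200) -> dict:
    """Sample disjoint, uniformly spread sectors of cells.

    Anchors are chosen by farthest-point greed among random candidate
    cells; each sector then takes the ``cells_per_sector`` cells nearest
    its anchor, never reusing a cell.
    """
    if tumor.n_extant < n_sectors * cells_per_sector:
        raise ValueError(
            f"tumor has {tumor.n_extant} cells, need at least "
            f"{n_sectors * cells_per_sector}")
    rng = np.random.default_rng(seed)
    cells = sorted(tumor.positions)
    coords = np.array([tumor.positions[c] for c in cells], dtype=float)

    cand_idx = rng.choice(len(cells), size=min(n_anchor_candidates, len(cells)),
                          replace=False)
    cand = coords[cand_idx]
    centroid = coords.mean(axis=0)
    anchors = [int(cand_idx[np.argmax(((cand - centroid) ** 2).sum(axis=1))])]
    while len(anchors) < n_sectors:
        dists = np.min(
            [((cand - coords[a]) ** 2).sum(axis=1) for a in anchors], axis=0)
        anchors.append(int(cand_idx[np.argmax(dists)]))

    taken = np.zeros(len(cells), dtype=bool)
    sectors: dict = {}
    for s, a in enumerate(anchors):
        d = ((coords - coords[a]) ** 2).sum(axis=1)
        d[taken] = np.inf
        pick = np.argsort(d, kind="stable")[:cells_per_sector]
        taken[pick] = True
        name = f"S{s + 1}"
        sectors[name] = [
            SampledCell(cells[i], name, tuple(map(int, coords[i])),
                        tumor.genotype(cells[i]))
            for i in pick
        ]
    return sectors


def call_clones(sectors: Mapping[str, Sequence[SampledCell]],
                maf_threshold: float = 0.05):
    """Filter SNVs, collapse identical genotypes into clones, count frequencies.

    An SNV is retained iff strictly more than ``maf_threshold`` of all
    pooled sampled cells carry it.  Cells whose genotypes (restricted to
    retained SNVs) are identical form one clone; per-sector clone
    frequencies are cell counts divided by the sector size.

    Returns ``(GenotypeMatrix, SampleComposition, retained SNV list)``.
    """
    if not sectors:
        raise ValueError("no sectors given")
    pooled = [c for cells in sectors.values() for c in cells]
    n_cells = len(pooled)
    counts: dict = {}
    for c in pooled:
        for m in c.mutations:
            counts[m] = counts.get(m, 0) + 1
    retained = sorted(m for m, n in counts.items() if n > maf_threshold * n_cells)
    keep = frozenset(retained)

    genosets: dict = {}  # restricted genotype -> clone name (discovery order)
    for c in pooled:
        g = c.mutations & keep
        if g not in genosets:
            genosets[g] = f"C{len(genosets) + 1}"

    clone_ids = [genosets[g] for g in genosets]
    order = {name: i for i, name in enumerate(clone_ids)}
    sj = {m: j for j, m in enumerate(retained)}
    vals = np.zeros((len(clone_ids), len(retained)), dtype=np.int8)
    for g, name in genosets.items():
        for m in g:
            vals[order[name], sj[m]] = 1
    genotypes = GenotypeMatrix(tuple(clone_ids), tuple(retained), vals)

    sample_ids = sorted(sectors)
    freq = np.zeros((len(sample_ids), len(clone_ids)))
    for i, s in enumerate(sample_ids):
        for c in sectors[s]:
            freq[i, order[genosets[c.mutations & keep]]] += 1
        freq[i] /= len(sectors[s])
    composition = SampleComposition(tuple(sample_ids), tuple(clone_ids), freq)
    return genotypes, composition, retained


def sampled_cells_frame(sectors: Mapping[str, Sequence[SampledCell]]) -> pd.DataFrame:
    """TSV dialect: cell_id, sector, x, y, z, comma-separated mutation list."""
    rows = []
    for s in sorted(sectors):
        for c in sectors[s]:
            rows.append({
                "cell_id": c.cell_id, "sector": c.sector,
                "x": c.coordinate[0], "y": c.coordinate[1], "z": c.coordinate[2],
                "mutations": ",".join(str(m) for m in sorted(c.mutations)),
            })
    return pd.DataFrame(rows,
                        columns=["cell_id", "sector", "x", "y", "z", "mutations"])
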