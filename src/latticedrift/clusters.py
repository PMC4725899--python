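"""Spatial structure of the genotype field: homozygous clusters.

Under local mate choice the lattice coarsens into AA and aa domains with
heterozygotes confined to the domain walls; only matings across a wall can
move the population allele frequency.  This module labels the homozygous
connected components (periodic wrap included, adjacency = the mating
topology) and quantifies how heterozygotes sit on the boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .engine import PopulationGrid
from .exceptions import NotSpatialError
from .lattice import neighbor_table


@dataclass
class ClusterLabeling:
    """Connected homozygous components of a genotype grid.

    ``labels`` has one entry per site: 0 for heterozygotes, else a dense
    positive cluster id assigned in row-major first-encounter order.
    """

    labels: np.ndarray  # (rows, cols) int array
    cluster_genotype: dict[int, str]  # label -> "AA" | "aa"
    cluster_sizes: dict[int, int]

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)

    @property
    def n_heterozygotes(self) -> int:
        return int(np.count_nonzero(self.labels == 0))

    def largest_cluster_fraction(self) -> float:
        """Size of the largest homozygous cluster over the population size."""
        if not self.cluster_sizes:
            return 0.0
        return max(self.cluster_sizes.values()) / self.labels.size


def label_clusters(grid: PopulationGrid, topology: str) -> ClusterLabeling:
    """Label same-genotype homozygous components under ``topology``.

    Adjacency is the mating neighbourhood (g4/g6/g8) with periodic wrap, so
    a cluster may span the lattice seam.  The panmictic scheme has no
    spatial adjacency and is rejected.
    """
    kind = grid.cfg.validate_for(topology)
    if kind == "gnf":
        raise NotSpatialError("cluster analysis requires a spatial topology")

    n = grid.cfg.n_sites
    flat = grid.copies.ravel()
    table = neighbor_table(grid.cfg, kind)

    homo = flat != 1
    # edges between homozygous neighbours with identical genotype
    focal = np.repeat(np.arange(n), table.shape[1])
    nb = table.ravel()
    same = homo[focal] & homo[nb] & (flat[focal] == flat[nb])
    i, j = focal[same], nb[same]
    # include homozygous singletons via self-loops
    sl = np.flatnonzero(homo)
    adj = coo_matrix(
        (np.ones(i.size + sl.size, dtype=np.int8),
         (np.concatenate([i, sl]), np.concatenate([j, sl]))),
        shape=(n, n),
    )
    n_comp, comp = connected_components(adj, directed=False)

    labels = np.zeros(n, dtype=np.int64)
    genotype: dict[int, str] = {}
    sizes: dict[int, int] = {}
    remap: dict[int, int] = {}
    next_label = 1
    for site in range(n):  # row-major first-encounter order
        if not homo[site]:
            continue
        c = comp[site]
        if c not in remap:
            remap[c] = next_label
            genotype[next_label] = "AA" if flat[site] == 2 else "aa"
            sizes[next_label] = 0
            next_label += 1
        lab = remap[c]
        labels[site] = lab
        sizes[lab] += 1

    return ClusterLabeling(
        labels=labels.reshape(grid.cfg.rows, grid.cfg.cols),
        cluster_genotype=genotype,
        cluster_sizes=sizes,
    )


@dataclass(frozen=True)
class BoundaryStats:
    """How the heterozygotes sit relative to the homozygous domains.

    ``bridging_fraction`` — fraction of heterozygous sites with at least
    one AA neighbour *and* at least one aa neighbour (sites mediating
    between opposite domains).
    ``adjacent_AA_fraction`` / ``adjacent_aa_fraction`` — fraction of
    heterozygous sites with at least one neighbour of that homozygote.
    All fractions are over the heterozygote count; ``no_heterozygotes``
    flags the degenerate case (fractions reported as 0).
    """

    bridging_fraction: float
    adjacent_AA_fraction: float
    adjacent_aa_fraction: float
    n_heterozygotes: int
    no_heterozygotes: bool

    def as_dict(self) -> dict:
        return {
            "bridging_fraction": self.bridging_fraction,
            "adjacent_AA_fraction": self.adjacent_AA_fraction,
            "adjacent_aa_fraction": self.adjacent_aa_fraction,
            "n_heterozygotes": self.n_heterozygotes,
            "no_heterozygotes": self.no_heterozygotes,
            "definitions": {
                "bridging_fraction": "het sites with >=1 AA and >=1 aa neighbour, over het count",
                "adjacent_AA_fraction": "het sites with >=1 AA neighbour, over het count",
                "adjacent_aa_fraction": "het sites with >=1 aa neighbour, over het count",
            },
        }


def boundary_heterozygote_fraction(
    grid: PopulationGrid, topology: str
) -> BoundaryStats:
    """Boundary statistics of heterozygotes under the mating topology."""
    kind = grid.cfg.validate_for(topology)
    if kind == "gnf":
        raise NotSpatialError("boundary analysis requires a spatial topology")
    flat = grid.copies.ravel()
    table = neighbor_table(grid.cfg, kind)
    het = np.flatnonzero(flat == 1)
    if het.size == 0:
        return BoundaryStats(0.0, 0.0, 0.0, 0, True)
    nb_geno = flat[table[het]]  # (n_het, degree)
    has_AA = (nb_geno == 2).any(axis=1)
    has_aa = (nb_geno == 0).any(axis=1)
    return BoundaryStats(
        bridging_fraction=float((has_AA & has_aa).mean()),
        adjacent_AA_fraction=float(has_AA.mean()),
        adjacent_aa_fraction=float(has_aa.mean()),
        n_heterozygotes=int(het.size),
        no_heterozygotes=False,
    )


def cluster_size_distribution(
    labeling: ClusterLabeling,
) -> dict[str, dict[int, int]]:
    """Histogram of cluster sizes, split by genotype.

    Returns ``{"AA": {size: count}, "aa": {size: count}}``.
    """
    out: dict[str, dict[int, int]] = {"AA": {}, "aa": {}}
    for label, size in labeling.cluster_sizes.items():
        hist = out[labeling.cluster_genotype[label]]
        hist[size] = hist.get(size, 0) + 1
    return out
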