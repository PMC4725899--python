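"""Forward-time drift engine: the four-step generation procedure.

One neutral biallelic locus (alleles ``A``/``a``) in a constant-size
diploid population, one individual per lattice site.  Each generation:

1. *(initiation, generation 0 only)* every one of the 2N gene copies is
   independently ``A`` with probability ``p0``;
2. *mate selection* — every individual draws a mate uniformly from its
   topology's candidate set (never itself);
3. *gamete generation* — each parent passes one of its two alleles with
   equal probability;
4. *birth* — the offspring occupies the focal parent's site.

Replacement is synchronous: all offspring are formed from the parental
generation before any site is overwritten, so generations are discrete and
non-overlapping.  Individuals are monoecious (biparental reproduction with
no sex classes).  A run ends when the allele frequency hits 0 or 1 — the
two absorbing states of the drift random walk — or at ``max_generations``.

Genotypes are stored as the number of ``A`` copies per site: 0 (aa),
1 (Aa), 2 (AA).  Determinism: a run is a pure function of its parameters
(including the seed); per generation the engine consumes, in order, one
vectorised mate draw, one focal-gamete draw and one mate-gamete draw, each
over all sites in row-major order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .lattice import LatticeConfig, neighbor_table
from .exceptions import LatticeConfigError

ENGINE_VERSION = "0.1.0"

#: Genotype labels for the 0/1/2 copy encoding.
GENOTYPE_LABELS = {0: "aa", 1: "Aa", 2: "AA"}


@dataclass(frozen=True)
class SimulationParams:
    """Everything that determines a single replicate, bit for bit."""

    cfg: LatticeConfig
    topology: str
    p0: float = 0.5
    seed: int = 0
    max_generations: int | None = None  # default: 1000 * n_sites

    def __post_init__(self) -> None:
        self.cfg.validate_for(self.topology)
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError(f"p0 must be in [0, 1], got {self.p0}")
        if self.max_generations is not None and self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")

    @property
    def generation_cap(self) -> int:
        if self.max_generations is not None:
            return self.max_generations
        return 1000 * self.cfg.n_sites


@dataclass
class PopulationGrid:
    """Diploid genotype state on the lattice at one generation.

    ``copies`` holds the number of A alleles per site, shape (rows, cols).
    """

    cfg: LatticeConfig
    copies: np.ndarray
    generation: int = 0

    def __post_init__(self) -> None:
        self.copies = np.asarray(self.copies, dtype=np.int8)
        if self.copies.shape != (self.cfg.rows, self.cfg.cols):
            raise ValueError(
                f"grid shape {self.copies.shape} does not match "
                f"{self.cfg.rows}x{self.cfg.cols} lattice"
            )
        if self.copies.min() < 0 or self.copies.max() > 2:
            raise ValueError("genotype copies must be 0, 1 or 2")

    def genotype_counts(self) -> tuple[int, int, int]:
        """(n_AA, n_Aa, n_aa)."""
        flat = self.copies.ravel()
        return (
            int(np.count_nonzero(flat == 2)),
            int(np.count_nonzero(flat == 1)),
            int(np.count_nonzero(flat == 0)),
        )

    @property
    def allele_frequency(self) -> float:
        return float(self.copies.sum()) / (2 * self.cfg.n_sites)

    @property
    def is_fixed(self) -> bool:
        total = int(self.copies.sum())
        return total == 0 or total == 2 * self.cfg.n_sites

    def genotype_at(self, site: tuple[int, int]) -> str:
        return GENOTYPE_LABELS[int(self.copies[site[0] - 1, site[1] - 1])]


@dataclass
class Trajectory:
    """Per-generation record of one replicate, plus its fixation outcome.

    ``counts`` rows are (n_AA, n_Aa, n_aa) for generations 0..T; ``t_h`` is
    the first generation with allele frequency 0 or 1, or None if the run
    hit the generation cap (``capped`` True, ``fixed_allele`` None).
    """

    params: SimulationParams
    counts: np.ndarray  # shape (T+1, 3)
    t_h: int | None
    fixed_allele: str | None  # "A", "a", or None if capped
    capped: bool = False
    final_grid: PopulationGrid | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.params.cfg.n_sites

    @property
    def f_A(self) -> np.ndarray:
        """Allele frequency per generation, (2 n_AA + n_Aa) / 2N."""
        return (2 * self.counts[:, 0] + self.counts[:, 1]) / (2 * self.n)

    @property
    def heterozygosity(self) -> np.ndarray:
        """Observed heterozygosity per generation, n_Aa / N."""
        return self.counts[:, 1] / self.n

    @property
    def generations(self) -> np.ndarray:
        return np.arange(self.counts.shape[0])


def rng_for(params: SimulationParams) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(params.seed))


def initialize_population(
    params: SimulationParams, rng: np.random.Generator
) -> PopulationGrid:
    """Draw generation 0: each of the 2N gene copies is A w.p. ``p0``."""
    shape = (params.cfg.rows, params.cfg.cols, 2)
    copies = (rng.random(shape) < params.p0).sum(axis=2).astype(np.int8)
    return PopulationGrid(params.cfg, copies, generation=0)


def _step_flat(
    flat: np.ndarray,
    table: np.ndarray | None,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One synchronous generation on a flat copy-count array."""
    if table is None:  # panmictic: uniform over the other n-1 individuals
        mate = rng.integers(0, n - 1, n)
        mate += mate >= np.arange(n)
    else:
        mate = table[np.arange(n), rng.integers(0, table.shape[1], n)]
    # each parent transmits A with probability (copies / 2)
    g_focal = rng.random(n) < flat * 0.5
    g_mate = rng.random(n) < flat[mate] * 0.5
    return (g_focal.astype(np.int8) + g_mate.astype(np.int8))


def step_generation(
    grid: PopulationGrid, topology: str, rng: np.random.Generator
) -> PopulationGrid:
    """Advance one generation (synchronous replacement); returns a new grid."""
    kind = grid.cfg.validate_for(topology)
    table = None if kind == "gnf" else neighbor_table(grid.cfg, kind)
    flat = _step_flat(grid.copies.ravel(), table, grid.cfg.n_sites, rng)
    return PopulationGrid(
        grid.cfg,
        flat.reshape(grid.cfg.rows, grid.cfg.cols),
        generation=grid.generation + 1,
    )


def _simulate(
    params: SimulationParams,
    rng: np.random.Generator,
    record: bool = True,
    keep_final_grid: bool = False,
) -> Trajectory:
    cfg = params.cfg
    kind = cfg.validate_for(params.topology)
    n = cfg.n_sites
    table = None if kind == "gnf" else neighbor_table(cfg, kind)
    cap = params.generation_cap

    grid0 = initialize_population(params, rng)
    flat = grid0.copies.ravel()

    counts: list[tuple[int, int, int]] = []

    def _counts_of(arr: np.ndarray) -> tuple[int, int, int]:
        n_aa = int(np.count_nonzero(arr == 0))
        n_het = int(np.count_nonzero(arr == 1))
        return (n - n_aa - n_het, n_het, n_aa)

    if record:
        counts.append(_counts_of(flat))

    t = 0
    total = int(flat.sum())
    while total != 0 and total != 2 * n and t < cap:
        flat = _step_flat(flat, table, n, rng)
        t += 1
        total = int(flat.sum())
        if record:
            counts.append(_counts_of(flat))

    fixed = total in (0, 2 * n)
    if record:
        counts_arr = np.asarray(counts, dtype=np.int64)
    else:
        c0 = _counts_of(flat)
        counts_arr = np.asarray([c0], dtype=np.int64)

    final = None
    if keep_final_grid:
        final = PopulationGrid(cfg, flat.reshape(cfg.rows, cfg.cols), generation=t)

    return Trajectory(
        params=params,
        counts=counts_arr,
        t_h=t if fixed else None,
        fixed_allele=("A" if total == 2 * n else "a") if fixed else None,
        capped=not fixed,
        final_grid=final,
    )


def run_to_fixation(
    params: SimulationParams, keep_final_grid: bool = False
) -> Trajectory:
    """Run one replicate to allelic fixation (or the generation cap).

    Identical parameters (including the seed) give a bit-identical
    trajectory.  A capped run is returned with ``capped=True`` and
    ``fixed_allele=None`` rather than silently truncated.
    """
    return _simulate(
        params, rng_for(params), record=True, keep_final_grid=keep_final_grid
    )


def run_fixation_time(
    params: SimulationParams, rng: np.random.Generator | None = None
) -> tuple[int | None, str | None]:
    """Light-weight path for replicate studies: (t_h, fixed_allele).

    Same dynamics and draw order as :func:`run_to_fixation` without
    storing the per-generation series.
    """
    traj = _simulate(
        params, rng if rng is not None else rng_for(params), record=False
    )
    return traj.t_h, traj.fixed_allele


def run_for_generations(
    params: SimulationParams, horizon: int
) -> Trajectory:
    """Run up to ``horizon`` generations, stopping early on fixation."""
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    capped_params = replace(params, max_generations=max(horizon, 1))
    if horizon == 0:
        rng = rng_for(params)
        grid = initialize_population(params, rng)
        n_AA, n_Aa, n_aa = grid.genotype_counts()
        fixed = grid.is_fixed
        return Trajectory(
            params=params,
            counts=np.asarray([[n_AA, n_Aa, n_aa]], dtype=np.int64),
            t_h=0 if fixed else None,
            fixed_allele=("A" if n_AA == grid.cfg.n_sites else "a") if fixed else None,
            capped=not fixed,
        )
    return _simulate(capped_params, rng_for(params), record=True)
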