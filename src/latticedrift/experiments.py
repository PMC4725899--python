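"""Replicate runner and the three stock computational experiments.

* :func:`run_replicates` — fixation-time samples under one parameter set,
* :func:`sweep_sizes` — T_ave across lattice sizes and topologies, with
  through-origin slopes and equal-diversity size ratios,
* :func:`heterozygosity_curves` — mean observed heterozygosity H(T).

Every replicate gets its own random stream derived deterministically from
(base_seed, topology, population size, replicate index), so any cell of any
experiment can be reproduced in isolation and results are independent of
execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import SimulationParams, _simulate
from .lattice import TOPOLOGIES, LatticeConfig
from .stats import SlopeFit, fit_slope, size_ratio, t_ave


def replicate_seed_sequence(
    base_seed: int, topology: str, n_sites: int, rep: int
) -> np.random.SeedSequence:
    """Deterministic per-replicate stream key; independent of scheduling."""
    topo_code = TOPOLOGIES.index(topology)
    return np.random.SeedSequence((int(base_seed), topo_code, int(n_sites), int(rep)))


@dataclass
class FixationSample:
    """Fixation times across replicates of one parameter set."""

    params: SimulationParams
    t_h_values: np.ndarray
    capped_count: int
    fixed_A_count: int
    base_seed: int

    @property
    def n_replicates(self) -> int:
        return int(self.t_h_values.size) + self.capped_count

    @property
    def t_ave(self) -> float:
        return t_ave(self.t_h_values, self.capped_count)[0]

    @property
    def se(self) -> float:
        """Monte-Carlo standard error of T_ave over the uncapped runs."""
        x = self.t_h_values
        if x.size < 2:
            return float("nan")
        return float(x.std(ddof=1) / np.sqrt(x.size))


def run_replicates(
    params: SimulationParams, n_reps: int, base_seed: int
) -> FixationSample:
    """Run ``n_reps`` independent replicates and collect fixation times.

    Replicate i uses the stream from :func:`replicate_seed_sequence`; the
    ``seed`` field of ``params`` is ignored here in favour of the derived
    per-replicate streams.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    kind = params.cfg.validate_for(params.topology)
    n_sites = params.cfg.n_sites
    t_h: list[int] = []
    capped = 0
    fixed_a = 0
    for rep in range(n_reps):
        rng = np.random.default_rng(
            replicate_seed_sequence(base_seed, kind, n_sites, rep)
        )
        traj = _simulate(params, rng, record=False)
        if traj.capped:
            capped += 1
        else:
            t_h.append(traj.t_h)
            if traj.fixed_allele == "A":
                fixed_a += 1
    return FixationSample(
        params=params,
        t_h_values=np.asarray(t_h, dtype=np.int64),
        capped_count=capped,
        fixed_A_count=fixed_a,
        base_seed=base_seed,
    )


@dataclass
class SweepResult:
    """T_ave across (topology, size) cells plus per-topology slopes."""

    table: pd.DataFrame  # topology, size, n_reps, t_ave, se, capped
    slopes: dict[str, SlopeFit]
    ratios: dict[str, float]  # slope(gnf) / slope(topology)
    base_seed: int
    samples: dict[tuple[str, int], FixationSample] = field(repr=False, default_factory=dict)

    def equivalent_size(self, topology: str, panmictic_size: float) -> float:
        """Constrained-population size with the T_ave of ``panmictic_size``
        panmictic individuals (smaller because drift is slower per capita)."""
        return panmictic_size * self.ratios[topology]


def sweep_sizes(
    topologies,
    sides,
    n_reps: int,
    base_seed: int,
    p0: float = 0.5,
    max_generations: int | None = None,
) -> SweepResult:
    """T_ave over square lattices of the given side lengths.

    ``sides`` are lattice side lengths (population sizes are side**2).
    Slopes are through-origin fits of T_ave on N per topology; ratios are
    slope(gnf)/slope(topology) when gnf is part of the sweep, else only
    the identity ratio for gnf itself is defined.
    """
    sides = [int(s) for s in sides]
    if len(sides) < 2:
        raise ValueError("need >= 2 lattice sizes per topology")
    rows = []
    samples: dict[tuple[str, int], FixationSample] = {}
    slopes: dict[str, SlopeFit] = {}
    for topo in topologies:
        t_aves, sizes_ok = [], []
        for side in sides:
            cfg = LatticeConfig(side, side)
            params = SimulationParams(
                cfg=cfg, topology=topo, p0=p0, max_generations=max_generations
            )
            sample = run_replicates(params, n_reps, base_seed)
            samples[(topo, cfg.n_sites)] = sample
            all_capped = sample.t_h_values.size == 0
            rows.append(
                {
                    "topology": topo,
                    "size": cfg.n_sites,
                    "n_reps": n_reps,
                    "t_ave": float("nan") if all_capped else sample.t_ave,
                    "se": sample.se,
                    "capped": sample.capped_count,
                }
            )
            if not all_capped:
                sizes_ok.append(cfg.n_sites)
                t_aves.append(sample.t_ave)
        if len(sizes_ok) >= 2:
            slopes[topo] = fit_slope(sizes_ok, t_aves, n_reps=n_reps)
    ratios: dict[str, float] = {}
    if "gnf" in slopes:
        for topo, fit in slopes.items():
            ratios[topo] = size_ratio(fit.slope, slopes["gnf"].slope)
    return SweepResult(
        table=pd.DataFrame(rows),
        slopes=slopes,
        ratios=ratios,
        base_seed=base_seed,
        samples=samples,
    )


def heterozygosity_curves(
    cfg: LatticeConfig,
    topologies,
    n_reps: int,
    horizon: int,
    base_seed: int,
    p0: float = 0.5,
) -> pd.DataFrame:
    """Mean observed heterozygosity per generation, per topology.

    Replicates that fix before ``horizon`` contribute H = 0 from their
    fixation generation onward (the absorbed state persists; the run is
    extended virtually, not re-simulated).  Returns a tidy frame with
    columns generation, topology, mean_H, se.
    """
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    frames = []
    for topo in topologies:
        kind = cfg.validate_for(topo)
        params = SimulationParams(
            cfg=cfg, topology=topo, p0=p0, max_generations=max(horizon, 1)
        )
        h = np.zeros((n_reps, horizon + 1))
        for rep in range(n_reps):
            rng = np.random.default_rng(
                replicate_seed_sequence(base_seed, kind, cfg.n_sites, rep)
            )
            traj = _simulate(params, rng, record=True)
            series = traj.heterozygosity
            h[rep, : min(series.size, horizon + 1)] = series[: horizon + 1]
            # beyond fixation the population stays homozygous: H = 0 (already)
        frames.append(
            pd.DataFrame(
                {
                    "generation": np.arange(horizon + 1),
                    "topology": topo,
                    "mean_H": h.mean(axis=0),
                    "se": h.std(axis=0, ddof=1) / np.sqrt(n_reps) if n_reps > 1
                    else np.nan,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
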