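"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's optimised code paths: flood fill by
breadth-first search over the public neighbour list, and exact one-step /
absorption computations for the 2x2 panmictic population by exhaustive
enumeration over its 3^4-configuration state space.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np

from latticedrift import LatticeConfig, neighbors


def flood_fill_labels(copies: np.ndarray, topology: str) -> list[set]:
    """Connected same-genotype homozygous components as sets of (r, c) sites."""
    rows, cols = copies.shape
    cfg = LatticeConfig(rows, cols)
    seen = set()
    components = []
    for r in range(1, rows + 1):
        for c in range(1, cols + 1):
            g = copies[r - 1, c - 1]
            if g == 1 or (r, c) in seen:
                continue
            comp = {(r, c)}
            queue = deque([(r, c)])
            seen.add((r, c))
            while queue:
                site = queue.popleft()
                for nb in neighbors(site, topology, cfg):
                    if nb in seen or nb in comp:
                        continue
                    if copies[nb[0] - 1, nb[1] - 1] == g:
                        comp.add(nb)
                        seen.add(nb)
                        queue.append(nb)
            components.append(comp)
    return components


def _offspring_marginal_gnf(state: tuple[int, ...], site: int) -> np.ndarray:
    """P(offspring copies = 0,1,2) at ``site`` for a panmictic population.

    The mate is uniform over the other individuals; each parent transmits A
    with probability (copies / 2).
    """
    n = len(state)
    q_focal = state[site] / 2.0
    probs = np.zeros(3)
    for mate in range(n):
        if mate == site:
            continue
        q_mate = state[mate] / 2.0
        p2 = q_focal * q_mate
        p0 = (1 - q_focal) * (1 - q_mate)
        probs += np.array([p0, 1 - p0 - p2, p2]) / (n - 1)
    return probs


def exact_one_step_counts_gnf(state: tuple[int, ...]) -> dict[tuple, float]:
    """Exact distribution of (n_AA, n_Aa, n_aa) after one generation.

    Offspring are conditionally independent across sites given the parental
    state (mate choices and gamete draws are independent), so the joint law
    is the product of per-site marginals; enumerate all genotype
    combinations.
    """
    marginals = [_offspring_marginal_gnf(state, i) for i in range(len(state))]
    dist: dict[tuple, float] = {}
    for combo in itertools.product((0, 1, 2), repeat=len(state)):
        p = 1.0
        for site, g in enumerate(combo):
            p *= marginals[site][g]
        if p == 0.0:
            continue
        key = (
            sum(1 for g in combo if g == 2),
            sum(1 for g in combo if g == 1),
            sum(1 for g in combo if g == 0),
        )
        dist[key] = dist.get(key, 0.0) + p
    return dist


def exact_mean_absorption_gnf(n_sites: int = 4, p0: float = 0.5) -> float:
    """Mean generations to fixation for a tiny panmictic population.

    Builds the full genotype-configuration Markov chain (3^n states),
    solves the fundamental-matrix equations (I - Q) t = 1 for the transient
    states and averages over the binomial initial distribution.
    """
    states = list(itertools.product((0, 1, 2), repeat=n_sites))
    index = {s: i for i, s in enumerate(states)}
    n_states = len(states)

    def absorbed(s):
        total = sum(s)
        return total == 0 or total == 2 * n_sites

    transient = [s for s in states if not absorbed(s)]
    t_index = {s: i for i, s in enumerate(transient)}

    Q = np.zeros((len(transient), len(transient)))
    for s in transient:
        marginals = [_offspring_marginal_gnf(s, i) for i in range(n_sites)]
        for combo in itertools.product((0, 1, 2), repeat=n_sites):
            p = 1.0
            for site, g in enumerate(combo):
                p *= marginals[site][g]
                if p == 0.0:
                    break
            if p == 0.0 or absorbed(combo):
                continue
            Q[t_index[s], t_index[combo]] += p

    t = np.linalg.solve(np.eye(len(transient)) - Q, np.ones(len(transient)))

    # binomial initiation: each site has Binomial(2, p0) copies of A
    site_p = np.array([(1 - p0) ** 2, 2 * p0 * (1 - p0), p0**2])
    mean = 0.0
    for s in states:
        prob = float(np.prod([site_p[g] for g in s]))
        if not absorbed(s):
            mean += prob * t[t_index[s]]
    return mean
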