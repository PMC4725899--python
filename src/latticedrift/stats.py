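"""Population-genetic summary statistics and fits.

Covers: allele frequency and observed heterozygosity from genotype counts,
the inbreeding coefficient F, closed-form maximum-likelihood fitting of the
inverse-Gaussian first-passage law to fixation-time samples, the classical
expected-heterozygosity decay H_e(T) = H0 (1 - 1/(2 N_e))^T for estimating
effective population size, mean fixation time T_ave, and the
T_ave-versus-size proportionality constant with the derived equal-diversity
population-size ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .exceptions import (
    AllRunsCappedError,
    DegenerateSampleError,
    NoDecayError,
    UndefinedInbreedingError,
)


@dataclass(frozen=True)
class GenotypeCounts:
    """Counts of AA, Aa and aa individuals at one generation."""

    n_AA: int
    n_Aa: int
    n_aa: int

    def __post_init__(self) -> None:
        if min(self.n_AA, self.n_Aa, self.n_aa) < 0:
            raise ValueError("genotype counts must be non-negative")
        if self.n == 0:
            raise ValueError("population must contain at least one individual")

    @property
    def n(self) -> int:
        return self.n_AA + self.n_Aa + self.n_aa


def allele_frequency(counts: GenotypeCounts) -> float:
    """Frequency of allele A: (2 n_AA + n_Aa) / (2N)."""
    return (2 * counts.n_AA + counts.n_Aa) / (2 * counts.n)


def heterozygosity(counts: GenotypeCounts) -> float:
    """Observed heterozygosity: n_Aa / N."""
    return counts.n_Aa / counts.n


def expected_heterozygosity(counts: GenotypeCounts) -> float:
    """Expected heterozygosity 2pq under random union of gametes."""
    p = allele_frequency(counts)
    return 2.0 * p * (1.0 - p)


def inbreeding_coefficient(counts: GenotypeCounts) -> float:
    """F = 1 - H_obs / (2pq), the deficit of heterozygotes relative to HWE.

    Undefined for a fixed population (p in {0, 1}).
    """
    he = expected_heterozygosity(counts)
    if he == 0.0:
        raise UndefinedInbreedingError(
            "inbreeding coefficient undefined: population is fixed"
        )
    return 1.0 - heterozygosity(counts) / he


# ---------------------------------------------------------------------------
# inverse-Gaussian fitting of fixation times
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InverseGaussianFit:
    """MLE of the inverse-Gaussian (Wald) first-passage distribution.

    mu is the mean, lam the shape parameter; both in generations.
    """

    mu: float
    lam: float
    n: int

    def loglik(self, samples: np.ndarray) -> float:
        """Log-likelihood of ``samples`` under the fitted distribution."""
        x = np.asarray(samples, dtype=float)
        return float(
            sps.invgauss.logpdf(x, self.mu / self.lam, scale=self.lam).sum()
        )

    def pdf(self, x: np.ndarray) -> np.ndarray:
        return sps.invgauss.pdf(np.asarray(x, float), self.mu / self.lam,
                                scale=self.lam)

    def summary(self) -> str:
        return (
            "Inverse-Gaussian fit (closed-form MLE)\n"
            f"  n       {self.n}\n"
            f"  mu      {self.mu:.6g}  (mean fixation time, generations)\n"
            f"  lambda  {self.lam:.6g}  (shape, generations)\n"
        )


def fit_inverse_gaussian(samples) -> InverseGaussianFit:
    """Closed-form MLE: mu = sample mean, lam = n / sum(1/x_i - 1/mu)."""
    x = np.asarray(list(samples), dtype=float)
    if x.size < 2:
        raise DegenerateSampleError("need at least two samples")
    if np.any(x <= 0):
        raise ValueError("inverse-Gaussian samples must be strictly positive")
    mu = float(x.mean())
    denom = float(np.sum(1.0 / x) - x.size / mu)
    if denom <= 0:
        raise DegenerateSampleError(
            "zero within-sample dispersion; inverse-Gaussian fit is degenerate"
        )
    return InverseGaussianFit(mu=mu, lam=x.size / denom, n=int(x.size))


# ---------------------------------------------------------------------------
# heterozygosity decay -> effective population size
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DecayFit:
    """Fit of H_e(T) = H0 (1 - 1/(2 N_e))^T on a heterozygosity series."""

    N_e: float
    H0: float
    fit_window: tuple[int, int]
    n_points: int
    n_dropped: int  # non-positive H values excluded from the log fit

    def predict(self, generations: np.ndarray) -> np.ndarray:
        g = np.asarray(generations, dtype=float)
        return self.H0 * (1.0 - 1.0 / (2.0 * self.N_e)) ** g

    def summary(self) -> str:
        return (
            "Heterozygosity-decay fit  H(T) = H0 (1 - 1/(2 Ne))^T\n"
            f"  window    T = {self.fit_window[0]}..{self.fit_window[1]}\n"
            f"  points    {self.n_points} used, {self.n_dropped} dropped (H <= 0)\n"
            f"  Ne        {self.N_e:.6g}\n"
            f"  H0        {self.H0:.6g}\n"
        )


def fit_het_decay(
    h_series, window: tuple[int, int] | None = None
) -> DecayFit:
    """OLS of log H on T over ``window`` (inclusive generation range).

    ``h_series`` is a sequence of (generation, heterozygosity) pairs.
    Points with H <= 0 are dropped (their count is reported); at least three
    usable points are required.  A non-decreasing series has no finite
    effective size and raises :class:`NoDecayError`.
    """
    arr = np.asarray(list(h_series), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("h_series must be (generation, heterozygosity) pairs")
    gen, h = arr[:, 0], arr[:, 1]
    if window is None:
        window = (int(gen.min()), int(gen.max()))
    in_win = (gen >= window[0]) & (gen <= window[1])
    gen, h = gen[in_win], h[in_win]
    positive = h > 0
    n_dropped = int(np.count_nonzero(~positive))
    gen, h = gen[positive], h[positive]
    if gen.size < 3:
        raise DegenerateSampleError(
            f"need >= 3 positive-H points in window, have {gen.size}"
        )
    res = sps.linregress(gen, np.log(h))
    if res.slope >= 0:
        raise NoDecayError(
            "heterozygosity does not decay over the window; N_e is unbounded"
        )
    n_e = 1.0 / (2.0 * (1.0 - np.exp(res.slope)))
    return DecayFit(
        N_e=float(n_e),
        H0=float(np.exp(res.intercept)),
        fit_window=(int(window[0]), int(window[1])),
        n_points=int(gen.size),
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# mean fixation time and size scaling
# ---------------------------------------------------------------------------


def t_ave(t_h_values, capped_count: int = 0) -> tuple[float, int]:
    """Arithmetic mean of the uncapped fixation times.

    Returns (mean, excluded_count): capped replicates have no defined T_h
    and are excluded, never imputed.
    """
    x = np.asarray(list(t_h_values), dtype=float)
    if x.size == 0:
        raise AllRunsCappedError("no uncapped replicates; T_ave undefined")
    return float(x.mean()), int(capped_count)


@dataclass(frozen=True)
class SlopeFit:
    """Proportionality constant of T_ave versus population size N.

    ``slope`` is the through-origin least-squares estimate (the primary
    quantity, T_ave per individual); ``slope_with_intercept`` and
    ``intercept`` are the unconstrained OLS fit, kept as a sensitivity
    diagnostic.
    """

    slope: float
    sizes: tuple[int, ...]
    t_aves: tuple[float, ...]
    n_reps: int
    slope_with_intercept: float
    intercept: float

    def summary(self) -> str:
        rows = "\n".join(
            f"    N={s:<6d} T_ave={t:.1f}" for s, t in zip(self.sizes, self.t_aves)
        )
        return (
            "T_ave vs size fit\n"
            f"{rows}\n"
            f"  slope (through origin)  {self.slope:.4g} generations/individual\n"
            f"  slope (with intercept)  {self.slope_with_intercept:.4g} "
            f"(intercept {self.intercept:.4g})\n"
        )


def fit_slope(sizes, t_aves, n_reps: int = 0) -> SlopeFit:
    """Least-squares proportionality constant through the origin."""
    s = np.asarray(list(sizes), dtype=float)
    t = np.asarray(list(t_aves), dtype=float)
    if s.size != t.size or s.size < 2:
        raise ValueError("need >= 2 (size, t_ave) pairs")
    if np.any(t <= 0) or np.any(s <= 0):
        raise ValueError("sizes and t_aves must be positive")
    slope = float(np.sum(s * t) / np.sum(s * s))
    ols = sps.linregress(s, t)
    return SlopeFit(
        slope=slope,
        sizes=tuple(int(v) for v in s),
        t_aves=tuple(float(v) for v in t),
        n_reps=int(n_reps),
        slope_with_intercept=float(ols.slope),
        intercept=float(ols.intercept),
    )


def size_ratio(slope_constrained: float, slope_panmictic: float) -> float:
    """Population-size fraction with equal T_ave: slope_gnf / slope_topology.

    A constrained population needs only this fraction of the panmictic size
    to hold genetic diversity for as many generations.
    """
    if slope_constrained <= 0 or slope_panmictic <= 0:
        raise ValueError("slopes must be positive")
    return slope_panmictic / slope_constrained
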