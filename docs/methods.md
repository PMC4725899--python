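# Methods

## Model

One neutral locus with alleles `A` and `a` in a diploid, monoecious
population of constant size N = rows·cols, one individual per site of a
periodic lattice. Generations are discrete and non-overlapping. Each
generation consists of four steps:

1. **Initiation** (generation 0 only): each of the 2N gene copies is
   independently `A` with probability `p0` (default 0.5), so genotypes
   start at binomial proportions AA:Aa:aa ≈ p0²:2p0q0:q0².
2. **Mate selection**: every individual draws one mate uniformly from its
   candidate set — its 4, 6 or 8 nearest neighbours (`g4`/`g6`/`g8`, with
   periodic wrap) or all other N−1 individuals (`gnf`). Selfing is never
   allowed; mate choice is independent of genotype (mating is random in
   the genetic sense even when spatially constrained).
3. **Gamete generation**: each parent transmits one of its two alleles
   with probability 1/2 (a homozygote transmits its allele with
   certainty). Allele order within an individual carries no information;
   genotypes are stored as A-copy counts 0/1/2.
4. **Birth**: the offspring occupies the focal parent's site. All N
   offspring are formed from the parental generation before any site is
   replaced (synchronous update), keeping N constant.

Every individual is therefore a focal parent exactly once per generation
and is additionally chosen as a mate a Binomial(N−1, k/(N−1)·1/k) ≈
Poisson(1) number of times. Mutual choices (i picks j while j picks i)
are two independent offspring events. "Bisexual" reproduction is
interpreted as biparental: there are no sex classes and no sex-restricted
mate choice.

A run terminates when the allele frequency f reaches 0 or 1 (every
individual homozygous for the same allele — the two absorbing states of
the drift random walk); that generation index is the fixation time T_h.
Runs that hit the generation cap (default 1000·N) are flagged `capped`
and excluded from T_ave with a reported count, never silently truncated.

### Expected behaviour

Because each offspring receives exactly one gamete from its resident
parent, the variance of per-generation allele-frequency change under
panmixia is Var(Δf) = f(1−f)(3−F)/(8N) ≈ 3f(1−f)/(8N), i.e. a
variance-effective size N_e = 4N/3 — drift is slower than in a classical
Wright–Fisher population of the same census size, where every gamete is
drawn at random from the whole pool. Diffusion theory then predicts a
mean fixation time from p0 = 1/2 of about 4·N_e·ln 2 ≈ 3.70·N generations
for `gnf`; the simulator reproduces this (through-origin slope ≈ 3.6 over
N = 100–900). Local mate choice adds isolation by distance: homozygous
domains coarsen, only boundary matings move f, and T_ave grows by a
further size-dependent factor, ordered g4 > g6 > g8 > gnf (measured
slopes ≈ 5.9, 5.4, 4.8 over the same size range, with a mild upward
trend in lattice size expected from the logarithmic corrections typical
of two-dimensional stepping-stone models).

## Lattice geometry

`g4` and `g8` are the standard von Neumann and Moore neighbourhoods on a
torus. `g6` embeds a triangular lattice in the square grid: even-numbered
rows are treated as shifted left by half a cell, giving offsets
(r,c±1), (r−1,c), (r−1,c+1), (r+1,c), (r+1,c+1) on odd rows and
(r,c±1), (r−1,c−1), (r−1,c), (r+1,c−1), (r+1,c) on even rows. This
convention yields a 6-regular, symmetric neighbour relation provided the
row count is even, which is therefore enforced (an odd row count would
pair a shifted row with an unshifted one across the top/bottom seam).
Neighbour order is fixed (W, E, N, S, then diagonals; for g6 the two
upper then two lower neighbours left-to-right) so that seeded draws are
reproducible. On degenerate wraps (e.g. 2×2 under g4, where the up- and
down-neighbour coincide) the duplicate entries are kept so each
geometric direction retains probability 1/k; such lattices appear only
in exact-oracle tests. Sites are 1-based externally, 0-based row-major
internally.

## Randomness and reproducibility

All stochastic steps consume a single numpy Generator per replicate. Per
generation the engine draws, in order: the mate indices for all sites
(row-major), the focal-parent gamete uniforms, the mate gamete uniforms —
all vectorised, so a replicate is a pure function of its parameters and
seed. Replicate studies derive each replicate's stream from
`SeedSequence((base_seed, topology_code, n_sites, replicate_index))`;
results are therefore independent of execution order and any single cell
or replicate can be reproduced in isolation.

## Statistics

- **Allele frequency** f = (2n_AA + n_Aa)/(2N); **observed
  heterozygosity** H = n_Aa/N; **expected heterozygosity** 2pq;
  **inbreeding coefficient** F = 1 − H/(2pq), undefined at fixation.
  No small-sample correction (2N/(2N−1)) is applied to 2pq.
- **Inverse-Gaussian fit** of fixation-time samples by closed-form
  maximum likelihood: μ̂ = x̄ exactly, λ̂ = n/Σ(1/x_i − 1/x̄). Chosen over
  moment matching because it is exact, deterministic and hand-checkable;
  a constant sample has no MLE and raises a degenerate-fit error. The
  inverse Gaussian is the first-passage law of Brownian motion with
  drift and describes the simulated T_h distributions well — better than
  a variance-matched normal by log-likelihood — though it is an
  approximation, not an exact result, for this finite Markov chain.
- **Heterozygosity decay**: H_e(T) = H0(1 − 1/(2N_e))^T fitted by
  ordinary least squares of log H on T over a generation window;
  non-positive H values are dropped with a reported count, at least
  three points are required, and a non-decaying series raises an error
  rather than returning an unbounded N_e. Only the panmictic scheme is
  expected to follow this single-exponential decay; spatial schemes
  develop inbreeding structure (F > 0, Wahlund-like) that the one-N_e
  model does not capture.
- **T_ave versus size**: the primary estimate is the least-squares slope
  through the origin, Σ(N·T_ave)/Σ(N²), matching the proportionality the
  quantity expresses; the unconstrained OLS slope and intercept are
  reported as a sensitivity diagnostic. The equal-diversity size ratio is
  slope(gnf)/slope(topology): the fraction of the panmictic population
  size a constrained population needs for the same T_ave.
- **Cluster analysis**: homozygous connected components under the mating
  topology (the adjacency that makes within-domain matings neutral for
  f), periodic wrap included, labelled densely in row-major
  first-encounter order; heterozygotes are never cluster members.
  Boundary statistics report the fraction of heterozygotes with both AA
  and aa neighbours (bridging) and with each separately. Components are
  computed with scipy's sparse connected-components routine and verified
  against a brute-force flood fill in the tests.

## Problem sizes

The stock experiments run at desk scale: the slope sweep uses N ∈
{100, 400, 900} with 200 replicates per cell (Monte-Carlo SE of T_ave
≈ 3–5% per cell), the ordering experiment N = 100 with 6000 replicates,
and the heterozygosity experiments N = 100–400 with 400–500 replicates.
Larger boards (e.g. 50×50 for cluster snapshots) and replicate counts in
the tens of thousands are supported through the same interfaces; all
scaling choices are parameters, not limits.

## What the generator does and does not emulate

The simulator is itself the study system — there is no external data.
It captures drift, isolation by distance, domain formation and
inbreeding under the four mating topologies. It does not model
selection, mutation, migration between separate populations, overlapping
generations, separate sexes, variable population size, multiple loci or
linkage; conclusions about real populations carry over only insofar as
those forces are negligible at the locus and timescale of interest.

## Known limitations

- The hexagonal (`g6`) scheme requires an even number of rows.
- T_ave-versus-size linearity is empirical over the tested range; in two
  dimensions mild logarithmic growth of the constrained slopes with
  lattice size is expected and visible, so slope estimates are tied to
  the size range used.
- The inverse-Gaussian description of T_h is an approximation; no
  goodness-of-fit test is enforced beyond the normal-comparison check.
- Capped replicates are excluded from T_ave and distribution fits; at
  the default cap (1000·N) this exclusion is never observed in practice.
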