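# latticedrift

Forward-in-time simulation of neutral genetic drift in diploid populations
whose individuals choose mates locally on a periodic lattice — or from the
whole population — together with the statistics used to study how spatial
constraints on mating change the loss of genetic diversity.

## The problem

A single biallelic neutral locus (alleles `A`/`a`) segregates in a
constant-size population of N diploid individuals, one per site of an
L×L torus ("chessboard" with periodic boundaries). Each generation every
individual draws a mate uniformly from its candidate set and the pair
produces one offspring at the focal individual's site, receiving one
randomly chosen allele from each parent (Mendelian transmission);
replacement is synchronous. Four mate-choice topologies are supported:

| name  | candidate mates                                |
|-------|------------------------------------------------|
| `g4`  | 4 orthogonal nearest neighbours (von Neumann)   |
| `g6`  | 6 neighbours on a hexagonal lattice (even rows offset left by half a cell) |
| `g8`  | 8 nearest neighbours (Moore)                    |
| `gnf` | every other individual (panmixia)               |

Without mutation or selection the allele frequency
f = (2·n<sub>AA</sub> + n<sub>Aa</sub>)/(2N) performs an unbiased random
walk between the absorbing states f = 0 and f = 1. The package records the
fixation time T<sub>h</sub> per replicate, its mean T<sub>ave</sub> over
replicates, observed heterozygosity H = n<sub>Aa</sub>/N and the
inbreeding coefficient F = 1 − H/2pq, fits the inverse-Gaussian
first-passage law to T<sub>h</sub> samples (closed-form MLE: μ̂ = x̄,
λ̂ = n/Σ(1/x<sub>i</sub> − 1/x̄)), estimates effective population size from
H<sub>e</sub>(T) = H<sub>0</sub>(1 − 1/(2N<sub>e</sub>))<sup>T</sup>, fits
the proportionality T<sub>ave</sub> = slope·N across lattice sizes, and
labels the homozygous spatial clusters whose boundaries carry all the
allele-frequency-changing matings.

## Worked example

One replicate on a 10×10 board with 4-neighbour mating:

```bash
$ latticedrift simulate --size 10 --topology g4 --p0 0.5 --seed 1 --out demo.csv
INFO fixed allele A at generation 339
demo.csv
```

`demo.csv` holds the per-generation genotype counts and allele frequency
(`generation,n_AA,n_Aa,n_aa,f_A`; generation 0 starts at f ≈ 0.5) and
`demo.json` echoes the full parameter set, the fixation time `t_h = 339`
and the fixed allele `A` — this particular population lost allele `a`
after 339 generations.

Replicated fixation times and the inverse-Gaussian fit, from Python:

```python
from latticedrift import (LatticeConfig, SimulationParams,
                          run_replicates, fit_inverse_gaussian)

params = SimulationParams(cfg=LatticeConfig(10, 10), topology="g4", p0=0.5)
sample = run_replicates(params, 2000, base_seed=7)
print(sample.t_ave, sample.fixed_A_count / 2000)
# 466.0 0.5115      <- mean fixation time; P(A fixes) ~ p0 = 0.5
print(fit_inverse_gaussian(sample.t_h_values).summary())
# Inverse-Gaussian fit (closed-form MLE)
#   n       2000
#   mu      466.002  (mean fixation time, generations)
#   lambda  717.634  (shape, generations)
```

The mean fixation time grows proportionally with population size and with
the tightness of the spatial constraint — T<sub>ave</sub>(gnf) <
T<sub>ave</sub>(g8) < T<sub>ave</sub>(g6) < T<sub>ave</sub>(g4) — so a
locally-mating population keeps both alleles segregating longer than a
panmictic one of the same size:

```bash
latticedrift sweep --topologies g4,g6,g8,gnf --sizes 10,20,30 --n-reps 200 --seed 1
```

writes `sweep_table.csv` (T<sub>ave</sub> ± SE per cell) and `slopes.json`
with the through-origin slopes and the equal-diversity size ratios
slope(gnf)/slope(g·). Other subcommands: `curves` (mean H(T) per
topology), `clusters` (homozygous-domain labelling, sizes and
boundary-heterozygote fractions of a simulated grid), `fit` (inverse
Gaussian / heterozygosity decay on external samples). Every output embeds
its parameters and seed; identical invocations are byte-identical.

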