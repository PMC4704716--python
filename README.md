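# purgesim

Forward-in-time Wright–Fisher simulation of **genetic purging under linkage**,
with the full set of inbreeding, diversity and load statistics needed to study
what happens to fitness and neutral genetic diversity when a large population
is suddenly reduced to a small one.

`purgesim` is aimed at population and conservation geneticists who want to

* generate base populations at the mutation–selection–drift (MSD) balance for
  chosen deleterious effects (`s`, `h`), genome length `L` (or free
  recombination) and mutation rates;
* derive small lines (`N` breeders per generation) maintained with natural
  selection (MSD scenario) or with selection switched off (mutation–drift, MD);
* track, per generation, mean fitness, neutral diversity `H`, the inbreeding
  load `B`, fitness variance components, the heterozygosity–fitness
  correlation (associative overdominance), and three inbreeding measures:
  Wright's census expectation `f_N`, the contribution-based `f_Vk` via
  `Ne = (4N − 2)/(2 + V_k)`, and pedigree inbreeding `f_p` by the tabular
  coancestry method;
* compare observed fitness trajectories with the classical neutral prediction
  and with inbreeding–purging (IP) theory.

## The model

Each haploid genome is one chromosome of 20,000 selective and 1,000 neutral
marker sites (repeating batches of 20 selective sites plus one marker).
Genotypes `++`, `+m`, `mm` at a selective site have fitness `1`, `1 − hs`,
`1 − s`; individual fitness is the product over sites.  New mutations arrive
Poisson-distributed (genomic rates `U_del`, `U_neu` per haploid genome) on
random non-segregating sites.  Adjacent sites recombine with fraction
`c = ½(1 − e^{−2L/(n_sites−1)})`.  Parents are drawn with replacement,
fitness-weighted (MSD) or uniformly (MD); selfing occurs at random.

Key derived quantities:

* purging coefficient `d = s(½ − h)`;
* inbreeding load `B = Σ 2dq(1 − q)` over selective sites;
* neutral diversity `H = Σ 2q(1 − q)/n_n` over the neutral markers;
* neutral fitness prediction `w_t = w_0 exp(−δ f_N,t)` with
  `f_N,t = 1 − (1 − 1/2N)^t`;
* purged inbreeding coefficient
  `g_t = [(1 − 1/2N) g_{t−1} + 1/2N](1 − 2d f_{N,t−1})`, giving the IP
  prediction `w_t = w_0 exp(−δ g_t)`.

The inbreeding depression rate `δ` can be the base population's `B`, or the
empirical estimate obtained by inverting the neutral equation from the mean
fitness at `t = 3` in `N = 2` lines.

## Worked example

Purging at work: a strongly recessive load (`s = 0.5`, `h = 0`, `d = 0.25`)
under free recombination, population reduced from `N_b = 200` to `N = 10`
(`Nd = 2.5`):

```python
import numpy as np
import purgesim as pg

config = pg.SimulationConfig(
    s=0.5, h=0.0, free_recombination=True,
    N_b=200, U_del=0.1, U_neu=0.025, T_burnin=2000, seed=7,
)
base = pg.burn_in(config, np.random.default_rng(config.seed))
w0 = float(np.mean(base.fitness))
B = pg.inbreeding_load(pg.site_frequencies(base, selective=True), config.d)
print(f"base population: mean fitness {w0:.4f}, inbreeding load B {B:.3f}")

lines = pg.LineConfig(N=10, T=50, scenario="MSD", n_replicates=100, seed=1)
trajs = pg.run_replicate_lines(base, lines, config)
w50 = float(np.mean([t["w_mean"][50] for t in trajs]))

delta_lc = pg.LineConfig(N=2, T=3, scenario="MSD", n_replicates=200, seed=5)
w3 = float(np.mean([t["w_mean"][3] for t in pg.run_replicate_lines(base, delta_lc, config)]))
delta = pg.estimate_delta(w0, w3)

print(f"realized inbreeding depression rate delta {delta:.3f}")
print(f"observed MSD fitness at t=50:       {w50:.3f}")
print(f"neutral prediction (no purging):    {pg.neutral_prediction(w0, delta, 10, 50):.3f}")
print(f"inbreeding-purging (IP) prediction: {pg.ip_prediction(w0, delta, 10, config.d, 50):.3f}")
```

Output:

```
base population: mean fitness 0.8903, inbreeding load B 2.671
realized inbreeding depression rate delta 2.472
observed MSD fitness at t=50:       0.844
neutral prediction (no purging):    0.091
inbreeding-purging (IP) prediction: 0.775
```

Without purging, a depression rate of 2.47 would crash fitness to 0.09 by
generation 50; the simulated lines instead level off at 0.84 because
selection removes the recessive load as inbreeding exposes it.  The IP
prediction (0.775) captures most of that rescue and errs on the conservative
side, as IP theory is expected to.

A command-line interface mirrors the library
(`purgesim burnin | lines | stats | pedigree-f | predict | grid`), e.g.

```sh
purgesim predict --w0 0.89 --delta 2.47 --n 10 --d 0.25 --t 50
```

prints the `(t, f_N, g_t, w_neutral, w_IP)` table, and `purgesim grid` runs a
whole parameter grid from a YAML file into TSV summaries.

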