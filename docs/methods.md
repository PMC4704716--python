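# Methods

## Model and life cycle

`purgesim` simulates discrete, non-overlapping generations of a monoecious
diploid population on a single chromosome.  The site layout is fixed:
repeating batches of 20 selective sites followed by one neutral marker, for
`n_s = 20 n_n` selective sites in total (defaults `n_s = 20000`,
`n_n = 1000`).  Each generation consists of reproduction (two parents drawn
with replacement per offspring — fitness-weighted in the
mutation–selection–drift (MSD) regime, uniform in the mutation–drift (MD)
regime — so selfing occurs at rate `1/N`), recombination (the gamete's first
site copies a uniformly chosen haplotype; each later site switches haplotype
with probability `½(1 − (1 − 2c)^g)` across a gap of `g` layout intervals,
where `c = ½(1 − e^{−2L/(n_sites−1)})` is the adjacent-site fraction for map
length `L` Morgans; free recombination sets `c = 0.5`), mutation (class
totals Poisson with genomic rates `U_del`, `U_neu` per haploid genome, each
mutation placed on a uniform haploid genome at a uniform currently
non-segregating site of its class), and fitness evaluation (multiplicative
over selective sites with per-site factors `1`, `1 − hs`, `1 − s`).

Base populations are produced by running this cycle for `T_burnin`
generations from a mutation-free cohort.  Lines are founded by drawing `N`
individuals uniformly without replacement from a base population; every
generation they produce a 100-offspring cohort on which all statistics are
computed, and `N` of those offspring are drawn uniformly as the next
breeders.  Gametic contributions (`k`) are counted toward the chosen
breeding pool only (2N gametes), since that is the quantity the
contribution-based effective size is defined on.

## Storage of segregating sites

Only segregating sites are stored as haplotype-matrix columns.  A site whose
mutant allele is lost becomes eligible for new mutation again; a site whose
mutant fixes is retired permanently, and each deleterious fixation is folded
into a per-population ledger that multiplies every fitness by `1 − s`.  This
is numerically identical to carrying the fixed columns (fixed sites
contribute a constant factor to every individual and nothing to `B`, `H` or
the variances) and it is what lets MD lines express fixation load.  Retired
sites are never re-used: after a fixation has been absorbed into the fitness
ledger the column's allelic state is no longer represented, so allowing
back-mutation there would corrupt the ledger.  With the default site counts
the eligible pool is never exhausted; if it ever were, the engine raises
rather than silently skipping a mutation.

## Statistics

Per cohort: mean fitness; inbreeding load `B = Σ 2dq(1−q)` with
`d = s(½ − h)`; neutral diversity `H = Σ 2q(1−q)/n_n` (all `n_n` markers,
fixed ones contributing zero); per-individual neutral heterozygosity and its
Pearson correlation with fitness (associative overdominance; reported as
missing, never zero, when a variance vanishes); additive and dominance
fitness variance from the one-locus decomposition
`V_A = Σ 2pq[a + d(q−p)]²`, `V_D = Σ (2pq d)²` with `a = s/2`, assuming
linkage equilibrium (an empirical offspring regression at cohort size 100
would be noise-dominated).  Linkage disequilibrium is the correlation `r`
of allelic states computed from two-site gamete frequencies and averaged
over pairs of *segregating selective* sites adjacent in segregating order —
the reported mean recombination distance between such pairs is then an
output, not an input, which is the interpretation consistent with adjacent
distances far above the fixed inter-site map step.

Three inbreeding measures are tracked per line: `f_N = 1 − (1 − 1/2N)^t`;
`f_Vk`, obtained by chaining per-generation effective sizes
`Ne_t = (4N − 2)/(2 + V_k,t)` through `1 − Π(1 − 1/2Ne_τ)` (with constant
`V_k` this is exactly the closed form; chaining handles the stochastic
per-generation variance, and `V_k` uses one-generation counts only, which is
known to understate long-term contributions because their heritable
component is ignored); and pedigree `f_p` by the tabular method, maintained
incrementally as the breeder-pool coancestry matrix, with the cohort mean
taken over the 100 offspring.  `V_k` is the sample variance (ddof = 1) of
the 2N gametic contributions across the N breeders.

## Predictions

Neutral: `w_t = w_0 exp(−δ f_N,t)`, with `w_0` the base population's mean
fitness at founding.  The depression rate `δ` is either the base
population's `B`, or the empirical estimate `−ln(w_3/w_0)/f_N(2,3)` from
`N = 2` MSD lines at `t = 3` (`f_N(2,3) = 0.578125`); a fitness above `w_0`
yields a negative `δ` with a warning instead of an exception.  The
inbreeding–purging prediction substitutes the purged inbreeding coefficient
`g_t = [(1 − 1/2N)g_{t−1} + 1/2N](1 − 2d f_{N,t−1})`, implemented literally
as stated (it is an approximation with no published error bound).  Note that
`g_t` is *not* monotone in `t` for larger `d`: it peaks and then declines
toward an asymptote as `f_N → 1`, which is the recursion's representation of
fitness rebound once most of the purgeable load is gone.  The guaranteed
properties are `g_t ≤ f_N,t`, equality throughout when `d = 0`, and
`g_1 = 1/2N`.

## Scaled problem sizes and what they show

The full-scale study design (`N_b = 1000`, 10,000 burn-in generations, 50
base populations, 1000 lines per case) is supported by configuration but is
not the default.  The shipped defaults — `N_b = 200`, 2000 burn-in
generations, 20 base replicates, a few hundred lines — keep the genomic
deleterious rate at `U_del = 0.1` (so the deterministic balance fitness
`e^{−2U}` for `h > 0`, `e^{−U}` for `h = 0` is the reference) and rescale
the neutral rate to preserve `4 N_b μ = 0.02` (so the mutation–drift
diversity expectation stays `0.0196`).

Two quantitative caveats of this scaling, both measured with this package:

* **Drift load.**  At `N_b = 200` (`N_b·hs = 10` for `s = 0.1, h = 0.5`)
  the equilibrium mean fitness is ≈ 0.806 ± 0.004, about 0.012 below both
  the deterministic `0.8187` and the full-scale simulated value; at
  `N_b = 1000` we measure 0.815 ± 0.007, consistent with full scale.  The
  deterministic balance is approached only as `N_b·hs` grows, so scaled
  equilibrium fitness is expected to sit slightly low.
* **Mutational input to `H_t/H_0`.**  With the rescaled neutral rate, new
  marker mutations inflate relative diversity in small lines by ≈ 3% of
  `H_0` by `t = 20` (the effect is ≈ 1/(2N_b)-sized, hence invisible at full
  scale).  The drift-decay test therefore silences line-phase mutation,
  which makes the identity `E[H_t]/H_0 = (1 − 1/2n)/(1 − 1/2N_b)·(1 − f_N,t)`
  exact — the leading factor being the standard finite-cohort
  heterozygosity bias of the plug-in `Σ2q(1−q)` estimator.

What the generator emulates: mutation–selection–drift balance genetics,
linkage on a single uniform chromosome, purging dynamics and contribution
variance after a bottleneck.  What it does not: separate sexes, overlapping
generations, variable recombination maps, beneficial mutations, epistasis,
distributions of mutational effects (one `(s, h)` class per run), or
environmental fitness variance.  Passing tests therefore validate the
model's internal consistency and its agreement with single-locus and
pedigree theory, not the realism of any particular rate for natural
populations.

## Numerical choices

* Fitness is computed as the exponential of summed per-site log factors
  (exact for thousands of sites where a direct product would be fine too);
  `s = 1` homozygotes receive fitness exactly 0 and can never be sampled as
  parents; an all-zero-fitness breeder set under MSD raises.
* Parent draws use inverse-CDF sampling on the fitness cumulative sum.
* Mutation placement rejection-samples positions against the occupied set,
  so a site hit earlier in the same batch cannot be hit again.
* Replicate `r` of any run uses `seed + r`; every stochastic routine takes
  an explicit `numpy` generator, making all outputs bit-reproducible.
* Undefined statistics (LD with no qualifying pair, correlations with zero
  variance, `V_k` at `N = 1`) are NaN and excluded from aggregation means;
  they are never coerced to zero.
* Pedigree files use 1-based ids with 0 for a founder's parents; the
  standalone tabular calculator is O(n²) memory and intended for recorded
  pedigrees up to a few thousand individuals.

## Open design points

Where the experimental protocol is ambiguous, the package chooses once:
lines are founded from `N` base individuals (not from a 100-offspring
pre-cohort); statistics cohorts are the 100 produced offspring; mutation
continues in derived lines under both scenarios (the long-term MD fitness
decline is mutational); LD means are computed within a population and then
averaged across replicate populations.
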