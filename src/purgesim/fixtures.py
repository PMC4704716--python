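"""Deterministic fixtures and exact validation oracles.

The single-locus Wright-Fisher oracle gives the exact one-generation
allele-count distribution implied by the engine's reproduction scheme
(fitness-weighted parent draws with replacement, one random allele per
gamete), against which simulated transition frequencies can be tested.
Tiny hand-specified populations and exhaustively enumerated pedigrees back
the unit tests.
"""

from __future__ import annotations

from itertools import combinations_with_replacement

import numpy as np
from scipy import stats

from .engine import Population, compute_fitness

__all__ = [
    "genotype_counts_from_frequency",
    "wf_transition_oracle",
    "make_fixture_population",
    "enumerate_pedigrees",
]


def genotype_counts_from_frequency(N: int, q0: float) -> tuple[int, int, int]:
    """A deterministic genotype configuration (n_++, n_+m, n_mm) carrying
    ``round(2N q0)`` mutant copies, spread over as many heterozygotes as
    possible."""
    copies = int(round(2 * N * q0))
    if not 0 <= copies <= 2 * N:
        raise ValueError("q0 out of range")
    if copies <= N:
        return N - copies, copies, 0
    return 0, 2 * N - copies, copies - N


def wf_transition_oracle(
    N: int,
    s: float,
    h: float,
    q0: float | None = None,
    genotype_counts: tuple[int, int, int] | None = None,
) -> np.ndarray:
    """Exact one-generation distribution of mutant copy counts 0..2N.

    Each of the ``2N`` offspring gametes independently picks a parent with
    probability proportional to its fitness (1, 1-hs, 1-s for 0, 1, 2 mutant
    copies) and then one of the parent's two alleles uniformly, so the count
    is binomial with per-gamete mutant probability
    ``pi = sum_g n_g w_g (g/2) / sum_g n_g w_g`` over genotype classes g.

    The parental configuration is given either explicitly or derived from
    ``q0`` via :func:`genotype_counts_from_frequency`.
    """
    if N < 1 or N > 30:
        raise ValueError("oracle is intended for 1 <= N <= 30")
    if genotype_counts is None:
        if q0 is None:
            raise ValueError("provide q0 or genotype_counts")
        genotype_counts = genotype_counts_from_frequency(N, q0)
    n = np.asarray(genotype_counts, dtype=float)
    if n.sum() != N or np.any(n < 0):
        raise ValueError("genotype counts must be non-negative and sum to N")
    w = np.array([1.0, 1.0 - h * s, 1.0 - s])
    weight = n * w
    total = weight.sum()
    if total <= 0:
        raise ValueError("all parental fitness is zero")
    pi = float(np.dot(weight, [0.0, 0.5, 1.0]) / total)
    return stats.binom.pmf(np.arange(2 * N + 1), 2 * N, pi)


def make_fixture_population(
    haplotype_pairs,
    positions,
    n_s: int,
    n_n: int,
    s: float = 0.0,
    h: float = 0.5,
) -> Population:
    """Deterministic population from explicit per-individual haplotypes.

    ``haplotype_pairs`` is a sequence of ``(hap1, hap2)`` 0/1 sequences, one
    pair per individual; ``positions`` gives the layout index of each site.
    Fitness is computed by the engine; monomorphic columns are kept as given.
    """
    pairs = [np.asarray(p, dtype=np.uint8) for pair in haplotype_pairs for p in pair]
    lengths = {p.shape for p in pairs}
    if len(lengths) != 1:
        raise ValueError("all haplotypes must have the same number of sites")
    positions = np.asarray(positions, dtype=np.int64)
    if positions.size != pairs[0].size:
        raise ValueError("one position per site is required")
    pop = Population(
        haplotypes=np.vstack(pairs),
        positions=positions,
        n_s=n_s,
        n_n=n_n,
    )
    compute_fitness(pop, s, h)
    return pop


def enumerate_pedigrees(n: int):
    """Yield every pedigree of exactly ``n`` topologically ordered members.

    Each member is either a founder or the offspring of an unordered pair of
    earlier members (selfing included), encoded as an ``(n, 2)`` parent-index
    array with -1 for founders.  The count grows as
    ``prod_i (1 + i(i-1)/2 ...)``; practical up to n of about 6.
    """
    choices_per_member = []
    for i in range(n):
        opts = [(-1, -1)]
        opts.extend(combinations_with_replacement(range(i), 2))
        choices_per_member.append(opts)

    def rec(prefix: list, i: int):
        if i == n:
            yield np.array(prefix, dtype=np.int64)
            return
        for opt in choices_per_member[i]:
            prefix.append(opt)
            yield from rec(prefix, i + 1)
            prefix.pop()

    yield from rec([], 0)
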