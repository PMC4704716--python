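"""Cohort statistics: inbreeding load, linkage disequilibrium, diversity,
heterozygosity-fitness correlation and fitness variance components."""

from __future__ import annotations

import numpy as np

from .engine import Population

__all__ = [
    "site_frequencies",
    "inbreeding_load",
    "gamete_freq_table",
    "ld_r",
    "mean_adjacent_ld",
    "mean_adjacent_c",
    "neutral_diversity",
    "expected_equilibrium_fitness",
    "expected_neutral_diversity",
    "individual_heterozygosity",
    "corr_fitness_heterozygosity",
    "variance_components",
]


def site_frequencies(pop: Population, selective: bool = True) -> np.ndarray:
    """Mutant allele frequencies of the segregating sites of one class."""
    mask = pop.selective_mask if selective else pop.neutral_mask
    return pop.frequencies()[mask]


def inbreeding_load(q: np.ndarray, d: float) -> float:
    """Inbreeding load B = sum over sites of 2 d q (1 - q).

    ``d = s(1/2 - h)`` is the purging coefficient; the load is the hidden
    fitness cost expressed upon inbreeding.  Fixed sites (q of 0 or 1)
    contribute nothing.
    """
    if d < 0:
        raise ValueError(f"purging coefficient d must be >= 0, got {d}")
    q = np.asarray(q, dtype=float)
    return float(np.sum(2.0 * d * q * (1.0 - q)))


def gamete_freq_table(pop: Population, col_a: int, col_b: int) -> np.ndarray:
    """Frequencies of the four two-site gamete classes for two stored columns.

    Returns ``[g(++), g(+m), g(m+), g(mm)]`` computed over the ``2n`` haploid
    genomes of the cohort, where the first symbol refers to ``col_a``.
    """
    a = pop.haplotypes[:, col_a].astype(np.int64)
    b = pop.haplotypes[:, col_b].astype(np.int64)
    counts = np.bincount(2 * a + b, minlength=4)
    return counts / counts.sum()


def ld_r(g: np.ndarray) -> float:
    """Correlation of allelic states between two sites from gamete frequencies.

    ``g = [g(++), g(+m), g(m+), g(mm)]`` must sum to one;
    ``r = [g(++) g(mm) - g(+m) g(m+)] / sqrt(qA (1-qA) qB (1-qB))``.
    Monomorphic sites leave r undefined and raise.
    """
    g = np.asarray(g, dtype=float)
    if g.shape != (4,):
        raise ValueError("expected the four two-site gamete frequencies")
    if np.any(g < 0) or not np.isclose(g.sum(), 1.0):
        raise ValueError("gamete frequencies must be non-negative and sum to 1")
    q_a = g[2] + g[3]
    q_b = g[1] + g[3]
    denom = q_a * (1.0 - q_a) * q_b * (1.0 - q_b)
    if denom <= 0.0:
        raise ValueError("LD correlation is undefined for a monomorphic site")
    return float((g[0] * g[3] - g[1] * g[2]) / np.sqrt(denom))


def _adjacent_selective_pairs(pop: Population) -> list[tuple[int, int]]:
    cols = np.flatnonzero(pop.selective_mask)
    return [(int(cols[i]), int(cols[i + 1])) for i in range(len(cols) - 1)]


def mean_adjacent_ld(pop: Population) -> float:
    """Mean LD correlation over pairs of adjacent segregating selective sites.

    "Adjacent" refers to the ordering of the segregating selective sites
    themselves (monomorphic and neutral sites in between are skipped).
    Returns NaN when no qualifying pair exists.
    """
    values = [
        ld_r(gamete_freq_table(pop, a, b)) for a, b in _adjacent_selective_pairs(pop)
    ]
    return float(np.mean(values)) if values else float("nan")


def mean_adjacent_c(pop: Population, c_adjacent: float) -> float:
    """Mean recombination fraction between adjacent segregating selective
    sites, given the layout's adjacent-site fraction ``c_adjacent``."""
    pairs = _adjacent_selective_pairs(pop)
    if not pairs:
        return float("nan")
    gaps = np.array([pop.positions[b] - pop.positions[a] for a, b in pairs])
    return float(np.mean(0.5 * (1.0 - (1.0 - 2.0 * c_adjacent) ** gaps)))


def neutral_diversity(q: np.ndarray, n_n: int) -> float:
    """Expected heterozygosity H = sum(2 q (1-q)) / n_n over ALL neutral
    sites; ``q`` may list only the segregating ones since fixed and absent
    mutants contribute zero."""
    if n_n <= 0:
        raise ValueError("n_n must be positive")
    q = np.asarray(q, dtype=float)
    return float(np.sum(2.0 * q * (1.0 - q)) / n_n)


def individual_heterozygosity(pop: Population) -> np.ndarray:
    """Per-individual proportion of the ``n_n`` neutral sites that are
    heterozygous."""
    neu = pop.neutral_mask
    if not neu.any():
        return np.zeros(pop.size)
    het = pop.haplotypes[0::2][:, neu] != pop.haplotypes[1::2][:, neu]
    return het.sum(axis=1) / pop.n_n


def corr_fitness_heterozygosity(pop: Population) -> float:
    """Pearson correlation r(w_i, H_i) between individual fitness and
    individual neutral heterozygosity within the cohort.

    A positive value is the signature of associative overdominance.  Returns
    NaN when either variable has no variance (never coerced to zero).
    """
    if pop.size < 3:
        raise ValueError("need at least 3 individuals for a correlation")
    if pop.fitness is None:
        raise ValueError("population fitness is unset")
    w = pop.fitness
    hi = individual_heterozygosity(pop)
    if np.std(w) == 0.0 or np.std(hi) == 0.0:
        return float("nan")
    return float(np.corrcoef(w, hi)[0, 1])


def expected_equilibrium_fitness(U_del: float, h: float) -> float:
    """Deterministic mutation-selection-balance mean fitness.

    Haldane's principle: with multiplicative fitness the load per site
    depends only on the mutation rate, giving ``exp(-2 U_del)`` when the
    heterozygote is selected against (h > 0) and ``exp(-U_del)`` for fully
    recessive mutations (h = 0).  Drift and linkage are ignored.
    """
    if U_del < 0:
        raise ValueError("U_del must be >= 0")
    if h < 0:
        raise ValueError("h must be >= 0")
    return float(np.exp(-2.0 * U_del if h > 0 else -U_del))


def expected_neutral_diversity(N: int, mu: float) -> float:
    """Mutation-drift-balance heterozygosity ``4 N mu / (1 + 4 N mu)``."""
    if N < 1 or mu < 0:
        raise ValueError("need N >= 1 and mu >= 0")
    theta = 4.0 * N * mu
    return theta / (1.0 + theta)


def variance_components(q: np.ndarray, s: float, h: float) -> tuple[float, float]:
    """Additive and dominance variance of fitness across sites.

    Uses the standard one-locus decomposition for genotype values
    ``{1, 1-hs, 1-s}`` with average allelic effect ``a = s/2`` and dominance
    deviation ``d = s(1/2 - h)``:

    ``V_A = sum 2 p q [a + d (q - p)]^2`` and ``V_D = sum (2 p q d)^2``,

    summed over sites assuming linkage equilibrium.
    """
    q = np.asarray(q, dtype=float)
    p = 1.0 - q
    a = s / 2.0
    d = s * (0.5 - h)
    va = np.sum(2.0 * p * q * (a + d * (q - p)) ** 2)
    vd = np.sum((2.0 * p * q * d) ** 2)
    return float(va), float(vd)
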