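"""Forward-in-time engine: mutation, selection, recombination, reproduction.

The simulated genome is one chromosome of ``n_s`` selective and ``n_n``
neutral sites (batches of 20 selective sites followed by one neutral marker).
Only currently segregating sites are stored as columns of a haplotype matrix;
deleterious fixations are folded into a per-population fitness ledger
(``n_fixed_del`` multiplicative factors of 1-s), which is numerically
identical to carrying the fixed columns.  A fixed site is retired and never
receives a new mutation; a site whose mutant is lost becomes eligible again.

Generations are discrete and non-overlapping; individuals are monoecious and
parents are drawn with replacement, so selfing occurs at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .config import Scenario, SimulationConfig

__all__ = [
    "Population",
    "recombination_fraction",
    "individual_fitness",
    "mutate",
    "make_gamete",
    "sample_parent",
    "advance_generation",
    "burn_in",
]

_BATCH = 20  # selective sites per neutral marker


def neutral_position_mask(positions: np.ndarray) -> np.ndarray:
    """True for layout positions that are neutral markers."""
    return positions % (_BATCH + 1) == _BATCH


def recombination_fraction(
    L: float | None, n_sites: int, free_recombination: bool = False
) -> float:
    """Recombination fraction between adjacent sites of the layout.

    For a chromosome of map length ``L`` Morgans carrying ``n_sites`` evenly
    spaced sites, Haldane's mapping gives
    ``c = 0.5 * (1 - exp(-2 L / (n_sites - 1)))``.  Free recombination means
    ``c = 0.5`` exactly.
    """
    if free_recombination:
        return 0.5
    if L is None:
        raise ValueError("L is required unless free_recombination is set")
    if L < 0:
        raise ValueError(f"genome length L must be >= 0, got {L}")
    if n_sites < 2:
        raise ValueError("n_sites must be >= 2")
    return 0.5 * (1.0 - np.exp(-2.0 * L / (n_sites - 1)))


@dataclass
class Population:
    """Diploid cohort restricted to its segregating sites.

    ``haplotypes`` has shape ``(2n, S)`` with rows ``2i`` and ``2i+1`` the two
    haploid genomes of individual ``i``; entries are 0 (wild type) or 1
    (mutant).  ``positions`` are the layout indices of the ``S`` columns, kept
    sorted.  ``retired`` holds positions of past deleterious or neutral
    fixations that are excluded from future mutation; each deleterious
    fixation also adds one factor ``1 - s`` to every fitness through
    ``n_fixed_del``.
    """

    haplotypes: np.ndarray
    positions: np.ndarray
    n_s: int
    n_n: int
    n_fixed_del: int = 0
    retired: set = field(default_factory=set)
    fitness: np.ndarray | None = None
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.haplotypes.shape[0] % 2:
            raise ValueError("haplotype matrix must have an even number of rows")
        if self.haplotypes.shape[1] != self.positions.size:
            raise ValueError("one position per haplotype column is required")
        if self.ids is None:
            self.ids = np.arange(self.size)

    @property
    def size(self) -> int:
        """Number of diploid individuals."""
        return self.haplotypes.shape[0] // 2

    @property
    def n_segregating(self) -> int:
        return self.positions.size

    @property
    def neutral_mask(self) -> np.ndarray:
        return neutral_position_mask(self.positions)

    @property
    def selective_mask(self) -> np.ndarray:
        return ~self.neutral_mask

    def mutant_counts(self) -> np.ndarray:
        return self.haplotypes.sum(axis=0, dtype=np.int64)

    def frequencies(self) -> np.ndarray:
        """Mutant allele frequency per tracked column."""
        return self.mutant_counts() / self.haplotypes.shape[0]

    def subset(self, index: np.ndarray) -> "Population":
        """Cohort restricted to the given individuals (columns re-pruned)."""
        rows = np.empty(2 * len(index), dtype=np.intp)
        rows[0::2] = 2 * np.asarray(index)
        rows[1::2] = 2 * np.asarray(index) + 1
        sub = Population(
            haplotypes=self.haplotypes[rows].copy(),
            positions=self.positions.copy(),
            n_s=self.n_s,
            n_n=self.n_n,
            n_fixed_del=self.n_fixed_del,
            retired=set(self.retired),
            fitness=None if self.fitness is None else self.fitness[index].copy(),
        )
        _prune_fixed_and_lost(sub)
        return sub


def empty_population(config: SimulationConfig, n: int) -> Population:
    """All-wild-type cohort of ``n`` individuals with fitness 1."""
    return Population(
        haplotypes=np.zeros((2 * n, 0), dtype=np.uint8),
        positions=np.empty(0, dtype=np.int64),
        n_s=config.n_s,
        n_n=config.n_n,
        fitness=np.ones(n),
    )


def individual_fitness(genotype: np.ndarray, s: float, h: float,
                       selective: np.ndarray | None = None,
                       n_fixed_del: int = 0) -> float:
    """Multiplicative fitness of one individual.

    ``genotype`` is a ``(2, S)`` array of 0/1 alleles; sites flagged by
    ``selective`` (all sites by default) contribute factors 1, 1-hs or 1-s for
    0, 1 or 2 mutant copies.  Neutral sites never contribute.
    """
    genotype = np.asarray(genotype)
    if genotype.ndim != 2 or genotype.shape[0] != 2:
        raise ValueError("genotype must be a (2, n_sites) array")
    g = genotype.sum(axis=0)
    if selective is not None:
        g = g[np.asarray(selective, dtype=bool)]
    n_het = int(np.count_nonzero(g == 1))
    n_hom = int(np.count_nonzero(g == 2)) + n_fixed_del
    return float(_fitness_from_counts(np.array([n_het]), np.array([n_hom]), s, h)[0])


def _fitness_from_counts(n_het: np.ndarray, n_hom: np.ndarray,
                         s: float, h: float) -> np.ndarray:
    """exp of summed per-site log factors; robust for thousands of sites."""
    het_factor = 1.0 - h * s
    hom_factor = 1.0 - s
    if hom_factor <= 0.0:  # lethal homozygote
        w = np.where(n_hom > 0, 0.0,
                     np.exp(n_het * np.log(het_factor)) if het_factor > 0
                     else np.where(n_het > 0, 0.0, 1.0))
        return np.asarray(w, dtype=float)
    return np.exp(n_het * np.log(het_factor) + n_hom * np.log(hom_factor))


def compute_fitness(pop: Population, s: float, h: float) -> np.ndarray:
    """Recompute and store per-individual fitness of a cohort."""
    sel = pop.selective_mask
    if sel.any():
        g = pop.haplotypes[0::2][:, sel].astype(np.int16) + pop.haplotypes[1::2][:, sel]
        n_het = (g == 1).sum(axis=1)
        n_hom = (g == 2).sum(axis=1)
    else:
        n_het = np.zeros(pop.size, dtype=np.int64)
        n_hom = np.zeros(pop.size, dtype=np.int64)
    pop.fitness = _fitness_from_counts(n_het, n_hom + pop.n_fixed_del, s, h)
    return pop.fitness


def mutate(pop: Population, config: SimulationConfig, rng: np.random.Generator) -> Population:
    """Place new Poisson-distributed mutations on the cohort, in place.

    The total count per class is Poisson with mean ``U * 2n``; each mutation
    lands on a uniformly chosen haploid genome at a uniformly chosen
    currently non-segregating, non-retired site of its class.
    """
    n_genomes = pop.haplotypes.shape[0]
    new_rows: list[int] = []
    new_positions: list[int] = []
    occupied = set(int(p) for p in pop.positions) | set(pop.retired)

    for selective, U, n_class in (
        (True, config.U_del, config.n_s),
        (False, config.U_neu, config.n_n),
    ):
        if U == 0.0:
            continue
        k = int(rng.poisson(U * n_genomes))
        if k == 0:
            continue
        n_occupied_class = sum(
            1 for p in occupied if (p % (_BATCH + 1) == _BATCH) != selective
        )
        if n_class - n_occupied_class < k:
            raise RuntimeError(
                "no non-segregating site available for a new mutation; "
                "increase the number of sites of the class"
            )
        for _ in range(k):
            row = int(rng.integers(n_genomes))
            while True:
                idx = int(rng.integers(n_class))
                if selective:
                    pos = (idx // _BATCH) * (_BATCH + 1) + idx % _BATCH
                else:
                    pos = idx * (_BATCH + 1) + _BATCH
                if pos not in occupied:
                    break
            occupied.add(pos)
            new_rows.append(row)
            new_positions.append(pos)

    if new_positions:
        block = np.zeros((n_genomes, len(new_positions)), dtype=np.uint8)
        block[new_rows, np.arange(len(new_positions))] = 1
        pop.haplotypes = np.concatenate([pop.haplotypes, block], axis=1)
        pop.positions = np.concatenate([pop.positions, np.asarray(new_positions)])
        order = np.argsort(pop.positions, kind="stable")
        pop.positions = pop.positions[order]
        pop.haplotypes = pop.haplotypes[:, order]
    return pop


def _interval_switch_probabilities(positions: np.ndarray, c: float) -> np.ndarray:
    """Per-column probability that a gamete switches source haplotype.

    Column 0 starts from a uniformly chosen haplotype (probability 0.5).  For
    later columns the switch probability across a gap of ``g`` layout
    intervals with adjacent-site fraction ``c`` is ``0.5 (1 - (1-2c)^g)``
    (odd number of crossovers in the gap).
    """
    S = positions.size
    p = np.empty(S)
    if S == 0:
        return p
    p[0] = 0.5
    if S > 1:
        gaps = np.diff(positions)
        p[1:] = 0.5 * (1.0 - (1.0 - 2.0 * c) ** gaps)
    return p


def make_gamete(parent: np.ndarray, c: float, rng: np.random.Generator,
                positions: np.ndarray | None = None) -> np.ndarray:
    """One recombinant haploid genome from a ``(2, S)`` parent genotype.

    The first site's copy comes from a uniformly chosen haplotype; each
    following site switches haplotype with probability ``c`` per intervening
    layout interval (``positions`` supplies the layout indices of the stored
    columns; contiguous sites are assumed when omitted).
    """
    parent = np.asarray(parent)
    if not 0.0 <= c <= 0.5:
        raise ValueError(f"recombination fraction must lie in [0, 0.5], got {c}")
    S = parent.shape[1]
    if positions is None:
        positions = np.arange(S)
    p = _interval_switch_probabilities(np.asarray(positions), c)
    switches = rng.random(S) < p
    src = np.cumsum(switches) & 1
    return parent[src, np.arange(S)].copy()


def _gamete_block(haplotypes: np.ndarray, parent_idx: np.ndarray,
                  switch_p: np.ndarray, free: bool,
                  rng: np.random.Generator) -> np.ndarray:
    """Gametes for a batch of parent draws; one row per gamete."""
    G = parent_idx.size
    S = switch_p.size
    if S == 0:
        return np.zeros((G, 0), dtype=np.uint8)
    if free:
        src = rng.integers(0, 2, size=(G, S), dtype=np.uint8)
    else:
        switches = rng.random((G, S)) < switch_p
        src = (np.cumsum(switches, axis=1) & 1).astype(np.uint8)
    h0 = haplotypes[2 * parent_idx]
    h1 = haplotypes[2 * parent_idx + 1]
    return np.where(src == 0, h0, h1)


def sample_parent(pop: Population, scenario: Scenario | str,
                  rng: np.random.Generator) -> int:
    """Index of one parent draw (fitness-weighted under MSD, uniform under MD)."""
    return int(_sample_parents(pop, Scenario(scenario), 1, rng)[0])


def _sample_parents(pop: Population, scenario: Scenario, k: int,
                    rng: np.random.Generator) -> np.ndarray:
    if pop.size == 0:
        raise ValueError("cannot sample parents from an empty population")
    if scenario is Scenario.MD:
        return rng.integers(0, pop.size, size=k)
    if pop.fitness is None:
        raise ValueError("population fitness is unset; compute it first")
    total = float(pop.fitness.sum())
    if total <= 0.0:
        raise RuntimeError("all breeder fitness is zero under the MSD scenario")
    # inverse-CDF draw: much cheaper than rng.choice with p for repeated use
    cdf = np.cumsum(pop.fitness) / total
    return np.searchsorted(cdf, rng.random(k), side="right").clip(0, pop.size - 1)


def advance_generation(
    pop: Population,
    config: SimulationConfig,
    scenario: Scenario | str,
    n_offspring: int,
    rng: np.random.Generator,
) -> tuple[Population, np.ndarray, np.ndarray]:
    """One full life cycle: reproduction, mutation, fitness.

    Returns ``(offspring, gamete_counts, parent_pairs)`` where
    ``gamete_counts[i]`` is the number of gametes parent ``i`` contributed to
    the whole offspring cohort and ``parent_pairs`` is an ``(n_offspring, 2)``
    array of parent indices (equal entries mean selfing).
    """
    scenario = Scenario(scenario)
    c = recombination_fraction(config.L, config.n_sites, config.free_recombination)
    parents = _sample_parents(pop, scenario, 2 * n_offspring, rng)
    parent_pairs = parents.reshape(n_offspring, 2)

    switch_p = _interval_switch_probabilities(pop.positions, c)
    gametes = _gamete_block(pop.haplotypes, parents, switch_p, c == 0.5, rng)
    haplotypes = np.empty((2 * n_offspring, pop.n_segregating), dtype=np.uint8)
    haplotypes[0::2] = gametes[0::2]
    haplotypes[1::2] = gametes[1::2]

    offspring = Population(
        haplotypes=haplotypes,
        positions=pop.positions.copy(),
        n_s=pop.n_s,
        n_n=pop.n_n,
        n_fixed_del=pop.n_fixed_del,
        retired=set(pop.retired),
    )
    mutate(offspring, config, rng)
    _prune_fixed_and_lost(offspring)
    compute_fitness(offspring, config.s, config.h)

    gamete_counts = np.bincount(parents, minlength=pop.size)
    return offspring, gamete_counts, parent_pairs


def _prune_fixed_and_lost(pop: Population) -> None:
    """Drop monomorphic columns; fold deleterious fixations into the ledger."""
    if pop.n_segregating == 0:
        return
    counts = pop.mutant_counts()
    n_genomes = pop.haplotypes.shape[0]
    fixed = counts == n_genomes
    if fixed.any():
        fixed_positions = pop.positions[fixed]
        neutral = neutral_position_mask(fixed_positions)
        pop.n_fixed_del += int(np.count_nonzero(~neutral))
        pop.retired.update(int(p) for p in fixed_positions)
    keep = (counts > 0) & ~fixed
    if not keep.all():
        pop.haplotypes = pop.haplotypes[:, keep]
        pop.positions = pop.positions[keep]


def burn_in(config: SimulationConfig, rng: np.random.Generator) -> Population:
    """Run the life cycle for ``T_burnin`` generations from a mutation-free
    cohort of ``N_b`` individuals under the MSD scenario and return the final
    cohort as a base population."""
    pop = empty_population(config, config.N_b)
    for _ in range(config.T_burnin):
        pop, _, _ = advance_generation(pop, config, Scenario.MSD, config.N_b, rng)
    return pop
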