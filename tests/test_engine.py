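"""Unit and property tests of the forward engine's life-cycle operations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from purgesim import (
    Population,
    SimulationConfig,
    advance_generation,
    burn_in,
    individual_fitness,
    make_gamete,
    mutate,
    recombination_fraction,
    sample_parent,
)
from purgesim.engine import compute_fitness, empty_population


class TestRecombinationFraction:
    def test_free_recombination_is_half(self):
        assert recombination_fraction(None, 21000, free_recombination=True) == 0.5

    def test_zero_map_length(self):
        assert recombination_fraction(0.0, 21000) == 0.0

    def test_one_morgan_default_layout(self):
        # closed form 0.5 (1 - exp(-2 L / (n_sites - 1)))
        expected = 0.5 * (1.0 - np.exp(-2.0 / 20999))
        assert recombination_fraction(1.0, 21000) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(4.7617e-5, rel=1e-4)

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            recombination_fraction(-1.0, 21000)


class TestIndividualFitness:
    def test_all_wild_type(self):
        geno = np.zeros((2, 5), dtype=np.uint8)
        assert individual_fitness(geno, s=0.3, h=0.1) == 1.0

    def test_single_heterozygote(self):
        geno = np.array([[1, 0], [0, 0]], dtype=np.uint8)
        assert individual_fitness(geno, s=0.1, h=0.2) == pytest.approx(0.98)

    def test_product_over_sites(self):
        # one heterozygous (factor 1 at h=0) and one homozygous (factor 0.5)
        geno = np.array([[1, 1], [0, 1]], dtype=np.uint8)
        assert individual_fitness(geno, s=0.5, h=0.0) == pytest.approx(0.5)

    def test_lethal_homozygote_is_zero_and_never_a_parent(self, tiny_config):
        pop = Population(
            haplotypes=np.array([[1], [1], [0], [0]], dtype=np.uint8),
            positions=np.array([0]),
            n_s=20, n_n=1,
        )
        compute_fitness(pop, s=1.0, h=0.5)
        assert pop.fitness[0] == 0.0 and pop.fitness[1] == 1.0
        rng = np.random.default_rng(0)
        draws = [sample_parent(pop, "MSD", rng) for _ in range(200)]
        assert set(draws) == {1}


class TestMutate:
    def test_zero_rates_leave_population_unchanged(self, tiny_config):
        config = tiny_config.replace(U_del=0.0, U_neu=0.0)
        pop = empty_population(config, 10)
        before = pop.haplotypes.copy()
        mutate(pop, config, np.random.default_rng(0))
        assert pop.n_segregating == 0
        np.testing.assert_array_equal(pop.haplotypes, before)

    def test_poisson_mean_matches_rate(self, tiny_config):
        config = tiny_config.replace(U_del=0.3, U_neu=0.0)
        rng = np.random.default_rng(1)
        counts = []
        for _ in range(2000):
            pop = empty_population(config, 20)
            mutate(pop, config, rng)
            counts.append(pop.n_segregating)
        mean = np.mean(counts)
        expected = config.U_del * 40  # U_del per haploid genome, 2N genomes
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(mean - expected) < 4 * se

    def test_new_mutation_lands_on_empty_site(self, tiny_config):
        config = tiny_config.replace(U_del=1.0, U_neu=0.1)
        pop = empty_population(config, 20)
        rng = np.random.default_rng(2)
        for _ in range(20):
            before = set(int(p) for p in pop.positions) | pop.retired
            n_before = pop.n_segregating
            mutate(pop, config, rng)
            new = pop.mutant_counts() == 1
            fresh = [int(p) for p in pop.positions[new]]
            assert pop.n_segregating >= n_before
            for p in set(fresh) - before:
                assert p not in before

    def test_exhausted_sites_raise(self):
        config = SimulationConfig(
            s=0.1, h=0.5, free_recombination=True,
            n_s=20, n_n=1, N_b=5, U_del=50.0, U_neu=0.0, T_burnin=0, seed=0,
        )
        pop = empty_population(config, 5)
        with pytest.raises(RuntimeError, match="non-segregating"):
            mutate(pop, config, np.random.default_rng(3))


class TestMakeGamete:
    def test_no_recombination_returns_intact_haplotype(self):
        rng = np.random.default_rng(4)
        parent = np.array([[0, 0, 0, 0], [1, 1, 1, 1]], dtype=np.uint8)
        hits = 0
        for _ in range(400):
            g = make_gamete(parent, 0.0, rng)
            assert g.sum() in (0, 4)  # one haplotype, never a mosaic
            hits += g.sum() == 4
        assert 150 < hits < 250  # each haplotype roughly half the time

    @pytest.mark.parametrize("c", [0.1, 0.37, 0.5])
    def test_recombinant_fraction_matches_c(self, c):
        # doubly heterozygous parent in coupling: recombinants are 01 / 10
        rng = np.random.default_rng(5)
        parent = np.array([[1, 1], [0, 0]], dtype=np.uint8)
        draws = np.array([make_gamete(parent, c, rng) for _ in range(20000)])
        recombinant = draws[:, 0] != draws[:, 1]
        se = np.sqrt(c * (1 - c) / len(draws))
        assert abs(recombinant.mean() - c) < 4 * se


class TestSampleParent:
    def test_fitness_weighted_sampling(self):
        pop = Population(
            haplotypes=np.zeros((4, 0), dtype=np.uint8),
            positions=np.empty(0, dtype=np.int64),
            n_s=20, n_n=1, fitness=np.array([0.8, 0.2]),
        )
        rng = np.random.default_rng(6)
        draws = np.array([sample_parent(pop, "MSD", rng) for _ in range(20000)])
        assert abs((draws == 0).mean() - 0.8) < 4 * np.sqrt(0.8 * 0.2 / 20000)

    def test_md_ignores_fitness(self):
        pop = Population(
            haplotypes=np.zeros((4, 0), dtype=np.uint8),
            positions=np.empty(0, dtype=np.int64),
            n_s=20, n_n=1, fitness=np.array([0.8, 0.2]),
        )
        rng = np.random.default_rng(7)
        draws = np.array([sample_parent(pop, "MD", rng) for _ in range(20000)])
        assert abs((draws == 0).mean() - 0.5) < 4 * np.sqrt(0.25 / 20000)

    def test_all_zero_fitness_fails_under_msd(self):
        pop = Population(
            haplotypes=np.zeros((4, 0), dtype=np.uint8),
            positions=np.empty(0, dtype=np.int64),
            n_s=20, n_n=1, fitness=np.zeros(2),
        )
        with pytest.raises(RuntimeError):
            sample_parent(pop, "MSD", np.random.default_rng(8))


class TestAdvanceGeneration:
    def test_gamete_counts_conservation(self, tiny_config, small_base):
        pop, config = small_base
        _, counts, pairs = advance_generation(
            pop, config, "MSD", 77, np.random.default_rng(9)
        )
        assert counts.sum() == 2 * 77
        assert pairs.shape == (77, 2)
        np.testing.assert_array_equal(
            np.bincount(pairs.ravel(), minlength=pop.size), counts
        )

    def test_neutral_martingale_under_md(self, tiny_config):
        """With selection off and no mutation the mean allele frequency is
        conserved across one generation."""
        config = tiny_config.replace(U_del=0.0, U_neu=0.0)
        rng = np.random.default_rng(10)
        n, q0 = 20, 0.3
        freqs = []
        for _ in range(3000):
            hap = (rng.random((2 * n, 1)) < q0).astype(np.uint8)
            pop = Population(haplotypes=hap, positions=np.array([20]),
                             n_s=config.n_s, n_n=config.n_n)
            compute_fitness(pop, config.s, config.h)
            q_parent = pop.frequencies()[0]
            off, _, _ = advance_generation(pop, config, "MD", n, rng)
            q_child = off.frequencies()[0] if off.n_segregating else (
                1.0 if off.n_fixed_del > pop.n_fixed_del or off.retired - pop.retired
                else 0.0
            )
            freqs.append(q_child - q_parent)
        drift = np.mean(freqs)
        se = np.std(freqs, ddof=1) / np.sqrt(len(freqs))
        assert abs(drift) < 4 * se


class TestBurnIn:
    def test_zero_generations_returns_pristine_cohort(self, tiny_config):
        config = tiny_config.replace(T_burnin=0)
        pop = burn_in(config, np.random.default_rng(11))
        assert pop.size == config.N_b
        assert pop.n_segregating == 0
        np.testing.assert_allclose(pop.fitness, 1.0)

    def test_mean_fitness_near_deterministic_balance(self, small_base):
        # N_b*h*s = 2.5 at the fixture's scale: expect the vicinity of
        # exp(-2 U_del), not exact agreement.
        pop, config = small_base
        assert 0.72 < float(np.mean(pop.fitness)) < 0.88


class TestEngineProperties:
    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_positions_sorted_unique_and_fitness_valid(self, seed):
        config = SimulationConfig(
            s=0.2, h=0.3, L=2.0, n_s=1000, n_n=50, N_b=15,
            U_del=0.2, U_neu=0.02, T_burnin=0, seed=seed,
        )
        rng = np.random.default_rng(seed)
        pop = empty_population(config, config.N_b)
        for _ in range(5):
            pop, counts, _ = advance_generation(pop, config, "MSD", config.N_b, rng)
            assert counts.sum() == 2 * config.N_b
            positions = pop.positions
            assert np.all(np.diff(positions) > 0)
            assert np.all((pop.fitness > 0) & (pop.fitness <= 1.0))
            counts_per_site = pop.mutant_counts()
            assert np.all((counts_per_site > 0) & (counts_per_site < 2 * pop.size))
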