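"""Forward simulator: genome map, meiosis, viability, one-generation
dynamics and their agreement with the deterministic single-locus model."""

import numpy as np
import pytest

from altload.params import ExtinctionError, GenomeMap, ModelParams, SimParams
from altload.recursion import LocusState, step_backup
from altload.simulate import (
    Population,
    build_genome_map,
    draw_gamete,
    embryo_viability,
    generation_step,
    run_to_balance,
    seed_single_variant,
)


class TestGenomeMap:
    def test_default_blocks(self):
        gmap = GenomeMap()
        assert gmap.block_bounds()[0] == (0, 10000)
        assert gmap.block_bounds()[-1] == (90000, 100000)
        assert len(gmap.block_bounds()) == 10

    def test_single_block(self):
        gmap = GenomeMap(n_sites=10, n_chromosomes=1)
        assert gmap.block_bounds() == [(0, 10)]

    def test_divisibility_error(self):
        with pytest.raises(ValueError):
            GenomeMap(n_sites=10, n_chromosomes=3)

    def test_build_from_params(self):
        gmap = build_genome_map(SimParams(N=10, n_sites=200, n_chromosomes=4))
        assert gmap.sites_per_chromosome == 50

    def test_chromosome_assignment(self):
        gmap = GenomeMap(n_sites=100, n_chromosomes=10)
        assert list(gmap.chromosome_of([0, 9, 10, 99])) == [0, 0, 1, 9]


class TestEmbryoViability:
    def test_no_mutations_is_viable(self):
        v = embryo_viability(np.zeros((3, 0), np.uint8), np.zeros((3, 0), np.uint8),
                             np.empty(0), np.empty(0))
        assert (v == 1.0).all()

    def test_heterozygous_recessive_lethal_is_viable(self):
        a = np.array([[1]], np.uint8)
        b = np.array([[0]], np.uint8)
        v = embryo_viability(a, b, np.array([1.0]), np.array([0.0]))
        assert v[0] == 1.0

    def test_multiplicative_across_homozygous_loci(self):
        a = np.array([[1, 1]], np.uint8)
        b = np.array([[1, 1]], np.uint8)
        v = embryo_viability(a, b, np.array([0.2, 0.2]), np.zeros(2))
        assert v[0] == pytest.approx(0.64)

    def test_mixed_coefficients_match_log_path(self):
        # heterogeneous (s, h) columns exercise the general matmul branch
        a = np.array([[1, 0, 1]], np.uint8)
        b = np.array([[1, 1, 0]], np.uint8)
        s = np.array([0.5, 0.8, 1.0])
        h = np.array([0.0, 0.25, 0.1])
        v = embryo_viability(a, b, s, h)
        assert v[0] == pytest.approx(0.5 * (1 - 0.2) * (1 - 0.1))


@pytest.fixture
def small_params():
    return SimParams(N=400, mu=0.0, sigma=0.3, s=1.0, h=0.0, w_inbred=0.0,
                     n_sites=10000, n_chromosomes=10, seed=0)


class TestMeiosis:
    def test_homozygous_parent_transmits_everything(self, small_params):
        rng = np.random.default_rng(1)
        pop = Population.founding(small_params)
        pop = seed_single_variant(pop, 123, 0.4, rng, s=1.0, h=0.0)
        pop.haps[0, :, 0] = 1  # make parent 0 homozygous
        ids, new = draw_gamete(pop, 0, mu=0.0, rng=rng)
        assert ids == frozenset(pop.registry.mid.tolist())
        assert new == []

    def test_mendelian_transmission_of_heterozygote(self, small_params):
        rng = np.random.default_rng(2)
        pop = Population.founding(small_params)
        pop = seed_single_variant(pop, 5000, 0.5, rng, s=1.0, h=0.0)
        pop.haps[0, 0, 0] = 1
        pop.haps[0, 1, 0] = 0
        n, hits = 4000, 0
        for _ in range(n):
            ids, _ = draw_gamete(pop, 0, mu=0.0, rng=rng)
            hits += len(ids)
        se = 0.5 / np.sqrt(n)
        assert abs(hits / n - 0.5) < 4 * se

    def test_de_novo_mutation_count_is_poisson(self, small_params):
        # mu * n_sites = 0.05 expected new mutations per gamete
        mu = 0.5e-6 * 10  # scaled to the 10^4-site fixture genome
        rng = np.random.default_rng(3)
        pop = Population.founding(small_params)
        n, total = 20000, 0
        from altload.simulate import _draw_gamete_matrix

        _, new_sites, _ = _draw_gamete_matrix(
            pop, np.zeros(n, dtype=np.int64), mu, rng
        )
        total = new_sites.size
        mean = mu * small_params.n_sites * n
        assert abs(total - mean) < 4 * np.sqrt(mean)

    def test_linked_sites_cotransmit_more_than_unlinked(self, small_params):
        # two mutations 0.01 Morgans apart on one chromosome stay together;
        # mutations on different chromosomes assort independently
        rng = np.random.default_rng(4)
        pop = Population.founding(small_params)
        pop = seed_single_variant(pop, 100, 0.5, rng, s=1.0, h=0.0)
        pop = seed_single_variant(pop, 110, 0.5, rng, s=1.0, h=0.0)
        pop = seed_single_variant(pop, 5100, 0.5, rng, s=1.0, h=0.0)
        # parent 0: sites 100 and 110 in cis on strand 0; 5100 on strand 1
        pop.haps[0] = 0
        pop.haps[0, 0, [0, 1]] = 1
        pop.haps[0, 1, 2] = 1
        id_a, id_b, id_c = pop.registry.mid
        n = 3000
        together = across = 0
        for _ in range(n):
            ids, _ = draw_gamete(pop, 0, mu=0.0, rng=rng)
            together += (id_a in ids) == (id_b in ids)
            across += (id_a in ids) == (id_c not in ids)
        # tight linkage: expected co-transmission ~ 1 - 0.01; independence: 0.5
        assert together / n > 0.95
        assert abs(across / n - 0.5) < 4 * 0.5 / np.sqrt(n)


class TestSeedSingleVariant:
    def test_zero_frequency_is_identity(self, small_params):
        rng = np.random.default_rng(5)
        pop = Population.founding(small_params)
        assert seed_single_variant(pop, 1, 0.0, rng) is pop

    def test_realized_count_is_binomial(self, small_params):
        rng = np.random.default_rng(6)
        pop = Population.founding(small_params)
        pop = seed_single_variant(pop, 1, 0.05, rng, s=1.0, h=0.0)
        count = int(pop.allele_counts()[0])
        n2 = 2 * pop.size
        se = np.sqrt(n2 * 0.05 * 0.95)
        assert abs(count - n2 * 0.05) < 4 * se

    def test_fixed_frequency_rejected(self, small_params):
        rng = np.random.default_rng(7)
        pop = Population.founding(small_params)
        with pytest.raises(ValueError):
            seed_single_variant(pop, 1, 1.0, rng, s=1.0, h=0.0)


class TestGenerationStep:
    def test_mutation_free_population_stays_clean(self, small_params):
        rng = np.random.default_rng(8)
        pop = Population.founding(small_params)
        pop, stats = generation_step(pop, small_params, rng)
        assert pop.registry.n_live == 0
        # only inbreeding-status selection operates: E[size] = N(1 - sigma)
        expect = small_params.N * (1 - small_params.sigma)
        se = np.sqrt(small_params.N * 0.3 * 0.7)
        assert abs(pop.size - expect) < 5 * se

    def test_seeded_determinism(self, small_params):
        params = small_params.with_(mu=2e-5, generations=40,
                                    min_generations=10**9, seed=77)
        a = run_to_balance(params)
        b = run_to_balance(params)
        assert np.array_equal(a.population.haps, b.population.haps)
        assert a.trajectory.equals(b.trajectory)
        assert np.array_equal(a.population.registry.mid,
                              b.population.registry.mid)

    def test_extinction_reported(self):
        params = SimParams(N=50, mu=0.0, sigma=1.0, s=1.0, h=0.0,
                           w_inbred=0.0, n_sites=100, n_chromosomes=1,
                           generations=5, min_generations=0, seed=9)
        res = run_to_balance(params)
        assert res.status == "extinct"
        assert res.population is None

    def test_neutral_mutations_drift_as_martingale(self):
        # with s = 0 the mean frequency change over replicates is ~0
        params = SimParams(N=500, mu=0.0, sigma=0.2, s=0.0, h=0.0,
                           w_inbred=1.0, n_sites=10000, seed=0)
        rng = np.random.default_rng(10)
        deltas = []
        for rep in range(60):
            pop = Population.founding(params)
            pop = seed_single_variant(pop, 4321, 0.2, rng, s=0.0, h=0.0)
            p0 = pop.allele_frequencies()[0]
            pop, _ = generation_step(pop, params, rng)
            p1 = pop.allele_frequencies()[0] if pop.registry.n_live else (
                1.0 if len(pop.registry.fixed) else 0.0
            )
            deltas.append(p1 - p0)
        se = np.std(deltas, ddof=1) / np.sqrt(len(deltas))
        assert abs(np.mean(deltas)) < 4 * se

    def test_single_locus_change_matches_recursion(self):
        # one-generation mean allele-frequency change at a recessive lethal
        # matches the deterministic backup-embryo step started from the
        # realized genotype state (the simulator's only extra behaviour is
        # drift)
        params = SimParams(N=2000, mu=0.0, sigma=0.3, s=1.0, h=0.0,
                           w_inbred=0.0, n_sites=10000, seed=0)
        mp = ModelParams(s=1.0, h=0.0, sigma=0.3, w_inbred=0.0)
        rng = np.random.default_rng(123)
        deltas = []
        det_deltas = []
        for rep in range(300):
            pop = Population.founding(params)
            pop = seed_single_variant(pop, 5000, 0.05, rng, s=1.0, h=0.0)
            hap = pop.haps[:, :, 0]
            geno = hap.sum(axis=1)
            g_freq = np.bincount(geno, minlength=3) / pop.size
            state = LocusState(np.column_stack([g_freq, np.zeros(3)]))
            det_deltas.append(step_backup(state, mp).p_A - state.p_A)
            p0 = pop.allele_frequencies()[0]
            pop, _ = generation_step(pop, params, rng)
            p1 = pop.allele_frequencies()[0] if pop.registry.n_live else 0.0
            deltas.append(p1 - p0)
        se = np.std(deltas, ddof=1) / np.sqrt(len(deltas))
        assert abs(np.mean(deltas) - np.mean(det_deltas)) < 4 * se

    def test_fixation_logged_and_removed(self):
        params = SimParams(N=60, mu=0.0, sigma=0.0, s=0.0, h=0.0,
                           w_inbred=1.0, n_sites=100, n_chromosomes=1,
                           seed=0)
        rng = np.random.default_rng(11)
        pop = Population.founding(params)
        pop = seed_single_variant(pop, 50, 0.5, rng, s=0.0, h=0.0)
        for _ in range(2000):
            pop, _ = generation_step(pop, params, rng)
            if pop.registry.n_live == 0:
                break
        assert pop.registry.n_live == 0
        # the neutral variant either fixed (and was logged) or was lost
        assert len(pop.registry.fixed) in (0, 1)


class TestRunToBalance:
    def test_mutation_free_run_is_immediately_stationary(self):
        params = SimParams(N=100, mu=0.0, sigma=0.2, s=1.0, h=0.0,
                           w_inbred=0.0, n_sites=1000, generations=200,
                           min_generations=0, balance_window=20, seed=1)
        res = run_to_balance(params)
        assert res.status == "stationary"
        assert res.trajectory["mean_mutations_per_individual"].abs().max() == 0
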