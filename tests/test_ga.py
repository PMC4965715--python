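import numpy as np
import networkx as nx
import pytest

from gacomplex import (
    Clustering,
    GAConfig,
    GeneticComplexDetector,
    PlantedSpec,
    density_fitness,
    evolve,
    generate,
    postprocess,
)
from gacomplex.ga import (
    _evaluate,
    init_population_random,
    init_population_spectral,
    mutate,
    select_parents,
)

from .conftest import gnp_net, net_from


def jaccard(a, b):
    return len(a & b) / len(a | b) if a | b else 1.0


class TestRandomInit:
    def test_seeded_runs_identical(self, planted_fixture):
        net, _ = planted_fixture
        cfg = GAConfig(population_size=10, n_clusters=6, seed=42)
        p1 = init_population_random(net, cfg)
        p2 = init_population_random(net, cfg)
        assert [ind.clusters for ind in p1.individuals] == [
            ind.clusters for ind in p2.individuals
        ]

    def test_k1_assigns_everything_to_one_cluster(self, planted_fixture):
        net, _ = planted_fixture
        cfg = GAConfig(population_size=4, n_clusters=1, seed=0)
        pop = init_population_random(net, cfg)
        for ind in pop.individuals:
            assert ind.k == 1
            assert ind.clusters[0] == set(net.proteins)

    def test_every_individual_covers_the_network(self, planted_fixture):
        net, _ = planted_fixture
        cfg = GAConfig(population_size=20, n_clusters=10, seed=1)
        pop = init_population_random(net, cfg)
        for ind in pop.individuals:
            assert ind.covered_nodes() == set(net.proteins)

    def test_population_diversity_positive(self, planted_fixture):
        net, _ = planted_fixture
        cfg = GAConfig(population_size=50, n_clusters=10, seed=2)
        pop = init_population_random(net, cfg)
        dists = []
        for i in range(0, 40, 2):
            a = pop.individuals[i].as_frozensets()
            b = pop.individuals[i + 1].as_frozensets()
            dists.append(1 - np.mean([max(jaccard(x, y) for y in b) for x in a]))
        assert np.mean(dists) > 0

    def test_k_larger_than_network_rejected(self, path4):
        with pytest.raises(ValueError, match="exceeds network size"):
            init_population_random(path4, GAConfig(n_clusters=99, seed=0))


class TestSpectralInit:
    def test_first_individual_is_exact_spectral_solution(self, clique_fixture):
        net, _ = clique_fixture
        cfg = GAConfig(population_size=5, seed=0)
        pop = init_population_spectral(net, cfg)
        assert _evaluate(net, pop.individuals[0], "density") == pytest.approx(6.0)

    def test_perturbed_individuals_still_valid(self, planted_fixture):
        net, _ = planted_fixture
        cfg = GAConfig(population_size=8, seed=3)
        pop = init_population_spectral(net, cfg)
        assert len(pop) == 8
        for ind in pop.individuals:
            for c in ind.clusters:
                assert c <= set(net.proteins)

    def test_spectral_beats_random_initial_fitness(self):
        wins = 0
        for seed in range(20):
            net, _ = generate(PlantedSpec(seed=seed))
            cfg = GAConfig(population_size=20, n_clusters=6, seed=seed)
            ps = init_population_spectral(net, cfg, rng=np.random.default_rng(seed))
            pr = init_population_random(net, cfg, rng=np.random.default_rng(seed))
            fs = max(_evaluate(net, i, "density") for i in ps.individuals)
            fr = max(_evaluate(net, i, "density") for i in pr.individuals)
            wins += fs >= fr
        assert wins >= 18


class TestSelection:
    def _population(self, net, fitnesses):
        inds = []
        for f in fitnesses:
            ind = Clustering([set(net.proteins[:3])])
            ind.fitness = f
            inds.append(ind)
        from gacomplex.ga import Population

        return Population(inds)

    def test_dominant_individual_nearly_always_selected(self, path4):
        pop = self._population(path4, [10.0, 0.0, 0.0, 0.0])
        cfg = GAConfig(population_size=4, elitism_count=1, seed=0)
        rng = np.random.default_rng(0)
        picks = [select_parents(pop, rng, cfg)[0] for _ in range(1000)]
        frac = np.mean([p.fitness == 10.0 for p in picks])
        assert frac >= 0.9

    def test_equal_fitness_selected_uniformly(self, path4):
        pop = self._population(path4, [1.0, 1.0])
        cfg = GAConfig(population_size=2, elitism_count=1, seed=0)
        rng = np.random.default_rng(1)
        picks = [select_parents(pop, rng, cfg)[0] for _ in range(10_000)]
        frac = np.mean([p is pop.individuals[0] for p in picks])
        assert abs(frac - 0.5) <= 0.05

    def test_unevaluated_population_rejected(self, path4):
        pop = self._population(path4, [1.0, None])
        with pytest.raises(ValueError, match="fitness"):
            select_parents(pop, np.random.default_rng(0), GAConfig(seed=0))


class TestMutation:
    def test_expand_is_idempotent_when_neighbors_present(self, path4):
        ind = Clustering([set(path4.proteins)])
        cfg = GAConfig(move_vs_expand_prob=0.0, seed=0)  # always expand
        out = mutate(ind, path4, np.random.default_rng(0), cfg)
        assert out.clusters == ind.clusters
        assert out.fitness is None

    def test_move_with_single_cluster_is_noop(self, path4):
        ind = Clustering([{"a", "b"}])
        cfg = GAConfig(move_vs_expand_prob=1.0, seed=0)  # always move
        out = mutate(ind, path4, np.random.default_rng(0), cfg)
        assert out.clusters == ind.clusters

    def test_expand_adds_exactly_the_outside_neighbors(self):
        # star: center in the cluster, its three neighbors outside
        net = net_from(nx.star_graph(["hub", "s1", "s2", "s3"]))
        ind = Clustering([{"hub"}, {"s1", "s2", "s3"}])
        cfg = GAConfig(move_vs_expand_prob=0.0, seed=0)
        rng = np.random.default_rng(5)  # first occurrence = ('hub' in cluster 0)
        out = mutate(ind, net, rng, cfg)
        grown = [c for c in out.clusters if "hub" in c]
        assert {"hub", "s1", "s2", "s3"} in grown

    def test_mutation_never_leaves_the_node_universe(self, planted_fixture):
        net, _ = planted_fixture
        rng = np.random.default_rng(7)
        cfg = GAConfig(seed=7)
        ind = init_population_random(net, cfg, rng).individuals[0]
        universe = set(net.proteins)
        for _ in range(200):
            ind = mutate(ind, net, rng, cfg)
            for c in ind.clusters:
                assert c <= universe

    def test_all_empty_individual_returned_unchanged(self, path4):
        ind = Clustering([set(), set()])
        out = mutate(ind, path4, np.random.default_rng(0), GAConfig(seed=0))
        assert out.clusters == [set(), set()]


class TestEvolve:
    def test_single_generation_never_loses_the_initial_best(self, planted_fixture):
        net, _ = planted_fixture
        cfg = GAConfig(population_size=10, generations=1, seed=0)
        best, history = evolve(net, cfg)
        assert best.fitness >= history[0]

    def test_history_is_monotone_nondecreasing(self):
        net, _ = generate(PlantedSpec(n_complexes=3, size_range=(8, 8), seed=5))
        cfg = GAConfig(
            population_size=20, generations=40, init="random", n_clusters=3, seed=5
        )
        _, history = evolve(net, cfg)
        assert all(b >= a for a, b in zip(history, history[1:]))

    def test_same_seed_identical_history(self):
        net, _ = generate(PlantedSpec(n_complexes=3, size_range=(8, 8), seed=6))
        cfg = GAConfig(population_size=15, generations=25, seed=9)
        _, h1 = evolve(net, cfg)
        _, h2 = evolve(net, cfg)
        assert h1 == h2

    def test_attains_exhaustive_optimum_on_small_graphs(self):
        # overlap is allowed, so the best partition is a lower bound the
        # GA must reach (and may legitimately exceed)
        from .test_acceptance import all_partitions

        wins = 0
        for seed in range(10):
            net = gnp_net(7, 0.5, seed=seed)
            opt = max(
                density_fitness(net, part) for part in all_partitions(list(net.proteins))
            )
            est = GeneticComplexDetector(
                init="random", n_clusters=3, population_size=30,
                generations=200, random_state=seed,
            ).fit(net)
            wins += est.best_fitness_ >= opt - 1e-9
        assert wins >= 9

    def test_overlap_capability_on_shared_complex_fixture(self):
        found = 0
        for seed in range(3):
            spec = PlantedSpec(
                n_complexes=2, size_range=(10, 10), p_in=0.9, p_out=0.02,
                overlap_pairs=1, shared_count=2, seed=seed,
            )
            net, _ = generate(spec)
            est = GeneticComplexDetector(
                random_state=seed, population_size=60, generations=150
            ).fit(net)
            found += any(
                c1 & c2
                for i, c1 in enumerate(est.clusters_)
                for c2 in est.clusters_[i + 1:]
            )
        assert found >= 1


class TestPostprocess:
    def test_duplicates_merge_and_small_clusters_drop(self):
        cfg = GAConfig(min_complex_size=3, seed=0)
        raw = Clustering([{"a", "b", "c"}, {"a", "b", "c"}, {"d"}])
        out = postprocess(raw, cfg)
        assert out.clusters == [{"a", "b", "c"}]

    def test_identity_when_all_clusters_large_and_distinct(self):
        cfg = GAConfig(min_complex_size=3, seed=0)
        raw = Clustering([{"a", "b", "c"}, {"d", "e", "f", "g"}])
        out = postprocess(raw, cfg)
        assert set(map(frozenset, out.clusters)) == set(map(frozenset, raw.clusters))

    def test_predicted_count_near_planted_count(self):
        close = 0
        for seed in range(10):
            net, truth = generate(PlantedSpec(seed=seed))
            est = GeneticComplexDetector(random_state=seed).fit(net)
            close += abs(est.n_clusters_ - len(truth)) <= 2
        assert close >= 7


class TestEstimatorInterface:
    def test_fit_predict_membership_matrix(self, clique_fixture):
        net, _ = clique_fixture
        est = GeneticComplexDetector(random_state=0, generations=5, population_size=10)
        member = est.fit_predict(net)
        assert member.shape == (net.n_proteins, est.n_clusters_)
        assert member.any(axis=0).all()  # no empty predicted complex

    def test_get_set_params_round_trip(self):
        est = GeneticComplexDetector(population_size=33)
        params = est.get_params()
        assert params["population_size"] == 33
        est.set_params(objective="ratio", generations=7)
        assert est.objective == "ratio" and est.generations == 7
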