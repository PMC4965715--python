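"""Genetic algorithm for overlapping protein-complex detection.

An individual is an ordered list of k node-sets (clusters) over the
network; the same protein may sit in several clusters, which is how
overlapping complexes are represented.  The population evolves by
fitness-proportionate selection with elitism and a two-branch mutation
(move a node between clusters / add a node's network neighbours to its
cluster); crossover is deliberately absent — it disrupts good partial
clusterings more than it helps.

The search maximizes one of four fitness functions (see
:mod:`gacomplex.objectives`): the density fitness JD, or the negated
multiway min-max / ratio / normalized cut.  Because the elite always
survives, the best-fitness trace is monotone non-decreasing, and every
run is a pure function of (inputs, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from . import objectives
from .network_io import PPINetwork, as_network
from .spectral import SpectralConfig, recursive_spectral_clustering

logger = logging.getLogger(__name__)

__all__ = [
    "Clustering",
    "GAConfig",
    "Population",
    "init_population_random",
    "init_population_spectral",
    "select_parents",
    "mutate",
    "evolve",
    "postprocess",
    "GeneticComplexDetector",
]


@dataclass
class Clustering:
    """A candidate solution: k clusters (sets of node IDs), overlap allowed."""

    clusters: list
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.clusters = [set(c) for c in self.clusters]

    def copy(self) -> "Clustering":
        return Clustering([set(c) for c in self.clusters], self.fitness)

    @property
    def k(self) -> int:
        return len(self.clusters)

    def covered_nodes(self) -> set:
        out: set = set()
        for c in self.clusters:
            out |= c
        return out

    def as_frozensets(self) -> list:
        return [frozenset(c) for c in self.clusters]


@dataclass
class GAConfig:
    """Run configuration for the genetic algorithm.

    ``n_clusters`` (k) only shapes random initialization; with spectral
    initialization k is inherited from the spectral partition.  Fitness
    is maximized; ``patience`` stops a run early after that many
    generations without improvement (None disables early stopping).
    """

    population_size: int = 80
    generations: int = 200
    n_clusters: int = 20
    mutation_rate: float = 0.8
    elitism_count: int = 2
    objective: str = "density"
    init: str = "spectral"
    seed: int = 0
    move_vs_expand_prob: float = 0.5
    min_complex_size: int = 3
    selection: str = "roulette"
    tournament_size: int = 2
    patience: int | None = 50

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 1 <= self.elitism_count < self.population_size:
            raise ValueError("need 1 <= elitism_count < population_size")
        for p in (self.mutation_rate, self.move_vs_expand_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.init not in ("random", "spectral"):
            raise ValueError("init must be 'random' or 'spectral'")
        if self.selection not in ("roulette", "tournament"):
            raise ValueError("selection must be 'roulette' or 'tournament'")
        objectives.get_objective(self.objective)  # validates the name


@dataclass
class Population:
    individuals: list
    generation: int = 0

    def __len__(self) -> int:
        return len(self.individuals)


def _rng_of(config: GAConfig, rng=None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(config.seed)


def _evaluate(net: PPINetwork, individual: Clustering, objective: str) -> float:
    if individual.fitness is None:
        individual.fitness = objectives.get_objective(objective)(net, individual)
    return individual.fitness


def init_population_random(net: PPINetwork, config: GAConfig, rng=None) -> Population:
    """m random individuals of k clusters each.

    Each cluster draws ~N/k node indices uniformly with replacement
    (repeats within a cluster collapse; cross-cluster repeats create
    overlap).  Nodes left unassigned are appended to a uniformly chosen
    cluster so every individual covers the network.
    """
    rng = _rng_of(config, rng)
    N, k = net.n_proteins, config.n_clusters
    if k < 1:
        raise ValueError("n_clusters must be >= 1")
    if k > N:
        raise ValueError(f"n_clusters={k} exceeds network size N={N}")
    per_cluster = max(1, round(N / k))
    individuals = []
    for _ in range(config.population_size):
        clusters = []
        for _ in range(k):
            draws = rng.integers(0, N, size=per_cluster)
            clusters.append({net.proteins[j] for j in draws})
        assigned = set().union(*clusters)
        for p in net.proteins:
            if p not in assigned:
                clusters[int(rng.integers(0, k))].add(p)
        individuals.append(Clustering(clusters))
    return Population(individuals)


def init_population_spectral(
    net: PPINetwork,
    config: GAConfig,
    spectral_config: SpectralConfig | None = None,
    rng=None,
) -> Population:
    """Population anchored at the recursive spectral clustering.

    Individual 0 is the exact spectral partition; the remaining m-1 are
    perturbations of it obtained by applying the mutation operator 1-3
    times, which keeps diversity while starting near a good solution.
    """
    if config.population_size < 2:
        raise ValueError("population_size must be >= 2")
    rng = _rng_of(config, rng)
    base = recursive_spectral_clustering(net, spectral_config or SpectralConfig())
    individuals = [base.copy()]
    for _ in range(config.population_size - 1):
        ind = base.copy()
        for _ in range(int(rng.integers(1, 4))):
            ind = mutate(ind, net, rng, config)
        individuals.append(ind)
    return Population(individuals)


def select_parents(population: Population, rng, config: GAConfig) -> list:
    """Sample m - elitism_count parents (with replacement) by fitness.

    Roulette wheel on shifted-positive fitness values: each fitness has
    the population minimum subtracted and a small epsilon added, so
    non-positive fitnesses are handled and an all-equal population
    degenerates to uniform sampling.  Tournament selection is available
    as a config alternative.
    """
    inds = population.individuals
    if any(ind.fitness is None for ind in inds):
        raise ValueError("all fitnesses must be computed before selection")
    fitness = np.array([ind.fitness for ind in inds], dtype=float)
    n_draw = len(inds) - config.elitism_count
    if config.selection == "tournament":
        chosen = []
        for _ in range(n_draw):
            contenders = rng.integers(0, len(inds), size=config.tournament_size)
            chosen.append(inds[int(max(contenders, key=lambda i: fitness[i]))])
        return chosen
    span = float(fitness.max() - fitness.min())
    shifted = fitness - fitness.min() + 1e-9 * max(1.0, span)
    probs = shifted / shifted.sum()
    picks = rng.choice(len(inds), size=n_draw, p=probs)
    return [inds[int(i)] for i in picks]


def mutate(individual: Clustering, net: PPINetwork, rng, config: GAConfig) -> Clustering:
    """One mutation step; returns a new individual (fitness invalidated).

    With probability ``move_vs_expand_prob`` a uniformly chosen
    (cluster, member) occurrence is moved to another uniformly chosen
    cluster; otherwise the member's network neighbours are all added to
    its cluster (the overlap-creating move).  Degenerate cases (k = 1
    for the move branch, all clusters empty) are no-ops.
    """
    clusters = [set(c) for c in individual.clusters]
    occurrences = [
        (ci, v)
        for ci, c in enumerate(clusters)
        for v in sorted(c, key=net.index.__getitem__)
    ]
    if not occurrences:
        logger.warning("mutate called on an individual with all-empty clusters")
        return Clustering(clusters)
    move = rng.random() < config.move_vs_expand_prob
    ci, v = occurrences[int(rng.integers(0, len(occurrences)))]
    if move:
        if len(clusters) > 1:
            targets = [j for j in range(len(clusters)) if j != ci]
            tj = targets[int(rng.integers(0, len(targets)))]
            clusters[ci].discard(v)
            clusters[tj].add(v)
    else:
        clusters[ci] |= net.neighbor_sets[v]
    return Clustering(clusters)


def postprocess(best: Clustering, config: GAConfig) -> Clustering:
    """Filter a raw GA solution into predicted complexes.

    Drops empty clusters and clusters smaller than ``min_complex_size``,
    merges duplicates (identical member sets), and orders clusters by
    (descending size, then sorted members) for reproducible output.
    """
    seen: set = set()
    kept = []
    for c in best.clusters:
        if len(c) < max(1, config.min_complex_size):
            continue
        key = frozenset(c)
        if key in seen:
            continue
        seen.add(key)
        kept.append(set(c))
    if not kept:
        logger.warning("post-processing removed every cluster")
    kept.sort(key=lambda c: (-len(c), tuple(sorted(str(m) for m in c))))
    return Clustering(kept)


class GeneticComplexDetector(BaseEstimator):
    """Overlapping complex detection by a mutation-only genetic algorithm.

    Parameters mirror :class:`GAConfig` plus the spectral-initialization
    knobs; ``random_state`` seeds every source of randomness.  Accepts a
    :class:`~gacomplex.network_io.PPINetwork`, a networkx graph or a
    symmetric adjacency matrix.

    Attributes (after :meth:`fit`)
    ------------------------------
    best_clustering_ : Clustering
        Raw best-ever individual.
    clusters_ : list of frozenset
        Post-processed predicted complexes (>= ``min_complex_size``
        members, duplicates merged).
    history_ : list of float
        Best fitness per generation (element 0 is the initial
        population); non-decreasing by the elitism guarantee.
    best_fitness_ : float
    n_clusters_ : int
    """

    def __init__(
        self,
        objective: str = "density",
        init: str = "spectral",
        population_size: int = 80,
        generations: int = 200,
        n_clusters: int = 20,
        mutation_rate: float = 0.8,
        elitism_count: int = 2,
        move_vs_expand_prob: float = 0.5,
        min_complex_size: int = 3,
        selection: str = "roulette",
        tournament_size: int = 2,
        patience: int | None = 50,
        split_threshold: float = 1.0,
        spectral_min_cluster_size: int = 1,
        eig_tol: float = 1e-8,
        random_state: int | None = None,
    ):
        self.objective = objective
        self.init = init
        self.population_size = population_size
        self.generations = generations
        self.n_clusters = n_clusters
        self.mutation_rate = mutation_rate
        self.elitism_count = elitism_count
        self.move_vs_expand_prob = move_vs_expand_prob
        self.min_complex_size = min_complex_size
        self.selection = selection
        self.tournament_size = tournament_size
        self.patience = patience
        self.split_threshold = split_threshold
        self.spectral_min_cluster_size = spectral_min_cluster_size
        self.eig_tol = eig_tol
        self.random_state = random_state

    def _ga_config(self) -> GAConfig:
        return GAConfig(
            population_size=self.population_size,
            generations=self.generations,
            n_clusters=self.n_clusters,
            mutation_rate=self.mutation_rate,
            elitism_count=self.elitism_count,
            objective=self.objective,
            init=self.init,
            seed=0 if self.random_state is None else int(self.random_state),
            move_vs_expand_prob=self.move_vs_expand_prob,
            min_complex_size=self.min_complex_size,
            selection=self.selection,
            tournament_size=self.tournament_size,
            patience=self.patience,
        )

    def _spectral_config(self) -> SpectralConfig:
        return SpectralConfig(
            split_threshold=self.split_threshold,
            min_cluster_size=self.spectral_min_cluster_size,
            eig_tol=self.eig_tol,
        )

    def fit(self, X, y=None):
        net = as_network(X)
        config = self._ga_config()
        if config.generations < 1:
            raise ValueError("generations must be >= 1")
        rng = np.random.default_rng(config.seed)
        if config.init == "spectral":
            pop = init_population_spectral(net, config, self._spectral_config(), rng)
        else:
            pop = init_population_random(net, config, rng)
        for ind in pop.individuals:
            _evaluate(net, ind, config.objective)
        best = max(pop.individuals, key=lambda ind: ind.fitness).copy()
        history = [best.fitness]
        stagnant = 0
        for gen in range(config.generations):
            ranked = sorted(
                range(len(pop.individuals)),
                key=lambda i: (-pop.individuals[i].fitness, i),
            )
            elites = [pop.individuals[i].copy() for i in ranked[: config.elitism_count]]
            parents = select_parents(pop, rng, config)
            offspring = []
            for parent in parents:
                if rng.random() < config.mutation_rate:
                    child = mutate(parent, net, rng, config)
                else:
                    child = parent.copy()
                offspring.append(child)
            pop = Population(elites + offspring, generation=gen + 1)
            improved = False
            for ind in pop.individuals:
                _evaluate(net, ind, config.objective)
                if ind.fitness > best.fitness:
                    best = ind.copy()
                    improved = True
            history.append(best.fitness)
            stagnant = 0 if improved else stagnant + 1
            if config.patience is not None and stagnant >= config.patience:
                break
        self.network_ = net
        self.best_clustering_ = best
        self.best_fitness_ = best.fitness
        self.history_ = history
        predicted = postprocess(best, config)
        self.clusters_ = predicted.as_frozensets()
        self.n_clusters_ = len(self.clusters_)
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        """Fit and return a boolean membership matrix (n_nodes, n_clusters_)."""
        self.fit(X, y)
        net = self.network_
        member = np.zeros((net.n_proteins, self.n_clusters_), dtype=bool)
        for ci, cluster in enumerate(self.clusters_):
            for v in cluster:
                member[net.index[v], ci] = True
        return member


def evolve(net: PPINetwork, config: GAConfig, spectral_config: SpectralConfig | None = None):
    """Run the GA; thin wrapper over :class:`GeneticComplexDetector`.

    Returns ``(best, history)``: the raw best-ever individual and the
    per-generation best-fitness trace.
    """
    spectral_config = spectral_config or SpectralConfig()
    est = GeneticComplexDetector(
        objective=config.objective,
        init=config.init,
        population_size=config.population_size,
        generations=config.generations,
        n_clusters=config.n_clusters,
        mutation_rate=config.mutation_rate,
        elitism_count=config.elitism_count,
        move_vs_expand_prob=config.move_vs_expand_prob,
        min_complex_size=config.min_complex_size,
        selection=config.selection,
        tournament_size=config.tournament_size,
        patience=config.patience,
        split_threshold=spectral_config.split_threshold,
        spectral_min_cluster_size=spectral_config.min_cluster_size,
        eig_tol=spectral_config.eig_tol,
        random_state=config.seed,
    ).fit(net)
    return est.best_clustering_, est.history_
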