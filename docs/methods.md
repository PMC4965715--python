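# Methods

## Model and search procedure

The package treats protein-complex prediction as the maximization of a
clustering objective over the space of *overlapping* clusterings of a
PPI network. An individual is an ordered list of k node-sets; within a
set repeats are impossible (sets), but the same protein may sit in
several sets, which is the representation's way of expressing shared
subunits. The genetic algorithm iterates

    evaluate -> copy elites -> select parents -> mutate,

with fitness-proportionate (roulette-wheel) selection over
shifted-positive fitness values (population minimum subtracted, small
epsilon added, so non-positive fitness and all-equal populations are
handled; tournament selection is available as an alternative). The
elitism_count best individuals are copied unchanged each generation, so
the best-fitness trace is monotone non-decreasing — a property the test
suite asserts. Crossover is excluded by design: recombining two
clusterings almost always breaks their dense blocks.

Mutation has two equiprobable branches (`move_vs_expand_prob = 0.5`):

* **move** — a uniformly chosen (cluster, member) occurrence is moved
  to another uniformly chosen cluster (no-op when k = 1);
* **expand** — a uniformly chosen (cluster, member) occurrence pulls
  all network neighbours of that member into its cluster. This is the
  overlap-creating move: a boundary protein can drag a neighbouring
  complex's members into its own cluster without removing them
  elsewhere.

Stopping: a fixed generation budget plus early stop after `patience`
(default 50) generations without improvement of the best-ever fitness.
Every run is a pure function of (inputs, seed); the test suite asserts
bit-reproducibility of populations and fitness traces.

## Objectives

The density fitness JD sums, over clusters, the ratio of internal edges
to (maximum possible internal edges + boundary edges). Terms with a
zero denominator (empty and singleton clusters) contribute 0, so
degenerate clusters are penalized rather than crash-inducing. In the
two-way objectives a zero denominator with a non-zero cut returns an
infinite sentinel (worst possible value), logged.

The two-way min-max / ratio / normalized cuts are defined on
bipartitions only; their multiway forms used as GA fitness variants sum
per-cluster boundary/denominator terms and are negated so that "higher
is better" holds for all four objectives uniformly. On a covering
2-cluster partition each multiway form reduces exactly to its two-way
counterpart (asserted by tests). Degree masses in the two-way
normalized cut are taken within the scored subgraph, so recursive
bisection is self-similar; the multiway normalized form uses
whole-network degrees.

A representational subtlety worth knowing: because clusters are scored
independently, an overlapping clustering (including one that repeats a
dense cluster verbatim) can score a higher JD than the best exclusive
partition. Post-processing merges duplicate clusters, and the
small-graph oracle test therefore asserts that the GA *attains at
least* the exhaustive-partition optimum rather than treating that
optimum as an upper bound.

## Spectral initialization

Recursive spectral bisection builds both the exclusive baseline
clustering and the GA's seeded population. Connected components are
always separated before any eigenproblem is solved, so the generalized
pencil (Q, D) is that of a connected graph and D is positive definite;
degree-0 nodes become singletons immediately. The Fiedler vector is
computed densely (`scipy.linalg.eigh`, generalized, second-smallest
eigenvalue), D-normalized, sign-fixed so the first nonzero component is
positive. The split is 1-D 2-means on the eigenvector components with
deterministic min/max initialization and ties breaking toward the
lower-mean centroid; a constant eigenvector falls back to an
index-parity split. A block is split while the normalized cut of the
accepted split is below `split_threshold` (default 1.0 — JN of a
covering bipartition lies in [0, 2], and 1.0 is the natural midpoint at
which a split stops being better than balanced noise) and both children
have at least `min_cluster_size` (default 1) nodes. No sweep over all
threshold cuts of the eigenvector is performed; the 2-means split is
the one evaluated.

With spectral initialization, individual 0 is the exact spectral
partition and the remaining m − 1 individuals are copies perturbed by
1–3 mutation steps. With random initialization each of the k clusters
draws ~N/k node indices uniformly with replacement, and any node left
unassigned is appended to a uniformly chosen cluster — the coverage
rule, chosen so that the discard ratio measures post-processing, not
initialization gaps.

## Evaluation protocol

For each predicted cluster and each reference complex sharing at least
one protein, the match p-value is the hypergeometric tail
P(X ≥ k) with N = number of network proteins, M = complex members
*present in the network* (members absent from the network cannot be
drawn, so the urn model stays coherent), n = cluster size, k = overlap;
the tail is evaluated by `scipy.stats.hypergeom.sf` and checked in the
tests against exact rational arithmetic to 1e-12 relative. Each cluster
keeps its minimum-p complex (ties: larger overlap, then complex name);
the best matches are Benjamini–Hochberg corrected and kept at
alpha = 0.05 by default.

Aggregation to single numbers: precision averages P = |C∩G|/|C| over
matched clusters (cluster-side); recall averages, over reference
complexes with at least one network member, the best R = |C∩G|/|G| any
matched cluster achieves (complex-side, 0 for complexes nobody found);
F is the harmonic mean of the two aggregates. The discard ratio counts
proteins (not clusters) in no predicted complex. Post-processing drops
clusters below `min_complex_size` (default 3, the usual convention for
complex prediction) and merges duplicates before evaluation.

## Synthetic benchmarks

The planted-complex generator emulates the modular structure the method
assumes: dense blocks (edge probability `p_in`) in a sparse background
(`p_out`), optionally sharing `shared_count` proteins between adjacent
complex pairs (planted overlap) and with filler proteins in no complex.
Edges are independent Bernoulli draws; each unordered pair receives one
uniform variate in a fixed order, so at a fixed seed the edge set is
reproducible and grows monotonically with `p_out`. Default conditions —
six complexes of ten proteins, p_in = 0.8, p_out = 0.02, no filler —
are the standard recovery setting used across the tests and the
acceptance script: dense enough that complexes are identifiable, sparse
enough that the background is not trivially empty.

What the generator does **not** emulate: the power-law degree
distribution, the false-positive/false-negative structure of real
interaction screens, and size heterogeneity of real catalogs. Passing
recovery tests therefore demonstrate correctness of the machinery and
robustness to mild background noise, not performance on real PPI data.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: 60-node planted
networks for end-to-end recovery (20 seeds), 30-node 2-block graphs for
spectral agreement, 8-node graphs for exhaustive-partition oracles
(Bell(8) = 4140 partitions), and the full N ≤ 30 hypergeometric grid.
The dense generalized eigensolver is comfortable to a few thousand
nodes, which covers the yeast-scale networks the method targets;
networks far beyond that would want a sparse Lanczos path, a known
limitation. Eigensolver residuals are checked against `eig_tol`
(default 1e-8). All file output orders clusters by (descending size,
first member) and members lexicographically, so results are
byte-reproducible across runs and platforms.

## Known limitations

* The multiway forms of JM/JR/JN are a generalization the two-way
  definitions do not uniquely determine; they are labelled as such.
* Aggregate R/P/F involve an aggregation choice (documented above);
  other summaries of the same match records are possible.
* Edge weights are accepted and propagated through the cut machinery,
  but the default workflow treats networks as unweighted, matching the
  counts-of-edges objective definitions; weighted operation is an
  extension, not a validated mode.
* JD's per-cluster independence means duplicated clusters inflate raw
  fitness (see Objectives); interpretation of raw fitness values should
  use the post-processed clustering.
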