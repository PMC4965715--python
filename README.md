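# gacomplex

Detection of protein complexes in protein–protein interaction (PPI)
networks by a genetic algorithm, with support for **overlapping**
complexes — the biological reality that one protein can participate in
several complexes, which classical exclusive graph clusterings cannot
express.

PPI networks are small-world, power-law graphs in which complexes appear
as locally dense subgraphs of very different densities. `gacomplex`
searches the space of clusterings directly: an individual is a list of
*k* node-sets over the network (a node may appear in several sets), and
a population of such clusterings evolves by fitness-proportionate
selection with elitism and a two-branch mutation operator (move a node
between clusters, or add a node's network neighbours to its cluster).
Crossover is deliberately excluded: it disrupts good partial
clusterings. The population is seeded either randomly or from a
recursive spectral bisection of the network.

## The objective functions

For a bipartition (V₁, V₂), with W₁₂ the cut weight, W₁₁/W₂₂ the
internal edge weights and d₁/d₂ the degree masses:

* min-max cut  JM = W₁₂/W₁₁ + W₁₂/W₂₂
* ratio cut  JR = W₁₂/|V₁| + W₁₂/|V₂|
* normalized cut  JN = W₁₂/d₁ + W₁₂/d₂

The normalized cut drives the spectral bisection: a connected subgraph
is split by the eigenvector of Qx = λDx (Q = D − A the Laplacian) at
the smallest positive λ, with the two sides chosen by 1-D 2-means on
the eigenvector, recursively while JN of the accepted split stays below
a threshold.

The GA's native fitness is the **density cut**, defined for a whole
clustering C₁,…,C_k:

JD = Σₖ W_kk / (A_k + W_ki)

where W_kk is the number of edges inside cluster C_k, W_ki the number
of edges leaving it, and A_k = |C_k|(|C_k|−1)/2 the maximum possible
internal edge count. Each term lies in [0, 1] and is 1 exactly for an
isolated clique, so JD rewards dense, well-separated clusters while
adapting to the local edge density. Multiway generalizations of
JM/JR/JN are provided so all four objectives can drive the GA.

Predicted clusters are matched to a reference catalog (CYC2008/MIPS
style) by the hypergeometric tail probability of the overlap, corrected
by Benjamini–Hochberg; precision, recall, F-measure and the discard
ratio (fraction of proteins in no predicted complex) are reported per
match and in aggregate.

## Worked example

No downloads are needed: the package ships a planted-complex generator
that produces a benchmark network together with its ground truth.

```sh
gacomplex simulate --seed 5 --out-network net.tsv --out-complexes truth.txt
# 60 proteins, 269 interactions, 6 planted complexes
gacomplex stats --network net.tsv
# {"n_proteins": 60, "n_edges": 269, "avg_degree": 8.9667, "density": 0.152}
gacomplex cluster --network net.tsv --seed 5 --pop-size 40 --generations 60 --out pred.tsv
# 8 predicted complexes (best fitness 5.0764) -> pred.tsv
gacomplex evaluate --clusters pred.tsv --reference truth.txt --network net.tsv
# #Cls=8 R=1.00 P=0.93 F=0.96 Discard=0%
```

The evaluate line reads: 8 predicted complexes had a significant
hypergeometric match; averaged over the 6 planted complexes the best
matching cluster recovers 100 % of the members (R), matched clusters
are 93 % pure on average (P), F is their harmonic mean, and every
protein of the network was placed in some complex (discard 0 %).

The same pipeline is available as a scikit-learn style estimator:

```python
from gacomplex import GeneticComplexDetector, PlantedSpec, generate

net, truth = generate(PlantedSpec(seed=5))
est = GeneticComplexDetector(objective="density", init="spectral",
                             random_state=5).fit(net)
est.clusters_      # list of frozensets of protein IDs (overlap allowed)
est.history_       # per-generation best fitness, non-decreasing
```

`RecursiveSpectralClustering` exposes the exclusive spectral baseline
with the same interface (`fit`, `labels_`), and both accept a
`PPINetwork`, a networkx graph or a symmetric adjacency matrix.

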