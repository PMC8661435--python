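# rankga

Pseudotime ordering of single cells by a genetic algorithm on a
rank-polynomial BIC cost.

## The problem

Single-cell RNA-seq captures a snapshot of cells spread along an ongoing
biological process — differentiation, the cell cycle, a stimulus
response.  *Pseudotime* inference orders the cells so that transcriptomes
change gradually along the ordering.  Most tools first compress the
expression matrix to two or three dimensions and build a trajectory
there; information that does not survive the embedding is lost.  `rankga`
instead searches the space of cell *permutations* directly, on the full
expression matrix.

## The model

Let `R_ij` be the rank of cell `i` among the expression values of gene
`j` (average ranks for ties; zeros rank lowest).  A candidate trajectory
assigns pseudotimes `t ∈ {1, …, n}` (a permutation), and each gene's ranks
are modelled as a polynomial of pseudotime of degree at most 3:

```
R_ij = β_j0 + β_j1 t_i + β_j2 t_i² + β_j3 t_i³ + ε_ij
```

Each degree d ∈ {1, 2, 3} is fit by least squares and scored with
`BIC_dj = n·ln(σ̂²_dj) + d·ln(n)`; the gene's cost is the best of the
three, and the ordering's cost `C` is the sum over genes.  A genetic
algorithm (inversion mutation, Poisson-cut crossover with
bipartite-matching repair, quarter selection; 400 cost evaluations per
generation, ≥30 generations) minimises `C` over permutations.  Working on
ranks makes the result invariant to any monotone transform of expression;
degree ≤ 3 covers monotone, single-peaked and one-cycle genes.

Also included, as part of the same method family:

* **Branching lineages** — order each cell cluster separately, join the
  cluster paths into a tree by a minimum-spanning-tree rule on
  quarter-segment junction costs, optionally root it at a cell/cluster.
* **Large datasets** — order random subsamples, extend each subsample
  trajectory to all cells by r-nearest-neighbour score averaging, and
  pool B subsamples with a principal curve through the B-dimensional
  score vectors.
* **A Gamma-Poisson trajectory simulator** (five gene trend classes,
  three dropout regimes) and evaluation metrics (absolute Spearman
  correlation against a reference; count of genes with a significant
  rank-polynomial relation to the estimate).

## Worked example

```python
from rankga import (SimConfig, simulate_trajectory, GAConfig, evolve,
                    rank_transform, abs_spearman, count_functional_genes)
from rankga.rank_cost import ordering_to_pseudotime

truth = simulate_trajectory(SimConfig(n_cells=80, n_genes=100, seed=1))
res = evolve(rank_transform(truth.counts), GAConfig(seed=1, min_generations=60))
pt = ordering_to_pseudotime(res.ordering)
print(f"best cost {res.cost:.1f} after {res.n_generations} generations")
print(f"|Spearman| vs generating pseudotime: {abs_spearman(pt, truth.true_pseudotime):.3f}")
print(f"pseudotime-associated genes (BH alpha=0.05): {count_functional_genes(truth.counts, res.ordering)}")
```

prints

```
best cost 46295.1 after 61 generations
|Spearman| vs generating pseudotime: 0.950
pseudotime-associated genes (BH alpha=0.05): 81
```

The simulated dataset has 80 trend-bearing genes and 20 pseudotime-independent
genes: the recovered ordering correlates 0.95 with the generating
pseudotime, and 81 genes show a significant rank-polynomial relation to
it.  The `min_generations` knob trades runtime for ordering quality; the
default (30) is the published operating point.

The same pipeline is available from the shell:

```sh
rankga simulate --n-cells 200 --n-genes 100 --seed 1 --out expr.tsv
rankga order expr.tsv --seed 1 --out pseudotime.tsv
rankga evaluate expr.tsv pseudotime.tsv
rankga big expr.tsv -b 10 -m 50 --seed 1 --out consensus.tsv   # subsample consensus
rankga lineage expr.tsv --k 3 --root 0 --out-dir lineage/      # branching tree
rankga run config.yaml                                          # config-driven pipeline
```

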