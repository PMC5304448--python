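# phenolink

Tools for linking RNAi loss-of-function phenotype profiles to cellular-process
function. The package covers four analysis stages, each usable on its own:

1. **Similarity measures** — seven binary-profile measures (euclidean,
   correlation, cosine, hamming, jaccard, Cohen's kappa, TF-IDF), the same
   vector measures in a logistic-PCA reduced space, and five ontology semantic
   similarity measures (Resnik, Lin, Schlicker, Jiang, Pesquita/simGIC) with
   max / average / best-match-average gene-level aggregation.
2. **Interaction benchmarking** — ranking the measures by AUC against labelled
   protein-interaction pair sets, nearest-neighbour interaction recovery with
   hypergeometric significance, and an average-linkage dendrogram of
   inter-measure correlation.
3. **Phenotype–function association** — per-phenotype mean functional
   similarity with column-sum-preserving permutation nulls, BH-corrected
   significance, cross-similarity binned distributions, high-similarity
   randomization checks, and IC-distribution comparisons.
4. **Annotation-driven clustering** — bipartite projection of gene–term
   annotations into a Jaccard-weighted term graph, normalized-cut spectral
   clustering with recursive splitting, and cross-ontology cluster-coherence
   tests against shuffle nulls.

A fully seeded synthetic-data module generates every input the pipeline
consumes (toy OBO ontologies, annotation corpora, binary phenotype matrices
with planted gene modules, interaction pair sets), so the whole analysis runs
and is tested without any external downloads.

## Command line

A single `phenolink` entry point with subcommands. Every run is driven by a
YAML config and writes plain-TSV reports plus a manifest that makes reruns
byte-identical.

```bash
# generate a synthetic dataset in the same file dialects real data would use
phenolink synth -c config.yaml -o out/synth

# rank all 15 similarity measures by interaction AUC
phenolink benchmark -c config.yaml -o out/benchmark

# per-phenotype functional-coherence permutation test (optionally with
# 5/10/20/30% sparsity-perturbation reruns)
phenolink phenotest -c config.yaml -o out/phenotest --perturb

# term-graph projection, spectral clustering, cross-ontology coherence
phenolink cluster -c config.yaml -o out/cluster

# per-term information-content table
phenolink ic -c config.yaml -o out/ic --ontology cmpo
```

A config either contains a `synthetic:` block with generator parameters, or
paths to real inputs:

```yaml
go_obo: go.obo            # OBO 1.2/1.4; restricted via go_root if given
go_root: "GO:0009987"
go_annotations: ann.gaf   # GAF 2.x (IEA excluded by default) or gene<TAB>term TSV
cmpo_obo: cmpo.obo
matrix: matrix.tsv        # header: phenotype ids; first column: gene id; 0/1 cells
interactions: pairs.tsv   # gene1<TAB>gene2<TAB>pos|neg[<TAB>source]
seed: 1
n_perm: 100
n_rand: 100
cluster: {go_k: 100, go_splits: [[1, 33], [2, 9]], cmpo_k: 13}
```

## Layout

```
src/phenolink/
  ontology.py     OBO parsing, DAG handling, annotation propagation, IC, MICA
  profiles.py     binary-profile similarity, logistic PCA, sparsity perturbation
  semantic.py     term- and gene-level semantic similarity
  benchmark.py    interaction AUC / nearest-neighbour benchmarking
  association.py  permutation tests and association diagnostics
  clustering.py   term-graph projection and normalized-cut spectral clustering
  synthetic.py    seeded generators for all inputs + packaged fixture table
  cli.py          command-line entry points
  stats.py        BH adjustment, empirical p-values, hypergeometric tails
```
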