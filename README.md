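# graynet

Binary structural-covariance networks, Newman-style spectral modularity, and
**gray nodes** — an overlapping-module metric obtained by maximising the
modularity quadratic form over ternary (−1/0/+1) assignments instead of
bipartitions. Nodes assigned 0 in an accepted division belong to both
resulting modules at once; the proportion of such nodes indexes the overlap
in a network's modular architecture.

The package covers the full analysis chain for two-group morphometry cohorts:

1. **Network construction** (`graynet.covariance_network`) — residualize each
   region on nuisance covariates (age, per-subject mean thickness), correlate
   regions across subjects, discard non-positive correlations, apply a
   Benjamini–Hochberg FDR step-up (default q = 0.2) to one-sided p-values and
   binarize. Correlation-threshold sweeps report edges, density, sparsity and
   isolated-group counts.
2. **Spectral modularity** (`graynet.spectral_modularity`) — modularity matrix
   `B = A − kkᵀ/(2m)`, shifted power iteration for the leading bipartition,
   Kernighan–Lin sign-flip refinement, recursive division via generalised
   subgraph matrices, and module-count curves over a sweep of quality
   thresholds (a division is accepted only if its Q/ΔQ contribution reaches
   the threshold).
3. **Gray nodes** (`graynet.gray_nodes`) — the same quadratic form maximised
   over ternary vectors by seeded coordinate descent (started from the
   spectral bipartition), recursive ternary division, gray-node sets and
   gray-proportion curves. Exhaustive 2ⁿ/3ⁿ oracles are included for
   validation on small graphs.
4. **Null ensembles** (`graynet.null_ensemble`) — degree-preserving
   double-edge-swap randomization, Monte-Carlo mean ± 1σ curves (default
   1000 replicates) and observed-vs-null z-scores.
5. **Cohort statistics** (`graynet.cohort_stats`) — pooled-variance two-sample
   t tests from raw values or published group summaries.
6. **Synthetic data** (`graynet.synthetic_data`) — seeded stochastic block
   graphs, shared-node clique chains, and a latent-factor cohort generator
   producing two-group thickness tables with planted block covariance,
   age effects and a tunable group difference in covariance strength.

Everything is deterministic under an explicit seed.

## Command line

```sh
# synthesize a two-group cohort from a YAML spec
graynet simulate --spec cohort.yaml --out-prefix sim_

# thickness table -> FDR-binarized covariance graph
graynet build-network --table sim_groupA.tsv --q 0.2 \
    --out-graph groupA_graph.tsv --out-corr groupA_corr.tsv

# module-count curve over a Q-threshold sweep
graynet modularity --graph groupA_graph.tsv --thresholds 0:0.32:0.02 \
    --restarts 32 --seed 7 --out curve.tsv

# gray-node proportion curve
graynet gray --graph groupA_graph.tsv --thresholds 0:0.32:0.02 \
    --seed 7 --out gray_curve.tsv

# observed curve vs a 1000-replicate degree-matched null
graynet null --graph groupA_graph.tsv --metric gray_proportion \
    --reps 1000 --seed 7 --out null.tsv

# pooled t report from a group-summary table
graynet cohort-stats --table summaries.tsv --out stats.tsv

# full two-group pipeline (network -> curves -> nulls -> comparison)
graynet run --group-a sim_groupA.tsv --group-b sim_groupB.tsv \
    --reps 1000 --seed 7 --out-dir results/
```

Thickness tables are delimited text (TSV/CSV autodetected): first column the
subject id, `cov_`-prefixed columns are covariates, every other column a
region. Graphs are two-column edge lists or labelled adjacency matrices.
Every output TSV embeds the effective configuration, so identical runs are
byte-identical. Exit codes: 0 success, 2 input error, 3 numerical failure.

## Layout

```
src/graynet/
  graph_core.py           simple binary graphs, components, density/sparsity
  covariance_network.py   residualize -> Pearson -> FDR binarize -> sweeps
  spectral_modularity.py  B matrix, power iteration, recursive division
  gray_nodes.py           ternary extended modularity, gray-node recursion
  null_ensemble.py        degree-matched rewiring, Monte-Carlo summaries
  cohort_stats.py         pooled two-sample t
  synthetic_data.py       planted graphs and cohort generators
  cli_io.py               file formats, RunConfig, pipeline, CLI
tests/                    unit + property tests, test_acceptance.py
scripts/acceptance.py     acceptance report
```
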