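# commrobust

How much should you trust the social communities you detected?

Animal social networks are usually inferred from incomplete observation
streams — flocks, herds or sampling periods recorded under the "gambit of
the group" assumption — and community-detection algorithms will happily
carve *any* such network into clusters. Modularity `Q` measures how strong
the clustering is, but not how reproducible the *assignment* of individuals
to communities is under the sampling effort actually invested.
`commrobust` computes **community assortativity** `r_com`, a bootstrap
measure of exactly that reproducibility, for researchers working with
group-by-individual (GBI) association data.

## The method

1. Build the weighted association network from the observation stream
   using the simple ratio index,
   `SRI_ij = x / (x + y_ij + y_i + y_j)`, the fraction of sampling units
   containing i or j in which the two were together.
2. Partition it by fast-greedy (Clauset–Newman–Moore) modularity
   optimization and record `Q` and the community labels.
3. Bootstrap the observation stream: resample units with replacement at
   the original sample size, rebuild the network, re-detect communities.
   Over replicates accumulate, for every dyad, `M_ij` (replicates where
   both were sampled and co-assigned) and `C_ij` (replicates where both
   were sampled), giving the co-membership proportion
   `P_ij = ΣM_ij / ΣC_ij`.
4. Score the `P` matrix against the empirical labels with the
   assortativity coefficient

   `r_com = (Σ_x e_xx − Σ_x a_x b_x) / (1 − Σ_x a_x b_x)`

   where `e` is the community mixing matrix of `P` and `a`, `b` its
   marginals. `r_com = 1` means every replicate reproduces the empirical
   assignment; values near the ≈0.2 random-association floor mean the
   assignment is no more stable than chance; negative values indicate
   systematic reassignment across community boundaries.

The package also provides the percentile bootstrap confidence interval of
`Q`, the bootstrap community-count histogram, a data-stream permutation
test of `Q` (swaps that preserve group sizes and individual observation
counts), a generative simulator with known ground-truth communities, and
sample-size (subsampling) curves for `Q` and `r_com`.

## Worked example

Given a wide GBI file `flocks.csv` (rows = observed groups, columns =
individual IDs, cells 0/1) for 30 birds observed in 200 flocks drawn from
three home communities:

```sh
$ commrobust compute --input flocks.csv --n-boot 100 --seed 1 --out demo_out
n = 30 individuals, 200 groups | c = 3, Q = 0.595 (95% CI 0.571-0.617), r_com = 1.000

$ commrobust permtest --input flocks.csv --n-perm 1000 --seed 1
Q = 0.595, P = 0.001998 (1000 permutations)
```

Reading: fast-greedy detection found `c = 3` communities with modularity
`Q = 0.595`; the data-stream permutation test says that much structure
essentially never arises from the sampling pattern alone (`P ≈ 0.002`);
and `r_com = 1.0` says all 100 bootstrap replicates reproduced the same
three communities — the assignment is as robust as it can be.
`demo_out/` contains `result.json` (Q, its CI, r_com, the labels and the
replicate community-count histogram), the dyadic `P_matrix.csv`, and the
labelled network as GraphML.

The same pipeline is available as library functions
(`read_gbi`, `build_sri_network`, `detect_communities`, `run_rcom`,
`permutation_test_Q`, `subsample_curve`, `sweep`), and
`commrobust simulate` / `commrobust subsample` expose the simulation grid
and the sample-size analysis from the shell. Individuals observed fewer
than a threshold number of times can be dropped with `--min-obs`.

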