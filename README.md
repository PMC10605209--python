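# scnkit

Group-level **structural covariance network (SCN)** analysis for regional
morphometry. Given a subjects × regions table of gray-matter volume (GMV)
— e.g. the 90 regions of the AAL atlas — and nuisance covariates (age,
sex, total intracranial volume), `scnkit` builds the group covariance
network, thresholds it into binary graphs over a density grid, computes
graph-theory metrics, and tests group differences with permutation
inference. A synthetic-cohort generator with block-modular covariance
makes every stage testable without subject-level MRI data.

## What it computes

For each group the network is the Pearson matrix `R = [r_ij]` of
covariate-residualized regional volumes across subjects, binarized at
each sparsity `s ∈ {0.19, 0.21, …, 0.49}` by keeping the
`round(s·N(N−1)/2)` strongest correlations. On each binary graph:

- **Global metrics** — mean clustering coefficient `Cp`, characteristic
  path length `Lp`, transitivity `T`, global/local efficiency
  `E_glob`/`E_loc`, and the small-world index
  `σ = (Cp/Cp_rand)/(Lp/Lp_rand)` against degree-preserving
  (Maslov–Sneppen) rewired null graphs.
- **Nodal metrics** — degree, betweenness (normalized to [0, 1]), nodal
  efficiency, nodal clustering; **hubs** are regions whose degree exceeds
  the across-region mean by more than 1.5 SD.
- **Degree distribution** — nonlinear least-squares fit of the
  exponentially truncated power law `P(d) = scale·d^(1/k)·exp(−d/d_c)`,
  with two-group log-rank comparison of degree samples.
- **Robustness** — decay of the largest connected component under random
  node failure (averaged over simulations) and adaptive degree-targeted
  attack, summarized by the area under the curve.
- **Inference** — between-group differences of any metric, aggregated
  across the density grid by trapezoidal AUC and tested by subject
  relabeling (default 1000 permutations, two-tailed
  `p = (count(|null| ≥ |obs|)+1)/(n_perm+1)`); per-density 95% null
  envelopes; Benjamini–Hochberg FDR across regions for nodal metrics.

## Worked example

```python
import numpy as np
from scnkit import (SyntheticSpec, generate_cohort, residualize,
                    correlation_network, threshold_over_grid,
                    sparsity_grid, metric_curve, small_world,
                    permutation_test)

gmv, cov = generate_cohort(SyntheticSpec(seed=1))   # 3 groups x 30 subjects
res = residualize(gmv, cov)                          # remove age/sex/TIV
grid = sparsity_grid()                               # 0.19 ... 0.49
net = correlation_network(res.subset("HC"), "HC")    # 90 x 90 Pearson r
graphs = threshold_over_grid(net, grid)              # 761 ... 1962 edges

print(metric_curve(graphs, "clustering", grid).auc)
rng = np.random.default_rng(0)
print(min(small_world(g, n_null=50, seed=rng).sigma for g in graphs))

r = permutation_test(res.subset("PWSD"), res.subset("HC"),
                     "clustering", grid, n_perm=1000, seed=0)
print(r.observed_diff, r.p_two_tailed)
```

prints (seeds as shown):

```
0.19152735047738506
1.2090665365811812
-0.004339129519302126 0.6173826173826173
```

The clustering AUC `0.1915` is the area of the clustering-versus-density
curve over the 0.30-wide grid (mean clustering ≈ 0.64); the minimum
small-world index `1.21 > 1` says the modular synthetic network is
clustered like a lattice but short-pathed like a random graph at every
density; and the permutation test correctly finds no clustering
difference (`p ≈ 0.62`) between two groups drawn from the same
generating law.

The `examples/` scripts walk one capability each (cohort simulation,
network construction, metrics, hubs and degree fits, robustness, group
comparison). A thin CLI mirrors the pipeline
(`scnkit simulate | build | metrics | hubs | fit-degree | attack |
compare | run-all`), driven by a YAML config; `run-all` writes tidy CSV
tables, BrainNet Viewer `.node`/`.edge` exports and a JSON manifest.

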