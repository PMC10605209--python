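# Methods

## Model and procedure

A structural covariance network treats each atlas region as a node and
the Pearson correlation of a morphometric measure (here regional
gray-matter volume, GMV, in mL) across the subjects of one group as the
edge weight. Because a group contributes a single network, there is no
per-subject network distribution; all group comparison is done by
permuting subject labels and rebuilding the networks.

The pipeline is:

1. **Residualization.** Each region's volume is regressed by OLS on an
   intercept, age (years), sex (0/1) and total intracranial volume (mL);
   residuals carry the inter-regional covariance of interest. The fit is
   per region, independent; regressors constant across subjects are
   dropped with a warning (they are absorbed by the intercept), and the
   design must leave more subjects than coefficients. Sex coding is
   irrelevant by the affine invariance of OLS (asserted in tests).
2. **Correlation network.** Pairwise Pearson `r` over subjects; the
   diagonal is fixed to 0 (no self-connections); zero-variance regions
   get zero correlations with a warning; at least 3 subjects required.
3. **Thresholding.** At target sparsity `s` the
   `round_half_away_from_zero(s·N(N−1)/2)` strongest edges become 1.
   Ranking uses *signed* correlation by default (most positive first);
   ranking by |r| is available (`ranking="absolute"`). Ties are broken
   by lexicographic region-pair index with a stable sort, which makes
   thresholding reproducible and the edge sets nested along the grid.
   The grid is 0.19–0.49 in steps of 0.02 (16 densities), built by
   integer indexing so no float drift can change an edge count. At
   N = 90 this spans 761–1962 edges.
4. **Metrics, hubs, degree fits, robustness, inference** as described
   below, each evaluated per density and summarized across the grid by
   the trapezoidal AUC (for the default grid a constant curve `c` has
   AUC `0.30·c`).

## Graph metrics

All metrics operate on undirected 0/1 graphs. Nodal clustering is
`triangles/(k(k−1)/2)` (0 for degree < 2); `Cp` is its mean; transitivity
is `3·triangles / connected triples`. Distances come from breadth-first
expansion; `Lp` averages over *reachable* ordered pairs only, with the
unreachable fraction reported — this keeps `Lp` finite and comparable
across permutations when a sparse graph momentarily disconnects.
`E_glob` is the mean inverse distance with `1/∞ = 0`, so disconnection is
handled natively; nodal efficiency is the row mean of inverse distances;
`E_loc` is the mean over nodes of the global efficiency of each node's
neighbor-induced subgraph. Betweenness is Brandes' accumulation
normalized by the `(N−1)(N−2)/2` pairs excluding the node, so values lie
in [0, 1] (a star center scores exactly 1).

Triangle counts, distances and efficiencies are vectorized numpy
routines (betweenness and component utilities delegate to networkx);
every metric is verified against exhaustive brute-force enumeration on
all ~1000 connected graphs with ≤ 7 nodes.

**Small-world index.** `σ = γ/λ` with `γ = Cp/⟨Cp_null⟩` and
`λ = Lp/⟨Lp_null⟩` over an ensemble of degree-preserving rewired graphs
(Maslov–Sneppen double-edge swaps, 10·|E| accepted swaps per null, 100
nulls by default). Degree-preserving nulls are used rather than
Erdős–Rényi because clustering and path normalization would otherwise
conflate degree-sequence effects with topology. The swap kernel is
numba-compiled with proposals drawn in bulk from the seeded generator,
so null ensembles are deterministic given a seed. Degree sequences that
admit no rewiring (e.g. complete graphs) return `γ = λ = σ = 1` with a
warning. With 100 nulls, `σ` varies by well under 5% between seeds on
the default synthetic networks.

## Hubs and degree structure

Hubs are regions whose degree summary strictly exceeds
`mean + 1.5·SD` (sample SD, n−1). The degree basis is the per-region
degree **averaged across the 16-density grid** by default — a
single-density basis is exposed — because hub status should not hinge
on one arbitrary density; the rule is shift-equivariant, so this choice
only affects resolution, not the principle.

The degree distribution is fitted with
`P(d) = scale·d^(1/k)·exp(−d/d_c)` — the exponent is read literally as
`1/k`, with `d^(k−1)` available as an option (`exponent="k_minus_1"`)
since that typographic reading exists in the literature. Fitting is
bounded multi-start nonlinear least squares on the degree
relative-frequency table over the full support `1..max(degree)`
(zero-count bins included, anchoring the tail); a cumulative (CCDF) form
is exposed as an alternative. `r² = 1 − SS_res/SS_tot` on the fitted
scale. Non-convergence and degenerate supports (< 3 distinct degrees)
yield a flagged failure, never an exception. At `n = 10⁵` samples the
fitter recovers generating parameters to well under 5% relative error;
at `n = 10⁴` the median error over replicates stays under 5%.

Degree samples of two groups are compared by the standard two-group
log-rank chi-square (degrees as uncensored event times, hypergeometric
variance, 1 df); three groups are compared pairwise. The implementation
is cross-checked against lifelines in the test suite, and its type-I
error is verified to sit at the nominal 5% over 2000 null replicates.

## Robustness

Random failure removes nodes in a uniformly random order; the largest
connected component (LCC), divided by the *original* N, is recorded
after each removal, and curves are averaged over `n_sim` orders (default
1000). The curve is computed by adding nodes in reverse order under a
union-find, which is effectively O(N+E) per simulation. Targeted attack
removes the currently highest-degree node at each step (degrees
recomputed after every removal — the adaptive protocol, stricter than a
static ordering, which remains available), ties going to the earlier
region label. The AUC over the removal fraction summarizes each curve;
random curves at `n_sim = 1000` match exact expectations (computable by
subset enumeration for N ≤ 8) within Monte-Carlo tolerance, and
targeted AUC never exceeds random AUC on hub-dominated graphs.

## Permutation inference

Residualization is performed **once on the pooled sample** before any
permutation: re-residualizing inside permuted pseudo-groups would be
ill-posed (the permuted labels carry no covariate meaning), and the
quantity being permuted is the covariate-corrected volume. For each of
`n_perm` relabelings (default 1000), pooled subjects are split into the
original group sizes, the full pipeline (correlate → threshold per
density → metric) is recomputed for both pseudo-groups, and the AUC
difference enters the null distribution. The two-tailed p is
`(count(|null| ≥ |observed|) + 1)/(n_perm + 1)` — never 0, valid by
construction. When the number of distinct splits does not exceed
`n_perm`, the engine enumerates every split exactly once and reports
`p = count/n_splits` (the identity split counts itself); this makes the
p-value exactly equal to exhaustive enumeration for small samples.
Per-density 2.5/97.5 percentiles of the null difference provide the 95%
envelopes used in difference-versus-density plots. Nodal metrics are
tested region-wise on their grid AUCs with Benjamini–Hochberg FDR across
the 90 regions (the field's default correction; recorded in output
metadata). Empirically the test is calibrated: over 200 independent
null cohort pairs the rejection rate at α = 0.05 stays within three
binomial standard errors of 0.05, and null p-values are compatible with
uniformity.

## Synthetic cohorts

The generator emulates what the analysis assumes about real
morphometry: per-region volumes that are multivariate normal with a
**block-constant correlation matrix** (six modules of 15 regions by
default, within-module `ρ_in = 0.5`, between-module `ρ_out = 0.1`),
additive linear covariate effects, and a mean volume of 6 mL with
residual SD 0.5 mL. Correlation is induced by latent factors — a global
factor with loading `√ρ_out`, one factor per block with loading
`√(ρ_in − ρ_out)`, idiosyncratic noise with loading `√(1 − ρ_in)` — so
the implied matrix is positive semi-definite by construction for any
`0 ≤ ρ_out ≤ ρ_in < 1`; anything else is rejected at construction.
Covariates default to age ~ N(25, 7) years, sex ~ Bernoulli(0.5), TIV ~
N(1450, 120) mL with per-region coefficients (−0.005, 0.15, 0.004) mL
per unit: a slight age-related decline, a small sex offset, and a strong
head-size scaling, the dominant nuisance in real volumetry. Group
covariance differences are injected as per-group `(Δρ_in, Δρ_out)`
perturbations; `generate_null_pair` strips all group effects so both
groups share one law. All randomness flows from a single seed through
numpy `SeedSequence` children spawned per group, so group order cannot
perturb draws and identical seeds reproduce byte-identical cohorts.

Degrees for testing the distribution fitter are sampled by inverse CDF
from the truncated power-law PMF on `{1..d_max}` (default `d_max = 50`),
which is exact and rejection-free; `d_c = None` drops the cutoff.

**What the generator does not emulate.** Real GMV covariance has
hemispheric symmetry, distance-dependent correlation, heavier-tailed
degree distributions and region-specific variances; the block-Gaussian
cohort has none of these. In particular its thresholded networks have
roughly binomial degree distributions, so the truncated power-law form
fits them poorly — parameter-recovery claims therefore use degrees
sampled from the model itself, and passing tests demonstrate
correctness of the machinery, not that real cohorts would show any
particular effect.

## Numerical choices and problem sizes

Edge counts round half away from zero (the convention is unstated in
the toolbox lineage; exactness matters only at ties). Correlations are
clipped to [−1, 1] and NaN-guarded for degenerate permuted columns.
Calibration runs use deliberately small problem sizes — 200 null pairs
of 20 subjects × 30 regions with 100 permutations, 100 rewired nulls
per density — chosen so the full calibration reruns in about a minute
while keeping binomial/Monte-Carlo error well below the margins being
asserted. The pipeline defaults (1000 permutations, 1000 attack
simulations, 100 nulls) are the standard protocol settings.

## Known limitations

- Group-level networks only; no individual-subject SCN construction
  (cube-based or distance-based variants).
- Binary graphs only; no weighted-metric variants.
- `Lp` on disconnected graphs averages reachable pairs, which is a
  choice, not the only convention; the unreachable fraction is always
  reported so users can detect when it matters.
- The truncated power-law fit is least squares on the frequency table,
  not maximum likelihood with model selection; it answers "do these
  degrees follow this printed form", not "which distribution family is
  best".
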