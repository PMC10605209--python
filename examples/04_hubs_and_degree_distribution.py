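"""Hub detection and truncated power-law degree-distribution fitting.

Hubs are regions whose grid-averaged degree exceeds mean + 1.5 SD. The
degree histogram is fitted with P(d) = scale * d^(1/k) * exp(-d/dc), and
groups are compared by the log-rank test on their degree samples.
"""

from scnkit import (SyntheticSpec, correlation_network, degrees,
                    fit_truncated_powerlaw, generate_cohort,
                    grid_averaged_degrees, identify_hubs, pairwise_logrank,
                    residualize, sparsity_grid, threshold_over_grid)

gmv, cov = generate_cohort(SyntheticSpec(seed=1))
res = residualize(gmv, cov)
grid = sparsity_grid()

degree_samples = {}
for group in gmv.groups():
    net = correlation_network(res.subset(group), group)
    graphs = threshold_over_grid(net, grid)
    hubs = identify_hubs(grid_averaged_degrees(
        [g.adjacency for g in graphs]), gmv.region_labels)
    print(f"{group}: {len(hubs)} hubs above degree "
          f"{hubs.threshold:.1f}: {', '.join(hubs.hub_regions[:4])} ...")
    # degree sample at the mid-grid density 0.33
    degree_samples[group] = degrees(graphs[7])

for (a, b), (stat, p) in pairwise_logrank(degree_samples).items():
    print(f"log-rank {a} vs {b}: chi2={stat:.3f}, p={p:.3f}")

# The truncated power-law fitter, shown on degrees actually drawn from
# the model (brain-network-like parameters k=1.17, dc=10.5):
from scnkit import sample_truncated_powerlaw_degrees  # noqa: E402

d = sample_truncated_powerlaw_degrees(1.1687, 10.4879, 50, 100_000,
                                      seed=0)
fit = fit_truncated_powerlaw(d)
print(f"refit of sampled degrees: k={fit.k:.3f}, dc={fit.dc:.2f}, "
      f"r2={fit.r2:.4f}")
# All groups here share one generating law, so the log-rank p-values are
# large; on real data a small p flags a shifted degree distribution. The
# block-Gaussian synthetic cohort produces roughly binomial degrees, not
# a truncated power law, so the parametric fit is demonstrated on
# degrees sampled from the model itself, where it recovers k and dc to
# within about 1%.
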