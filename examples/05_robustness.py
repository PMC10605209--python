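"""Attack robustness: random failure versus degree-targeted removal.

Tracks the largest connected component while nodes are removed and
summarizes each curve by its AUC.
"""

from scnkit import (SyntheticSpec, correlation_network, generate_cohort,
                    random_failure, residualize, sparsity_grid,
                    targeted_attack, threshold_by_sparsity)

gmv, cov = generate_cohort(SyntheticSpec(seed=1))
res = residualize(gmv, cov)

net = correlation_network(res.subset("PWoSD"), "PWoSD")
g = threshold_by_sparsity(net, 0.19)

rand = random_failure(g, n_sim=1000, seed=0)
targ = targeted_attack(g)
print(f"density 0.19 ({g.edge_count} edges)")
print(f"  random failure  AUC {rand.auc:.4f} "
      f"(LCC {rand.lcc_relative_size[0]:.2f} -> "
      f"{rand.lcc_relative_size[45]:.2f} at half removed)")
print(f"  targeted attack AUC {targ.auc:.4f} "
      f"(LCC {targ.lcc_relative_size[0]:.2f} -> "
      f"{targ.lcc_relative_size[45]:.2f} at half removed)")
# Removing hubs first (targeted) fragments the network faster than
# random failure, so its AUC is lower; the gap widens with degree
# heterogeneity. A fragile clinical-group network shows smaller AUCs
# than controls under both attacks.
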