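"""Between-group permutation inference with AUC aggregation.

Compares two groups' clustering-coefficient curves with the relabeling
permutation test, including a null cohort pair where no true difference
exists and a cohort with an injected covariance difference.
"""

import numpy as np

from scnkit import (SyntheticSpec, generate_cohort, generate_null_pair,
                    permutation_test, residualize, sparsity_grid)

grid = sparsity_grid()

# no true difference: both groups share the generating law
spec = SyntheticSpec(n_subjects_per_group=30)
gmv, cov = generate_null_pair(spec, seed=3)
res = residualize(gmv, cov)
r = permutation_test(res.subset("null_A"), res.subset("null_B"),
                     "clustering", grid, n_perm=1000, seed=0)
print(f"null pair:      clustering AUC diff {r.observed_diff:+.4f}, "
      f"p = {r.p_two_tailed:.3f}")

# a real difference: one group gets stronger within-module covariance
spec_eff = SyntheticSpec(n_subjects_per_group=30,
                         group_effects=(("PWSD", 0.25, 0.0),))
gmv, cov = generate_cohort(spec_eff, seed=3)
res = residualize(gmv, cov)
r = permutation_test(res.subset("PWSD"), res.subset("HC"),
                     "clustering", grid, n_perm=1000, seed=0)
print(f"rho_in +0.25:   clustering AUC diff {r.observed_diff:+.4f}, "
      f"p = {r.p_two_tailed:.3f}")
print(f"per-density null envelope half-width at 0.19: "
      f"{(r.ci95_high[0] - r.ci95_low[0]) / 2:.4f}")
# The null pair's p is large (no difference to find); the perturbed
# cohort's tighter within-module correlations raise clustering across
# densities, giving a positive AUC difference outside the permutation
# envelope and a small p.
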