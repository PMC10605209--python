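"""Nonparametric permutation inference for between-group network differences.

Because group-level covariance networks have no per-subject replicates,
group differences are tested by relabeling: pooled (covariate-corrected)
subjects are repeatedly reassigned to two pseudo-groups of the original
sizes, the full pipeline (correlate → threshold across the density grid →
metric → trapezoidal AUC) is recomputed for each relabeling, and the
observed AUC difference is located in the resulting null distribution.
Per-density 95% null envelopes support difference-versus-density plots.
Nodal metrics are tested per region with Benjamini–Hochberg false
discovery rate correction across regions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from statsmodels.stats.multitest import multipletests

from .cohort import ResidualTable
from .metrics import NODAL_STATISTICS, resolve_statistic
from .netbuild import SparsityGrid, adjacency_stack, correlation_matrix, \
    sparsity_grid


@dataclass
class PermResult:
    """Outcome of one between-group permutation test."""

    statistic: str
    observed_diff: float            #: group A − group B AUC
    null_diffs: np.ndarray
    p_two_tailed: float
    n_perm: int
    grid: SparsityGrid
    observed_curve_a: np.ndarray
    observed_curve_b: np.ndarray
    ci95_low: np.ndarray            #: 2.5th pct of null per-density diff
    ci95_high: np.ndarray           #: 97.5th pct of null per-density diff
    exact: bool = False


def permute_groups(res_a: ResidualTable, res_b: ResidualTable,
                   seed: int | np.random.Generator | None = None
                   ) -> tuple[ResidualTable, ResidualTable]:
    """One random relabeling: pooled subjects split into the original sizes."""
    if res_a.region_labels != res_b.region_labels:
        raise ValueError("groups must share the same regions")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    values = np.vstack([res_a.values, res_b.values])
    ids = res_a.subject_ids + res_b.subject_ids
    na = res_a.n_subjects
    perm = rng.permutation(len(ids))
    pa, pb = perm[:na], perm[na:]
    return (
        ResidualTable(values[pa], tuple(ids[i] for i in pa),
                      res_a.region_labels),
        ResidualTable(values[pb], tuple(ids[i] for i in pb),
                      res_a.region_labels),
    )


def _statistic_curve(values: np.ndarray, grid: SparsityGrid, stat_fn,
                     ranking: str) -> np.ndarray:
    """correlate → threshold per density → scalar metric per density."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # permuted data may degenerate
        r = correlation_matrix(values)
    return np.array([stat_fn(a) for a in adjacency_stack(r, grid, ranking)])


def _grid_auc(vals: np.ndarray, x: np.ndarray) -> float:
    return float(np.trapezoid(vals, x))


def permutation_test(res_a: ResidualTable, res_b: ResidualTable,
                     statistic="clustering",
                     grid: SparsityGrid | None = None,
                     n_perm: int = 1000,
                     seed: int | np.random.Generator | None = None,
                     ranking: str = "signed",
                     exact: bool | None = None) -> PermResult:
    """Two-tailed permutation test of the AUC-summarized group difference.

    ``statistic`` is a registered global metric name (or any callable
    adjacency → scalar). Sampled mode computes
    ``p = (count(|null| ≥ |observed|) + 1)/(n_perm + 1)``, so p is never
    0 and never below 1/(n_perm+1). When ``exact=True`` — or the number
    of distinct splits does not exceed ``n_perm`` — every split is
    enumerated once and ``p = count(|null| ≥ |observed|)/n_splits``
    (the identity split counts itself, so p ≥ 1/n_splits).
    """
    if res_a.region_labels != res_b.region_labels:
        raise ValueError("groups must share the same regions")
    if grid is None:
        grid = sparsity_grid()
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives a coarse p-value grid",
                      stacklevel=2)
    stat_fn = resolve_statistic(statistic)
    name = statistic if isinstance(statistic, str) else \
        getattr(statistic, "__name__", "custom")
    x = grid.as_array()
    na, nb = res_a.n_subjects, res_b.n_subjects
    pooled = np.vstack([res_a.values, res_b.values])

    curve_a = _statistic_curve(res_a.values, grid, stat_fn, ranking)
    curve_b = _statistic_curve(res_b.values, grid, stat_fn, ranking)
    observed = _grid_auc(curve_a, x) - _grid_auc(curve_b, x)

    n_total = na + nb
    n_splits = math.comb(n_total, na)
    use_exact = exact if exact is not None else n_splits <= n_perm

    def split_diff(idx_a: np.ndarray) -> tuple[float, np.ndarray]:
        mask = np.zeros(n_total, dtype=bool)
        mask[idx_a] = True
        ca = _statistic_curve(pooled[mask], grid, stat_fn, ranking)
        cb = _statistic_curve(pooled[~mask], grid, stat_fn, ranking)
        return _grid_auc(ca, x) - _grid_auc(cb, x), ca - cb

    null = []
    density_diffs = []
    if use_exact:
        for comb in combinations(range(n_total), na):
            d, dd = split_diff(np.array(comb))
            null.append(d)
            density_diffs.append(dd)
        null = np.array(null)
        p = float((np.abs(null) >= abs(observed) - 1e-12).mean())
        n_used = len(null)
    else:
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        for _ in range(n_perm):
            perm = rng.permutation(n_total)
            d, dd = split_diff(perm[:na])
            null.append(d)
            density_diffs.append(dd)
        null = np.array(null)
        count = int((np.abs(null) >= abs(observed) - 1e-12).sum())
        p = (count + 1) / (n_perm + 1)
        n_used = n_perm
    density_diffs = np.array(density_diffs)
    lo, hi = np.percentile(density_diffs, [2.5, 97.5], axis=0)
    return PermResult(name, observed, null, float(p), n_used, grid,
                      curve_a, curve_b, lo, hi, exact=use_exact)


@dataclass
class NodalPermResult:
    """Per-region permutation p-values for one nodal metric."""

    statistic: str
    region_labels: tuple[str, ...]
    observed_diff: np.ndarray       #: per-region AUC difference (A − B)
    p_raw: np.ndarray
    p_fdr: np.ndarray
    n_perm: int


def permutation_test_nodal(res_a: ResidualTable, res_b: ResidualTable,
                           statistic: str = "degree",
                           grid: SparsityGrid | None = None,
                           n_perm: int = 1000,
                           seed=None, ranking: str = "signed"
                           ) -> NodalPermResult:
    """Region-wise permutation test with BH-FDR across regions.

    The per-region statistic is the AUC of the nodal metric across the
    density grid; raw two-tailed p-values use the +1 rule and are then
    FDR-adjusted over the regions.
    """
    if statistic not in NODAL_STATISTICS:
        raise ValueError(f"unknown nodal metric {statistic!r}; known: "
                         f"{sorted(NODAL_STATISTICS)}")
    fn = NODAL_STATISTICS[statistic]
    if grid is None:
        grid = sparsity_grid()
    x = grid.as_array()
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)

    def nodal_auc(values: np.ndarray) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = correlation_matrix(values)
        vals = np.array([fn(a) for a in adjacency_stack(r, grid, ranking)])
        return np.trapezoid(vals, x, axis=0)

    na = res_a.n_subjects
    pooled = np.vstack([res_a.values, res_b.values])
    observed = nodal_auc(res_a.values) - nodal_auc(res_b.values)
    count = np.zeros_like(observed)
    for _ in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        d = nodal_auc(pooled[perm[:na]]) - nodal_auc(pooled[perm[na:]])
        count += np.abs(d) >= np.abs(observed) - 1e-12
    p_raw = (count + 1) / (n_perm + 1)
    return NodalPermResult(statistic, res_a.region_labels, observed,
                           p_raw, fdr_correct(p_raw), n_perm)


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, ≤ 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def plot_difference_curve(result: PermResult, ax=None, labels=("A", "B")):
    """Difference vs density with dashed 95% permutation envelopes."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    x = result.grid.as_array()
    diff = result.observed_curve_a - result.observed_curve_b
    ax.plot(x, diff, "k*-", label=f"{labels[0]} − {labels[1]}")
    ax.plot(x, result.ci95_low, "b--", lw=1, label="95% null envelope")
    ax.plot(x, result.ci95_high, "b--", lw=1)
    ax.axhline(0.0, color="gray", lw=0.5)
    ax.set_xlabel("network density")
    ax.set_ylabel(f"Δ {result.statistic}")
    ax.set_title(f"AUC diff {result.observed_diff:+.4f}, "
                 f"p = {result.p_two_tailed:.3g}")
    ax.legend(fontsize=8)
    return ax
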