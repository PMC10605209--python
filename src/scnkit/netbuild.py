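"""Structural covariance network construction.

From a subjects × regions GMV table: (1) regress out nuisance covariates
(age, sex, total intracranial volume) per region by ordinary least
squares; (2) correlate residuals between every pair of regions across
subjects, giving a symmetric N×N Pearson matrix (the covariance network);
(3) binarize at a target sparsity — the fraction of possible edges kept —
by retaining the strongest correlations. Thresholding over a grid of
sparsities (0.19 to 0.49 in steps of 0.02) produces a nested sequence of
binary graphs on which all graph metrics are computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CovariateTable, GMVTable, ResidualTable

SPARSITY_MIN = 0.19
SPARSITY_MAX = 0.49
SPARSITY_STEP = 0.02


@dataclass(frozen=True)
class SparsityGrid:
    """The ordered network densities at which graphs are thresholded."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        v = self.values
        if len(v) < 1 or any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("grid must be non-empty and strictly increasing")
        if any(not 0 < s <= 1 for s in v):
            raise ValueError("densities must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def sparsity_grid(lo: float = SPARSITY_MIN, hi: float = SPARSITY_MAX,
                  step: float = SPARSITY_STEP) -> SparsityGrid:
    """Density grid built by integer indexing to avoid float drift.

    Defaults give the 16 densities 0.19, 0.21, …, 0.49.
    """
    n = int(round((hi - lo) / step)) + 1
    scale = 1_000_000
    lo_i, step_i = round(lo * scale), round(step * scale)
    return SparsityGrid(tuple((lo_i + i * step_i) / scale for i in range(n)))


@dataclass
class CovarianceNetwork:
    """Group-level Pearson correlation network R = [r_ij], diagonal zeroed."""

    weights: np.ndarray
    region_labels: tuple[str, ...]
    group_label: str = ""
    n_subjects: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if w.shape[0] != len(self.region_labels):
            raise ValueError("region_labels do not match matrix size")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.abs(np.diagonal(w)).max(initial=0.0) > 1e-12:
            raise ValueError("diagonal must be zero (no self-connections)")
        self.weights = w

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        labels = list(self.region_labels)
        return pd.DataFrame(self.weights, index=labels, columns=labels)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")


@dataclass
class BinaryGraph:
    """Undirected 0/1 adjacency at a given target sparsity."""

    adjacency: np.ndarray
    sparsity: float
    region_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.diagonal(a).any():
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        if not 0 < self.sparsity <= 1:
            raise ValueError("sparsity must lie in (0, 1]")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def edge_count(self) -> int:
        return int(self.adjacency.sum()) // 2

    def to_networkx(self):
        import networkx as nx
        g = nx.from_numpy_array(self.adjacency)
        return nx.relabel_nodes(
            g, dict(enumerate(self.region_labels)), copy=True)

    def to_edge_file(self, path) -> None:
        """BrainNet Viewer .edge dialect: N×N whitespace-separated matrix."""
        np.savetxt(path, self.adjacency, fmt="%d", delimiter="\t")


def residualize(gmv: GMVTable, cov: CovariateTable) -> ResidualTable:
    """Remove age, sex and TIV effects from each region by OLS.

    Each region is regressed (with intercept) on the three covariates
    independently; the residuals carry the inter-regional covariance that
    the network is built from. Regressors that are constant across
    subjects are dropped with a warning (they are absorbed by the
    intercept). Requires covariates for exactly the table's subjects.
    """
    cov = cov.reorder(gmv.subject_ids)
    n = gmv.n_subjects
    X = cov.design_matrix()
    keep = [0]
    for j, name in enumerate(("age", "sex", "tiv"), start=1):
        if np.ptp(X[:, j]) == 0:
            warnings.warn(f"covariate {name!r} is constant; dropped from "
                          "the design", stacklevel=2)
        else:
            keep.append(j)
    X = X[:, keep]
    if n <= X.shape[1]:
        raise ValueError(f"need more subjects ({n}) than regression "
                         f"coefficients ({X.shape[1]})")
    beta, *_ = np.linalg.lstsq(X, gmv.values, rcond=None)
    resid = gmv.values - X @ beta
    return ResidualTable(resid, gmv.subject_ids, gmv.region_labels,
                         gmv.group_labels)


def correlation_matrix(values: np.ndarray) -> np.ndarray:
    """Pairwise Pearson r between columns, diagonal zeroed.

    Zero-variance columns get correlation 0 with a warning.
    """
    values = np.asarray(values, dtype=float)
    sd = values.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance column(s); "
                      "their correlations are set to 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(values, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return r


def correlation_network(res: ResidualTable,
                        group_label: str = "") -> CovarianceNetwork:
    """Build the group-level covariance network from residualized GMV."""
    if res.n_subjects < 3:
        raise ValueError("need at least 3 subjects for a correlation network")
    r = correlation_matrix(res.values)
    return CovarianceNetwork(r, res.region_labels, group_label,
                             res.n_subjects)


def edge_count_for_sparsity(sparsity: float, n_nodes: int) -> int:
    """round-half-away-from-zero of sparsity · N(N−1)/2."""
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must lie in (0, 1]")
    return int(np.floor(sparsity * n_nodes * (n_nodes - 1) / 2 + 0.5))


def _edge_order(weights: np.ndarray, ranking: str) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle edge indices sorted strongest-first.

    ``ranking='signed'`` ranks by signed correlation (most positive
    first); ``'absolute'`` by |r|. Ties are broken by lexicographic
    region-pair index (stable sort), which makes thresholding
    reproducible and the edge sets nested across densities.
    """
    iu, ju = np.triu_indices(weights.shape[0], k=1)
    w = weights[iu, ju]
    if ranking == "absolute":
        w = np.abs(w)
    elif ranking != "signed":
        raise ValueError("ranking must be 'signed' or 'absolute'")
    order = np.argsort(-w, kind="stable")
    return iu[order], ju[order]


def threshold_by_sparsity(net: CovarianceNetwork, sparsity: float,
                          ranking: str = "signed") -> BinaryGraph:
    """Binarize the covariance network at a target density.

    Keeps exactly ``round(sparsity·N(N−1)/2)`` edges with the largest
    (signed, by default) correlations; all kept entries become 1.
    """
    n = net.n_regions
    m = edge_count_for_sparsity(sparsity, n)
    oi, oj = _edge_order(net.weights, ranking)
    adj = np.zeros((n, n), dtype=np.int8)
    adj[oi[:m], oj[:m]] = 1
    adj |= adj.T
    return BinaryGraph(adj, sparsity, net.region_labels)


def threshold_over_grid(net: CovarianceNetwork,
                        grid: SparsityGrid | None = None,
                        ranking: str = "signed") -> list[BinaryGraph]:
    """Binary graphs at every grid density (nested by construction)."""
    if grid is None:
        grid = sparsity_grid()
    n = net.n_regions
    oi, oj = _edge_order(net.weights, ranking)
    graphs = []
    adj = np.zeros((n, n), dtype=np.int8)
    prev = 0
    for s in grid:
        m = edge_count_for_sparsity(s, n)
        adj[oi[prev:m], oj[prev:m]] = 1
        adj[oj[prev:m], oi[prev:m]] = 1
        prev = max(prev, m)
        graphs.append(BinaryGraph(adj.copy(), s, net.region_labels))
    return graphs


def adjacency_stack(weights: np.ndarray, grid: SparsityGrid,
                    ranking: str = "signed") -> list[np.ndarray]:
    """Fast path: nested 0/1 adjacency arrays without container overhead.

    Used inside permutation loops where thousands of networks are
    thresholded; semantics identical to :func:`threshold_over_grid`.
    """
    n = weights.shape[0]
    oi, oj = _edge_order(weights, ranking)
    out = []
    adj = np.zeros((n, n), dtype=np.int8)
    prev = 0
    for s in grid:
        m = edge_count_for_sparsity(s, n)
        adj[oi[prev:m], oj[prev:m]] = 1
        adj[oj[prev:m], oi[prev:m]] = 1
        prev = max(prev, m)
        out.append(adj.copy())
    return out
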