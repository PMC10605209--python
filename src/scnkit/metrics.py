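"""Graph-theory metrics on binary networks.

Global measures: mean clustering coefficient (Cp), transitivity (T),
characteristic path length (Lp), global efficiency (Eglob), local
efficiency (Eloc), and the small-world index sigma = (Cp/Cp_rand)/(Lp/
Lp_rand) computed against an ensemble of degree-preserving rewired null
graphs (Maslov–Sneppen double-edge swaps). Nodal measures: degree,
betweenness centrality (normalized to [0, 1]), nodal efficiency and nodal
clustering.

Cp, T, distances and efficiencies are implemented as vectorized numpy
routines (triangle counts from A³, all-pairs distances by breadth-first
expansion with boolean matrix products) because they run inside
permutation loops; betweenness delegates to networkx's Brandes
implementation. Disconnected graphs are handled by averaging Lp over
reachable pairs only (the unreachable fraction is reported), while
efficiencies treat unreachable pairs as zero contribution natively.

A metric evaluated at every density of the sparsity grid forms a
``MetricCurve``, summarized by its trapezoidal area (AUC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numba
import numpy as np

from .netbuild import BinaryGraph, SparsityGrid


def _as_adjacency(g) -> np.ndarray:
    if isinstance(g, BinaryGraph):
        return np.asarray(g.adjacency, dtype=np.int8)
    return np.asarray(g, dtype=np.int8)


# ---------------------------------------------------------------- clustering

def clustering_and_transitivity(g) -> tuple[np.ndarray, float, float]:
    """Nodal clustering vector, its mean Cp, and transitivity T.

    Nodal clustering of node i = triangles_i / (k_i(k_i−1)/2), zero for
    degree < 2. T = 3·triangles / connected triples, a whole-graph ratio.
    """
    a = _as_adjacency(g).astype(float)
    deg = a.sum(axis=1)
    tri = np.einsum("ij,ji->i", a @ a, a) / 2.0   # closed 3-walks / 2
    pairs = deg * (deg - 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(pairs > 0, tri / pairs, 0.0)
    cp = float(c.mean()) if c.size else 0.0
    total_pairs = pairs.sum()
    t = float(tri.sum() / total_pairs) if total_pairs > 0 else 0.0
    return c, cp, t


# ----------------------------------------------------------------- distances

def shortest_path_lengths(g) -> np.ndarray:
    """All-pairs unweighted distances; ``inf`` for unreachable pairs.

    Breadth-first expansion with boolean matrix products: the frontier at
    step d is (frontier @ A) minus everything already visited.
    """
    a = _as_adjacency(g) > 0
    n = a.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    visited = np.eye(n, dtype=bool)
    frontier = visited
    d = 0
    while True:
        d += 1
        frontier = (frontier @ a) & ~visited
        if not frontier.any():
            return dist
        dist[frontier] = d
        visited |= frontier


def path_length_and_efficiency(g) -> tuple[float, float, np.ndarray, float]:
    """(Lp, Eglob, nodal efficiency vector, reachable-pair fraction).

    Lp is the mean distance over *reachable* ordered pairs; Eglob the
    mean of 1/distance over all ordered pairs (1/inf = 0); nodal
    efficiency of i is the mean inverse distance from i to every other
    node. An edgeless graph has Eglob = 0 and Lp = nan with reachable
    fraction 0.
    """
    dist = shortest_path_lengths(g)
    n = dist.shape[0]
    if n < 2:
        return float("nan"), 0.0, np.zeros(n), 0.0
    off = ~np.eye(n, dtype=bool)
    d_off = dist[off]
    finite = np.isfinite(d_off)
    frac = float(finite.mean())
    lp = float(d_off[finite].mean()) if finite.any() else float("nan")
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~off] = 0.0
    inv[np.isinf(dist)] = 0.0
    nodal_eff = inv.sum(axis=1) / (n - 1)
    eglob = float(nodal_eff.mean())
    return lp, eglob, nodal_eff, frac


def global_efficiency(g) -> float:
    return path_length_and_efficiency(g)[1]


def characteristic_path_length(g) -> float:
    return path_length_and_efficiency(g)[0]


def local_efficiency(g) -> tuple[float, np.ndarray]:
    """(Eloc, per-node vector): efficiency of each neighbor subgraph.

    A node's local efficiency is the global efficiency of the subgraph
    induced on its neighbors (0 with fewer than 2 neighbors); Eloc is the
    mean over all nodes.
    """
    a = _as_adjacency(g)
    n = a.shape[0]
    per_node = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(a[i])
        if nb.size < 2:
            continue
        per_node[i] = path_length_and_efficiency(a[np.ix_(nb, nb)])[1]
    return (float(per_node.mean()) if n else 0.0), per_node


def betweenness(g) -> np.ndarray:
    """Betweenness centrality, normalized so values lie in [0, 1].

    Fraction of shortest paths between other node pairs that pass
    through each node (Brandes' algorithm via networkx; the
    normalization divides by the number of such pairs, so any node of a
    complete graph scores 0 and the center of a star scores 1).
    """
    a = _as_adjacency(g)
    bc = nx.betweenness_centrality(nx.from_numpy_array(a), normalized=True)
    return np.array([bc[i] for i in range(a.shape[0])])


def degrees(g) -> np.ndarray:
    return _as_adjacency(g).sum(axis=1).astype(np.int64)


# --------------------------------------------------------------- small world

@numba.njit(cache=True)
def _swap_kernel(ei, ej, present, e1s, e2s, flips, accepted, n_swaps):
    """Apply a batch of double-edge-swap proposals in place.

    ``ei/ej`` are the current edge endpoints, ``present`` the boolean
    adjacency used for duplicate-edge checks. Returns the updated
    accepted count and how many proposals were consumed.
    """
    used = 0
    for idx in range(e1s.shape[0]):
        if accepted >= n_swaps:
            break
        used += 1
        e1 = e1s[idx]
        e2 = e2s[idx]
        if e1 == e2:
            continue
        a1, b1 = ei[e1], ej[e1]
        c1, d1 = ei[e2], ej[e2]
        if flips[idx]:
            c1, d1 = d1, c1
        # proposed edges (a1,d1) and (c1,b1)
        if a1 == d1 or c1 == b1:
            continue
        if present[a1, d1] or present[c1, b1]:
            continue
        present[a1, b1] = False
        present[b1, a1] = False
        present[c1, d1] = False
        present[d1, c1] = False
        present[a1, d1] = True
        present[d1, a1] = True
        present[c1, b1] = True
        present[b1, c1] = True
        if a1 < d1:
            ei[e1], ej[e1] = a1, d1
        else:
            ei[e1], ej[e1] = d1, a1
        if b1 < c1:
            ei[e2], ej[e2] = b1, c1
        else:
            ei[e2], ej[e2] = c1, b1
        accepted += 1
    return accepted, used


def rewire_degree_preserving(adj: np.ndarray, n_swaps: int,
                             rng: np.random.Generator,
                             max_tries: int | None = None) -> np.ndarray:
    """Maslov–Sneppen double-edge swaps; preserves every node's degree.

    Repeatedly picks two edges (a,b), (c,d) and rewires to (a,d), (c,b)
    when that creates neither self-loops nor duplicate edges, until
    ``n_swaps`` swaps are accepted or ``max_tries`` attempts are spent.
    Returns a new adjacency matrix; returns a copy unchanged if the graph
    has < 2 edges.
    """
    a = _as_adjacency(adj).copy()
    iu, ju = np.nonzero(np.triu(a, k=1))
    m = iu.size
    if m < 2 or n_swaps <= 0:
        return a
    ei = iu.astype(np.int64)
    ej = ju.astype(np.int64)
    if max_tries is None:
        max_tries = 20 * n_swaps
    present = (a > 0)
    tries = accepted = 0
    chunk = max(1024, min(4 * n_swaps, 1 << 18))
    while accepted < n_swaps and tries < max_tries:
        # draw proposals in bulk: the swap loop itself runs compiled
        budget = min(chunk, max_tries - tries)
        e1s = rng.integers(0, m, size=budget)
        e2s = rng.integers(0, m, size=budget)
        flips = rng.random(budget) < 0.5
        accepted, used = _swap_kernel(ei, ej, present, e1s, e2s, flips,
                                      accepted, n_swaps)
        tries += used
    a[:] = 0
    a[ei, ej] = 1
    a[ej, ei] = 1
    return a


@dataclass
class SmallWorldResult:
    gamma: float          #: Cp / mean null Cp
    lambda_: float        #: Lp / mean null Lp
    sigma: float          #: gamma / lambda_
    n_null: int


def small_world(g, n_null: int = 100,
                seed: int | np.random.Generator | None = None,
                swaps_per_edge: int = 10) -> SmallWorldResult:
    """Small-world index against degree-preserving rewired nulls.

    gamma = Cp/⟨Cp_null⟩, lambda = Lp/⟨Lp_null⟩, sigma = gamma/lambda;
    sigma > 1 indicates small-world organization (lattice-like clustering
    with random-like path lengths). Each null graph receives
    ``swaps_per_edge · |E|`` accepted double-edge swaps. Degree sequences
    that admit no rewiring (e.g. complete graphs) return gamma = lambda =
    sigma = 1 with a warning.
    """
    a = _as_adjacency(g)
    m = int(a.sum()) // 2
    if m < 1:
        raise ValueError("graph must have at least one edge")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    _, cp, _ = clustering_and_transitivity(a)
    lp = path_length_and_efficiency(a)[0]
    null_cp = np.empty(n_null)
    null_lp = np.empty(n_null)
    any_rewired = False
    for i in range(n_null):
        null = rewire_degree_preserving(a, swaps_per_edge * m, rng)
        if not np.array_equal(null, a):
            any_rewired = True
        _, null_cp[i], _ = clustering_and_transitivity(null)
        null_lp[i] = path_length_and_efficiency(null)[0]
    if not any_rewired:
        warnings.warn("degree sequence admits no rewiring; "
                      "gamma = lambda = sigma = 1", stacklevel=2)
        return SmallWorldResult(1.0, 1.0, 1.0, n_null)
    gamma = cp / null_cp.mean()
    lam = lp / np.nanmean(null_lp)
    return SmallWorldResult(float(gamma), float(lam),
                            float(gamma / lam), n_null)


# --------------------------------------------------------------- aggregates

@dataclass
class GlobalMetrics:
    """All global measures of one binary graph."""

    clustering_mean: float
    path_length: float
    transitivity: float
    global_efficiency: float
    local_efficiency: float
    gamma: float = float("nan")
    lambda_: float = float("nan")
    sigma: float = float("nan")
    reachable_fraction: float = 1.0


@dataclass
class NodalMetrics:
    """Per-node measures of one binary graph, keyed by region label."""

    region_labels: tuple[str, ...]
    degree: np.ndarray
    betweenness: np.ndarray
    nodal_efficiency: np.ndarray
    nodal_clustering: np.ndarray

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame(
            {"degree": self.degree, "betweenness": self.betweenness,
             "nodal_efficiency": self.nodal_efficiency,
             "nodal_clustering": self.nodal_clustering},
            index=pd.Index(self.region_labels, name="region"),
        )


def compute_global_metrics(g, n_null: int = 0,
                           seed=None) -> GlobalMetrics:
    """Evaluate every global metric; ``n_null > 0`` adds the small-world
    normalization (gamma, lambda, sigma)."""
    a = _as_adjacency(g)
    _, cp, t = clustering_and_transitivity(a)
    lp, eglob, _, frac = path_length_and_efficiency(a)
    eloc, _ = local_efficiency(a)
    gm = GlobalMetrics(cp, lp, t, eglob, eloc, reachable_fraction=frac)
    if n_null > 0:
        sw = small_world(a, n_null=n_null, seed=seed)
        gm.gamma, gm.lambda_, gm.sigma = sw.gamma, sw.lambda_, sw.sigma
    return gm


def compute_nodal_metrics(g: BinaryGraph) -> NodalMetrics:
    a = _as_adjacency(g)
    c, _, _ = clustering_and_transitivity(a)
    _, _, ne, _ = path_length_and_efficiency(a)
    return NodalMetrics(tuple(g.region_labels), degrees(a), betweenness(a),
                        ne, c)


#: Named scalar global statistics usable in curves and permutation tests.
GLOBAL_STATISTICS = {
    "clustering": lambda a: clustering_and_transitivity(a)[1],
    "transitivity": lambda a: clustering_and_transitivity(a)[2],
    "path_length": lambda a: path_length_and_efficiency(a)[0],
    "global_efficiency": lambda a: path_length_and_efficiency(a)[1],
    "local_efficiency": lambda a: local_efficiency(a)[0],
}

#: Named nodal (vector-valued) statistics.
NODAL_STATISTICS = {
    "degree": lambda a: degrees(a).astype(float),
    "betweenness": betweenness,
    "nodal_efficiency": lambda a: path_length_and_efficiency(a)[2],
    "nodal_clustering": lambda a: clustering_and_transitivity(a)[0],
}


def resolve_statistic(statistic):
    """Accept a registry name or a callable A → scalar."""
    if callable(statistic):
        return statistic
    try:
        return GLOBAL_STATISTICS[statistic]
    except KeyError:
        raise ValueError(
            f"unknown metric {statistic!r}; known: "
            f"{sorted(GLOBAL_STATISTICS)}") from None


@dataclass
class MetricCurve:
    """A global metric across the sparsity grid, with its AUC summary."""

    grid: SparsityGrid
    values: np.ndarray
    metric: str = ""
    auc: float = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.grid):
            raise ValueError("one value per grid density required")
        if len(self.grid) < 2:
            raise ValueError("AUC needs at least two densities")
        self.auc = float(np.trapezoid(self.values, self.grid.as_array()))


def metric_curve(graphs: list, statistic, grid: SparsityGrid) -> MetricCurve:
    """Evaluate a named global metric at each grid density."""
    if len(graphs) != len(grid):
        raise ValueError("one graph per grid density required")
    fn = resolve_statistic(statistic)
    vals = [fn(_as_adjacency(g)) for g in graphs]
    name = statistic if isinstance(statistic, str) else \
        getattr(statistic, "__name__", "custom")
    return MetricCurve(grid, np.array(vals), name)
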