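"""Network robustness under random failure and targeted attack.

Nodes are removed one at a time — uniformly at random (averaged over many
simulated removal orders) or in descending order of current degree
(recomputed after each removal, the adaptive protocol) — and the size of
the largest connected component (LCC), relative to the original node
count, is tracked as a function of the fraction of nodes removed. The
trapezoidal area under that curve summarizes robustness: fragile networks
collapse early and have small AUC.

Random-failure curves are computed by the reverse union-find trick: nodes
are *added* in reverse removal order while components are merged, which
costs nearly O(N + E) per simulation instead of recomputing components
after every removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .netbuild import BinaryGraph


def _as_adjacency(g) -> np.ndarray:
    if isinstance(g, BinaryGraph):
        return np.asarray(g.adjacency, dtype=np.int8)
    return np.asarray(g, dtype=np.int8)


@dataclass
class RobustnessCurve:
    """Relative LCC size after 0, 1, …, N−1 removals."""

    fractions_removed: np.ndarray
    lcc_relative_size: np.ndarray
    attack_type: str
    n_sim: int = 1
    auc: float = field(init=False)

    def __post_init__(self) -> None:
        self.fractions_removed = np.asarray(self.fractions_removed, float)
        self.lcc_relative_size = np.asarray(self.lcc_relative_size, float)
        if self.fractions_removed.shape != self.lcc_relative_size.shape:
            raise ValueError("curve arrays must have equal length")
        self.auc = float(np.trapezoid(self.lcc_relative_size,
                                      self.fractions_removed))


class _UnionFind:
    __slots__ = ("parent", "size", "max_size")

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.size = [1] * n
        self.max_size = 0

    def find(self, x: int) -> int:
        parent = self.parent
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    def union(self, x: int, y: int) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx == ry:
            return
        if self.size[rx] < self.size[ry]:
            rx, ry = ry, rx
        self.parent[ry] = rx
        self.size[rx] += self.size[ry]
        if self.size[rx] > self.max_size:
            self.max_size = self.size[rx]


def largest_component_size(g) -> int:
    """Node count of the largest connected component (0 for no nodes)."""
    a = _as_adjacency(g)
    n = a.shape[0]
    if n == 0:
        return 0
    uf = _UnionFind(n)
    uf.max_size = 1
    ii, jj = np.nonzero(np.triu(a, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        uf.union(i, j)
    return uf.max_size


def _lcc_after_removals(a: np.ndarray, order: np.ndarray,
                        neighbors: list[np.ndarray]) -> np.ndarray:
    """LCC size after m = 0..N−1 removals for one removal order.

    Adds nodes back in reverse order, merging components with union-find.
    """
    n = a.shape[0]
    lcc = np.empty(n, dtype=float)
    uf = _UnionFind(n)
    active = np.zeros(n, dtype=bool)
    for j in range(1, n + 1):
        v = int(order[n - j])
        active[v] = True
        for u in neighbors[v]:
            if active[u]:
                uf.union(v, int(u))
        # an isolated active node is itself a size-1 component
        lcc[n - j] = max(uf.max_size, 1)
    return lcc


def _neighbor_lists(a: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero(a[i]) for i in range(a.shape[0])]


def random_failure(g, n_sim: int = 1000,
                   seed: int | np.random.Generator | None = None
                   ) -> RobustnessCurve:
    """Average LCC decay over ``n_sim`` random removal orders."""
    if n_sim < 1:
        raise ValueError("n_sim must be at least 1")
    a = _as_adjacency(g)
    n = a.shape[0]
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    neighbors = _neighbor_lists(a)
    total = np.zeros(n)
    for _ in range(n_sim):
        order = rng.permutation(n)
        total += _lcc_after_removals(a, order, neighbors)
    fractions = np.arange(n) / n
    return RobustnessCurve(fractions, total / (n_sim * n), "random", n_sim)


def targeted_attack(g, adaptive: bool = True) -> RobustnessCurve:
    """LCC decay removing the highest-degree node at each step.

    With ``adaptive=True`` (default) degrees are recomputed after every
    removal; ``adaptive=False`` fixes the removal order by the original
    degrees. Ties go to the earlier region in label order (lowest node
    index). Deterministic.
    """
    a = _as_adjacency(g).copy()
    n = a.shape[0]
    static_deg = a.sum(axis=1)
    alive = np.ones(n, dtype=bool)
    order = np.empty(n, dtype=int)
    work = a.astype(np.int64)
    for step in range(n):
        deg = work.sum(axis=1) if adaptive else static_deg
        masked = np.where(alive, deg, -1)
        v = int(np.argmax(masked))   # argmax takes the first max: label order
        order[step] = v
        alive[v] = False
        if adaptive:
            work[v, :] = 0
            work[:, v] = 0
    neighbors = _neighbor_lists(a)
    lcc = _lcc_after_removals(a, order, neighbors)
    fractions = np.arange(n) / n
    return RobustnessCurve(fractions, lcc / n, "targeted", 1)


def robustness_auc(curve: RobustnessCurve) -> float:
    """Trapezoidal area of the LCC curve over the removal fraction."""
    return curve.auc
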