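"""Independent brute-force oracles for graph quantities on tiny graphs.

Everything here is deliberately naive — triple loops over node tuples,
Floyd–Warshall distances, explicit shortest-path counting — and shares no
code with the package implementation, so agreement is a genuine
cross-check.
"""

from itertools import combinations

import numpy as np


def fw_distances(a):
    """Floyd–Warshall all-pairs distances (inf when unreachable)."""
    n = len(a)
    d = np.full((n, n), np.inf)
    for i in range(n):
        d[i, i] = 0.0
        for j in range(n):
            if i != j and a[i][j]:
                d[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def nodal_clustering(a):
    n = len(a)
    out = []
    for i in range(n):
        nbrs = [j for j in range(n) if a[i][j]]
        k = len(nbrs)
        if k < 2:
            out.append(0.0)
            continue
        tri = sum(1 for x, y in combinations(nbrs, 2) if a[x][y])
        out.append(tri / (k * (k - 1) / 2))
    return np.array(out)


def transitivity(a):
    n = len(a)
    triangles = 0
    triples = 0
    for i in range(n):
        nbrs = [j for j in range(n) if a[i][j]]
        k = len(nbrs)
        triples += k * (k - 1) // 2
        triangles += sum(1 for x, y in combinations(nbrs, 2) if a[x][y])
    return triangles / triples if triples else 0.0


def path_stats(a):
    """(Lp over reachable pairs, Eglob, nodal efficiency vector)."""
    d = fw_distances(a)
    n = len(a)
    dists, invs = [], []
    nodal = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j in range(n):
            if i == j:
                continue
            if np.isfinite(d[i, j]):
                dists.append(d[i, j])
                invs.append(1.0 / d[i, j])
                acc += 1.0 / d[i, j]
            else:
                invs.append(0.0)
        nodal[i] = acc / (n - 1) if n > 1 else 0.0
    lp = float(np.mean(dists)) if dists else float("nan")
    eglob = float(np.mean(invs)) if invs else 0.0
    return lp, eglob, nodal


def local_efficiency(a):
    n = len(a)
    per = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if a[i][j]]
        if len(nbrs) < 2:
            continue
        sub = [[a[x][y] for y in nbrs] for x in nbrs]
        per[i] = path_stats(sub)[1]
    return float(per.mean()) if n else 0.0, per


def count_shortest_paths(a, s):
    """Number of shortest s→t paths for every t, with the distances."""
    d = fw_distances(a)
    n = len(a)
    counts = np.zeros(n)
    counts[s] = 1.0
    order = sorted(range(n), key=lambda v: d[s, v])
    for v in order:
        if v == s or not np.isfinite(d[s, v]):
            continue
        counts[v] = sum(counts[u] for u in range(n)
                        if a[u][v] and d[s, u] == d[s, v] - 1)
    return counts, d[s]


def betweenness(a):
    """Normalized betweenness: pair fraction averaged over the
    (n−1)(n−2)/2 unordered pairs excluding the node."""
    n = len(a)
    if n < 3:
        return np.zeros(n)
    d = fw_distances(a)
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s] = count_shortest_paths(a, s)[0]
    bc = np.zeros(n)
    for v in range(n):
        total = 0.0
        for s, t in combinations(range(n), 2):
            if v in (s, t) or not np.isfinite(d[s, t]) or sigma[s, t] == 0:
                continue
            if d[s, v] + d[v, t] == d[s, t]:
                total += sigma[s, v] * sigma[v, t] / sigma[s, t]
        bc[v] = total / ((n - 1) * (n - 2) / 2)
    return bc


def largest_component(a):
    n = len(a)
    seen = set()
    best = 0
    for start in range(n):
        if start in seen:
            continue
        stack = [start]
        comp = {start}
        while stack:
            v = stack.pop()
            for u in range(n):
                if a[v][u] and u not in comp:
                    comp.add(u)
                    stack.append(u)
        seen |= comp
        best = max(best, len(comp))
    return best
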