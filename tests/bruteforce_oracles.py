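"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: textbook formulas, double loops, and
BFS shortest-path counting, sharing no code with the package internals.
"""

from __future__ import annotations

import math
from collections import deque


def pearson_textbook(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def pearson_pvalue(r: float, n: int) -> float:
    """Two-sided p via the exact t relation (scipy only for the CDF)."""
    from scipy import stats

    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return 2 * stats.t.sf(abs(t), df=n - 2)


def bh_adjust(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up, written out longhand."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        value = pvalues[i] * m / (rank_from_top + 1)
        running_min = min(running_min, value)
        adjusted[i] = min(1.0, running_min)
    return adjusted


def bonferroni_adjust(pvalues: list[float]) -> list[float]:
    m = len(pvalues)
    return [min(1.0, p * m) for p in pvalues]


def network_edges_bruteforce(data, candidates, r_min: float, alpha: float):
    """Edge set by double loop: textbook Pearson, longhand BH, strict rules."""
    pairs, rs, ps = [], [], []
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            x = list(data[candidates[i]])
            y = list(data[candidates[j]])
            if len(set(x)) == 1 or len(set(y)) == 1:
                continue
            r = pearson_textbook(x, y)
            pairs.append((candidates[i], candidates[j]))
            rs.append(r)
            ps.append(pearson_pvalue(r, len(x)))
    adj = bh_adjust(ps)
    return {
        frozenset(pair): (r, q)
        for pair, r, q in zip(pairs, rs, adj)
        if abs(r) > r_min and q < alpha
    }


def bfs_distances(adj: dict[int, set[int]], source: int) -> dict[int, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                queue.append(w)
    return dist


def centralities_bruteforce(n: int, edges: list[tuple[int, int]]):
    """Degree, harmonic closeness / (n-1), normalized betweenness by
    explicit shortest-path enumeration."""
    adj = {v: set() for v in range(n)}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    degree = [len(adj[v]) for v in range(n)]

    closeness = []
    for v in range(n):
        dist = bfs_distances(adj, v)
        closeness.append(sum(1.0 / d for u, d in dist.items() if u != v) / (n - 1))

    # betweenness: enumerate all shortest paths between every ordered pair
    # by DFS over the BFS distance structure
    between = [0.0] * n
    for s in range(n):
        dist = bfs_distances(adj, s)
        for t in range(n):
            if t == s or t not in dist:
                continue
            paths: list[list[int]] = []

            def extend(path):
                v = path[-1]
                if v == t:
                    paths.append(path)
                    return
                for w in adj[v]:
                    if w in dist and dist[w] == dist[v] + 1:
                        extend(path + [w])

            extend([s])
            for path in paths:
                for inner in path[1:-1]:
                    between[inner] += 1.0 / len(paths)
    scale = (n - 1) * (n - 2)  # ordered pairs; nx normalizes undirected by /2 then 2/
    between = [b / scale for b in between]
    return degree, closeness, between
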