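"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (and, where possible, the libraries)
they verify: exact combinatorial enumeration for Fisher/hypergeometric
probabilities, exhaustive shortest-path enumeration for betweenness, and a
direct cross-pair recomputation for agglomerative linkage heights.
"""

from itertools import combinations, permutations
from math import comb


def fisher_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration over tables with fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    denom = comb(r1 + r2, c1)

    def prob(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / denom

    pobs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= pobs * (1 + 1e-7))


def hypergeom_upper_enum(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by direct summation of hypergeometric point masses."""
    denom = comb(N, n)
    hi = min(K, n)
    return sum(comb(K, i) * comb(N - K, n - i) / denom for i in range(k, hi + 1))


def betweenness_enum(nodes, edges) -> dict:
    """Unnormalized betweenness by exhaustive simple-path enumeration.

    For every unordered pair (s, t), enumerate all simple paths, keep the
    shortest ones, and credit each interior node with its fraction of them.
    Exponential; fine for graphs of <= 8 nodes.
    """
    nodes = list(nodes)
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)

    def all_simple_paths(s, t):
        paths, stack = [], [(s, [s])]
        while stack:
            v, path = stack.pop()
            if v == t:
                paths.append(path)
                continue
            for w in adj[v]:
                if w not in path:
                    stack.append((w, path + [w]))
        return paths

    bc = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        paths = all_simple_paths(s, t)
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        geodesics = [p for p in paths if len(p) == shortest]
        for p in geodesics:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(geodesics)
    return bc


def average_linkage_heights(D) -> list:
    """Merge heights of UPGMA clustering recomputed from raw cross-pairs."""
    import numpy as np

    D = np.asarray(D, dtype=float)
    clusters = [frozenset([i]) for i in range(D.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(clusters, 2):
            d = float(np.mean([D[i, j] for i in a for j in b]))
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    return heights
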