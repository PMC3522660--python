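"""Independent brute-force oracles shared across the test suite."""

import itertools

import mitopool as mp
from mitopool.pool_design import PairEvidence


def matrix_from_adjacency(adj):
    """CompatibilityMatrix from a boolean adjacency array (test helper)."""
    n = len(adj)
    ids = [f"n{i:02d}" for i in range(n)]
    evidence, compatible = {}, {}
    for i, j in itertools.combinations(range(n), 2):
        key = frozenset((ids[i], ids[j]))
        comp = bool(adj[i][j])
        evidence[key] = PairEvidence(coi_proxy=0.30 if comp else 0.05)
        compatible[key] = comp
    return mp.CompatibilityMatrix(ids, evidence, compatible, mp.CompatPolicy())


def brute_max_clique(adj):
    """Exhaustive maximum clique with the lexicographic tie-break."""
    n = len(adj)
    masks = [sum(1 << j for j in range(n) if adj[i][j]) for i in range(n)]
    best = []
    for s in range(1 << n):
        members = [i for i in range(n) if s >> i & 1]
        if all((masks[i] | 1 << i) & s == s for i in members):
            names = [f"n{i:02d}" for i in members]
            if len(names) > len(best) or (len(names) == len(best) and names < best):
                best = names
    return best


def brute_chromatic(adj_incompatible):
    """Exact chromatic number by backtracking over k = 1..n colours."""
    n = len(adj_incompatible)
    neighbours = [
        [j for j in range(n) if adj_incompatible[i][j]] for i in range(n)
    ]
    for k in range(1, n + 1):
        colors = [-1] * n

        def solve(v):
            if v == n:
                return True
            for c in range(k):
                if all(colors[u] != c for u in neighbours[v]):
                    colors[v] = c
                    if solve(v + 1):
                        return True
                    colors[v] = -1
            return False

        if solve(0):
            return k
    return n
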