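"""Independent brute-force oracles used to verify the implementation.

Everything here deliberately avoids the package's own code paths: plain
loops, exhaustive enumeration and textbook dynamic programming.
"""

from __future__ import annotations

import itertools
import math

from Bio.Align import substitution_matrices

BLOSUM62 = substitution_matrices.load("BLOSUM62")
GAP_OPEN = -10.0
GAP_EXTEND = -0.5


# ---------------------------------------------------------------------------
# Global alignment
# ---------------------------------------------------------------------------

def gotoh_score(a: str, b: str) -> float:
    """Affine-gap global alignment score by the three-matrix recursion."""
    n, m = len(a), len(b)
    neg = float("-inf")
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (b consumed)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = GAP_OPEN + GAP_EXTEND * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = GAP_OPEN + GAP_EXTEND * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = BLOSUM62[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1],
                          Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + GAP_OPEN, X[i - 1][j] + GAP_EXTEND,
                          Y[i - 1][j] + GAP_OPEN)
            Y[i][j] = max(M[i][j - 1] + GAP_OPEN, Y[i][j - 1] + GAP_EXTEND,
                          X[i][j - 1] + GAP_OPEN)
    return max(M[n][m], X[n][m], Y[n][m])


def enumerate_alignment_score(a: str, b: str) -> float:
    """Optimal score by exhaustive enumeration of all alignments (tiny
    strings only); validates the DP oracle itself."""
    best = float("-inf")

    def rec(i: int, j: int, score: float, state: str) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + BLOSUM62[a[i], b[j]], "m")
        if i < len(a):
            cost = GAP_EXTEND if state == "x" else GAP_OPEN
            rec(i + 1, j, score + cost, "x")
        if j < len(b):
            cost = GAP_EXTEND if state == "y" else GAP_OPEN
            rec(i, j + 1, score + cost, "y")

    rec(0, 0, 0.0, "m")
    return best


# ---------------------------------------------------------------------------
# Column statistics
# ---------------------------------------------------------------------------

def kl_bits(p: dict[str, float], q: dict[str, float]) -> float:
    return sum(
        pv * math.log2(pv / q[k]) for k, pv in p.items() if pv > 0
    )


def jsd_bits(p: dict[str, float], q: dict[str, float]) -> float:
    keys = set(p) | set(q)
    r = {k: 0.5 * (p.get(k, 0.0) + q.get(k, 0.0)) for k in keys}
    return 0.5 * kl_bits(p, r) + 0.5 * kl_bits(q, r)


def mi_bits(col_i: str, col_j: str) -> float:
    """Mutual information over rows where both symbols are amino acids."""
    pairs = [
        (x, y) for x, y in zip(col_i, col_j)
        if x.isalpha() and y.isalpha() and x != "X" and y != "X"
    ]
    n = len(pairs)
    if n < 2:
        return 0.0
    from collections import Counter
    joint = Counter(pairs)
    px = Counter(x for x, _ in pairs)
    py = Counter(y for _, y in pairs)
    mi = 0.0
    for (x, y), c in joint.items():
        mi += (c / n) * math.log2((c / n) / ((px[x] / n) * (py[y] / n)))
    return mi


def omes(col_i: str, col_j: str) -> float:
    pairs = [
        (x, y) for x, y in zip(col_i, col_j)
        if x.isalpha() and y.isalpha() and x != "X" and y != "X"
    ]
    n = len(pairs)
    if n < 2:
        return 0.0
    from collections import Counter
    joint = Counter(pairs)
    nx = Counter(x for x, _ in pairs)
    ny = Counter(y for _, y in pairs)
    total = 0.0
    for x in nx:
        for y in ny:
            obs = joint.get((x, y), 0)
            exp = nx[x] * ny[y] / n
            total += (obs - exp) ** 2 / n
    return total


def mcbasc(col_i: str, col_j: str, table) -> float:
    """Pearson correlation of substitution scores over sequence pairs."""
    rows = [
        k for k in range(len(col_i))
        if col_i[k].isalpha() and col_j[k].isalpha()
        and col_i[k] != "X" and col_j[k] != "X"
    ]
    if len(rows) < 2:
        return 0.0
    si, sj = [], []
    for k, l in itertools.combinations(rows, 2):
        si.append(float(table[col_i[k], col_i[l]]))
        sj.append(float(table[col_j[k], col_j[l]]))
    mean_i = sum(si) / len(si)
    mean_j = sum(sj) / len(sj)
    var_i = sum((v - mean_i) ** 2 for v in si)
    var_j = sum((v - mean_j) ** 2 for v in sj)
    if var_i == 0 or var_j == 0:
        return 0.0
    cov = sum((u - mean_i) * (v - mean_j) for u, v in zip(si, sj))
    return cov / math.sqrt(var_i * var_j)


def apc(matrix) -> list[list[float]]:
    n = len(matrix)
    mean_i = [
        sum(matrix[i][j] for j in range(n) if j != i) / (n - 1)
        for i in range(n)
    ]
    mean_all = sum(
        matrix[i][j] for i in range(n) for j in range(n) if i != j
    ) / (n * (n - 1))
    out = [
        [
            0.0 if i == j else matrix[i][j] - mean_i[i] * mean_i[j] / mean_all
            for j in range(n)
        ]
        for i in range(n)
    ]
    return out


# ---------------------------------------------------------------------------
# Cliques and designs
# ---------------------------------------------------------------------------

def brute_force_maximal_cliques(n: int, edges: set[frozenset]) -> set[frozenset]:
    """All maximal cliques of a graph on nodes 0..n-1 by 2^n enumeration."""
    adj = [0] * n
    for e in edges:
        a, b = tuple(e)
        adj[a] |= 1 << b
        adj[b] |= 1 << a
    cliques = set()
    for s in range(1, 1 << n):
        members = [v for v in range(n) if s >> v & 1]
        if any((adj[v] & s) != s ^ (1 << v) for v in members):
            continue
        # maximal: no outside vertex adjacent to all members
        if any((adj[u] & s) == s for u in range(n) if not s >> u & 1):
            continue
        cliques.add(frozenset(members))
    return cliques


def exhaustive_best_design(mutations, singles, edge_ok):
    """Best mutation subset by full enumeration.

    Valid subsets have pairwise-distinct positions and every pair accepted
    by ``edge_ok``; ranking is (sum of singles, larger size, lexicographic
    positions) — identical to the selection contract.
    """
    best_key = None
    best_set = ()
    for r in range(len(mutations) + 1):
        for combo in itertools.combinations(mutations, r):
            positions = [(m.chain, m.position) for m in combo]
            if len(set(positions)) != len(positions):
                continue
            if any(
                not edge_ok(a, b)
                for a, b in itertools.combinations(combo, 2)
            ):
                continue
            total = sum(singles[m] for m in combo)
            key = (total, -len(combo),
                   tuple(sorted((m.chain, m.position, m.mut) for m in combo)))
            if best_key is None or key < best_key:
                best_key = key
                best_set = tuple(sorted(
                    combo, key=lambda m: (m.chain, m.position, m.mut)
                ))
    return best_set, (best_key[0] if best_key else 0.0)
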