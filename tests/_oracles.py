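"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives a quantity by the most literal route available —
union-find for connected components, a plain Gotoh dynamic program for local
alignment, an explicit projection + eigendecomposition for constrained
ordination, exhaustive enumeration for the rank-sum null — so agreement with
the package is a genuine cross-check, not a tautology.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from Bio.Align import substitution_matrices


# ---------------------------------------------------------------------------
# union-find connected components


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def union_find_partition(nodes, edges):
    """Components of size >= 2 (as a set of frozensets) plus singleton set."""
    uf = UnionFind(nodes)
    for a, b in edges:
        uf.union(a, b)
    groups: dict = {}
    for x in nodes:
        groups.setdefault(uf.find(x), set()).add(x)
    clusters = {frozenset(g) for g in groups.values() if len(g) >= 2}
    singletons = {next(iter(g)) for g in groups.values() if len(g) == 1}
    return clusters, singletons


# ---------------------------------------------------------------------------
# Gotoh local alignment (affine gaps, BLOSUM62-style matrix)


def gotoh_local(seq_a: str, seq_b: str, matrix_name="BLOSUM62",
                gap_open=11.0, gap_extend=1.0):
    """Brute-force local alignment DP with affine gap cost open + extend*L.

    Returns (score, pident, cov_a, cov_b) of the best local alignment, or
    None when the optimal score is <= 0.  Traceback is deterministic with
    preference diagonal > gap-in-b > gap-in-a on ties.
    """
    mat = substitution_matrices.load(matrix_name)
    la, lb = len(seq_a), len(seq_b)
    NEG = -1e18
    M = np.full((la + 1, lb + 1), 0.0)
    Ix = np.full((la + 1, lb + 1), NEG)  # gap in seq_b (consume a)
    Iy = np.full((la + 1, lb + 1), NEG)  # gap in seq_a (consume b)
    best, best_pos = 0.0, None
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = mat[seq_a[i - 1]][seq_b[j - 1]]
            m = max(0.0, M[i - 1][j - 1] + s, Ix[i - 1][j - 1] + s,
                    Iy[i - 1][j - 1] + s)
            M[i][j] = m
            Ix[i][j] = max(M[i - 1][j] - gap_open - gap_extend,
                           Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - gap_open - gap_extend,
                           Iy[i][j - 1] - gap_extend)
            if m > best:
                best, best_pos = m, (i, j)
    if best <= 0 or best_pos is None:
        return None
    # traceback from the best cell in state M
    i, j = best_pos
    state = "M"
    identities = columns = 0
    while True:
        if state == "M":
            if M[i][j] == 0:
                break
            s = mat[seq_a[i - 1]][seq_b[j - 1]]
            columns += 1
            if seq_a[i - 1] == seq_b[j - 1]:
                identities += 1
            prev = M[i][j] - s
            if abs(M[i - 1][j - 1] - prev) < 1e-9 or abs(prev) < 1e-9:
                state = "M"
            elif abs(Ix[i - 1][j - 1] - prev) < 1e-9:
                state = "X"
            else:
                state = "Y"
            i, j = i - 1, j - 1
            if i == 0 or j == 0:
                break
        elif state == "X":
            columns += 1
            if abs(M[i - 1][j] - gap_open - gap_extend - Ix[i][j]) < 1e-9:
                state = "M"
            i = i - 1
            if i == 0:
                break
        else:
            columns += 1
            if abs(M[i][j - 1] - gap_open - gap_extend - Iy[i][j]) < 1e-9:
                state = "M"
            j = j - 1
            if j == 0:
                break
    return (
        best,
        100.0 * identities / columns,
        min(100.0, 100.0 * columns / la),
        min(100.0, 100.0 * columns / lb),
    )


# ---------------------------------------------------------------------------
# constrained correspondence analysis via explicit eigendecomposition


def cca_eigen_oracle(Y: np.ndarray, X: np.ndarray):
    """Eigenvalues + inertias of CCA by forming the weighted projection
    explicitly and solving the symmetric eigenproblem of the fitted
    cross-product (independent route from the package's lstsq + SVD)."""
    total = Y.sum()
    P = Y / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    Q = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    Xc = X - r @ X
    Xw = np.sqrt(r)[:, None] * Xc
    H = Xw @ np.linalg.pinv(Xw.T @ Xw) @ Xw.T
    Qfit = H @ Q
    S = Qfit @ Qfit.T
    eig = np.linalg.eigvalsh(S)[::-1]
    eig = eig[eig > 1e-12]
    return eig, float((Q**2).sum()), float((Qfit**2).sum())


# ---------------------------------------------------------------------------
# exact rank-sum null by enumeration


def exact_ranksum_pvalue(x, y):
    """Two-sided rank-sum p-value by full enumeration of group assignments
    (midranks for ties)."""
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1 = len(x)
    observed = ranks[:n1].sum()
    sums = [sum(ranks[list(idx)]) for idx in combinations(range(len(pooled)), n1)]
    sums = np.array(sums)
    mean = sums.mean()
    # two-sided: as-or-more-extreme deviation from the null mean
    p = np.mean(np.abs(sums - mean) >= np.abs(observed - mean) - 1e-9)
    return float(p)
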