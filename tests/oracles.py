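"""Independent brute-force oracles used to verify the production recursions.

Everything here is deliberately written with a different algorithmic strategy
from the package: exhaustive DFS path enumeration, Wright's path-counting
formula over common ancestors, the dense tabular relationship matrix, and a
top-down pairwise partial-kinship recursion.  Slow and simple on purpose;
intended for pedigrees of a few dozen individuals.
"""

from __future__ import annotations

from functools import lru_cache

from purgekit.pedigree import Pedigree, UNKNOWN_IDX


def all_paths_up(ped: Pedigree, i: int, j: int) -> list[list[int]]:
    """Every chain of parent links from i up to j, by exhaustive DFS."""
    out: list[list[int]] = []

    def dfs(node, trail):
        if node == j:
            out.append(trail)
            return
        for p in (ped.sire_idx[node], ped.dam_idx[node]):
            if p != UNKNOWN_IDX:
                dfs(p, trail + [p])

    if i == j:
        return []
    dfs(i, [i])
    return out


def paths_to_all_ancestors(ped: Pedigree, i: int) -> dict[int, list[list[int]]]:
    """Paths from i up to every ancestor, keyed by ancestor index.

    The trivial path [i] to itself is included (generation distance 0), which
    is what Wright's formula needs when a parent is itself a common ancestor.
    """
    found: dict[int, list[list[int]]] = {}

    def dfs(node, trail):
        found.setdefault(node, []).append(trail)
        for p in (ped.sire_idx[node], ped.dam_idx[node]):
            if p != UNKNOWN_IDX:
                dfs(p, trail + [p])

    dfs(i, [i])
    return found


def wright_F(ped: Pedigree) -> list[float]:
    """Wright's path-counting inbreeding: F = sum (1/2)^(n1+n2+1) (1 + F_A).

    Summed over every common ancestor A of the parents and every pair of
    parent-to-A paths that share no individual except A; n1, n2 are the
    generation counts (links) of the two paths.
    """

    @lru_cache(maxsize=None)
    def F_of(idx: int) -> float:
        s, d = ped.sire_idx[idx], ped.dam_idx[idx]
        if s == UNKNOWN_IDX or d == UNKNOWN_IDX:
            return 0.0
        sp = paths_to_all_ancestors(ped, s)
        dp = paths_to_all_ancestors(ped, d)
        total = 0.0
        for a, s_paths in sp.items():
            if a not in dp:
                continue
            fa = F_of(a)
            for p1 in s_paths:
                set1 = set(p1) - {a}
                for p2 in dp[a]:
                    if set1 & (set(p2) - {a}):
                        continue  # paths must be disjoint except at A
                    n1, n2 = len(p1) - 1, len(p2) - 1
                    total += 0.5 ** (n1 + n2 + 1) * (1.0 + fa)
        return total

    return [F_of(i) for i in range(ped.n)]


def tabular_relationship(ped: Pedigree) -> list[list[float]]:
    """Dense additive-relationship matrix by the classic tabular method.

    a[i][i] = 1 + F_i; kinship(i, j) = a[i][j] / 2.
    """
    n = ped.n
    a = [[0.0] * n for _ in range(n)]
    for i in range(n):
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        for j in range(i):
            v = 0.0
            if s != UNKNOWN_IDX:
                v += 0.5 * a[s][j]
            if d != UNKNOWN_IDX:
                v += 0.5 * a[d][j]
            a[i][j] = a[j][i] = v
        self_extra = 0.5 * a[s][d] if (s != UNKNOWN_IDX and d != UNKNOWN_IDX) else 0.0
        a[i][i] = 1.0 + self_extra
    return a


def tabular_F(ped: Pedigree) -> list[float]:
    a = tabular_relationship(ped)
    return [a[i][i] - 1.0 for i in range(ped.n)]


def partial_F_oracle(ped: Pedigree, j: int) -> list[float]:
    """Top-down pairwise recursion for F_i(j), independent of the bottom-up kernel.

    phi(x, y) is the probability that an allele drawn from x and one drawn
    from y are IBD copies of the allele labels originating in j; descent(x) is
    the probability a random allele of x descends from those labels.
    """
    F = tabular_F(ped)

    @lru_cache(maxsize=None)
    def descent(x: int) -> float:
        if x == j:
            return 1.0
        acc = 0.0
        for p in (ped.sire_idx[x], ped.dam_idx[x]):
            if p != UNKNOWN_IDX:
                acc += 0.5 * descent(p)
        return acc

    @lru_cache(maxsize=None)
    def phi(x: int, y: int) -> float:
        if x == UNKNOWN_IDX or y == UNKNOWN_IDX:
            return 0.0
        if descent(x) == 0.0 or descent(y) == 0.0:
            return 0.0
        if x == j and y == j:
            return 0.5 * (1.0 + F[j])
        # expand the individual further down the pedigree; never expand j
        if x == j or (y != j and y > x):
            x, y = y, x
        if x == y:
            base = phi(ped.sire_idx[x], ped.dam_idx[x])
            return 0.5 * (descent(x) + base)
        return 0.5 * (phi(ped.sire_idx[x], y) + phi(ped.dam_idx[x], y))

    out = []
    for i in range(ped.n):
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        if i <= j or s == UNKNOWN_IDX or d == UNKNOWN_IDX:
            out.append(0.0)
        else:
            out.append(phi(s, d))
    return out


def brute_opportunity(ped: Pedigree) -> tuple[list[float], list[float]]:
    """O_raw and Oe_raw by exhaustive per-ancestor, per-path summation."""
    F = tabular_F(ped)
    n = ped.n
    partial = {j: partial_F_oracle(ped, j) for j in range(n) if F[j] > 0.0}
    O = [0.0] * n
    Oe = [0.0] * n
    for i in range(n):
        for j in range(n):
            if j == i or F[j] <= 0.0:
                continue
            paths = all_paths_up(ped, i, j)
            for p in paths:
                O[i] += 0.5 ** (len(p) - 1) * F[j]
            if paths:
                Oe[i] += 2.0 * partial[j][i] * F[j]
    return O, Oe
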