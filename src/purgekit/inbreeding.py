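"""Inbreeding coefficients on pedigrees.

* Wright's ``F`` — probability the two alleles of an individual at a neutral
  locus are identical by descent (IBD); equals the kinship of its parents.
* Ancestral inbreeding ``Fa`` — probability a random allele carried by an
  individual has already been exposed in IBD homozygosity in at least one of
  its ancestors (Ballou-type recursion).
* Partial inbreeding ``F_i(j)`` — probability that individual ``i`` is
  autozygous *for alleles derived from ancestor* ``j``.  The two alleles
  present in ``j`` are taken as the origin labels; autozygosity from ``j``
  means both of ``i``'s alleles are copies of the same label, or copies of the
  two distinct labels when those are themselves IBD (probability ``F_j``).
  Summed over founders, ``F_i(j)`` partitions ``F_i``.
* A seedable gene-dropping Monte Carlo engine that estimates all three by
  simulating Mendelian transmission of labelled alleles; it serves as an
  independent oracle for the exact recursions.

All functions require a sorted pedigree (parents before offspring).  An
unknown parent behaves as an unrelated, non-inbred founder line.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .pedigree import Pedigree, UNKNOWN_IDX


# ---------------------------------------------------------------------------
# kinship and F
# ---------------------------------------------------------------------------
class KinshipCalculator:
    """Memoized recursive kinship on a sorted pedigree.

    kinship(x, x) = (1 + F_x) / 2; for x != y the individual with the larger
    position is expanded into its parents; unknown parents contribute 0.
    """

    def __init__(self, ped: Pedigree):
        ped.require_sorted()
        self.ped = ped
        self._memo: dict[tuple[int, int], float] = {}

    def kinship_idx(self, x: int, y: int) -> float:
        if x == UNKNOWN_IDX or y == UNKNOWN_IDX:
            return 0.0
        if x < y:
            x, y = y, x
        key = (x, y)
        memo = self._memo
        hit = memo.get(key)
        if hit is not None:
            return hit
        sire, dam = self.ped.sire_idx, self.ped.dam_idx
        if x == y:
            val = 0.5 * (1.0 + self.kinship_idx(sire[x], dam[x]))
        else:
            s, d = sire[x], dam[x]
            val = 0.0
            if s != UNKNOWN_IDX:
                val += 0.5 * self.kinship_idx(s, y)
            if d != UNKNOWN_IDX:
                val += 0.5 * self.kinship_idx(d, y)
        memo[key] = val
        return val

    def kinship(self, a: str, b: str) -> float:
        return self.kinship_idx(self.ped.position(a), self.ped.position(b))

    def inbreeding(self) -> np.ndarray:
        """F for every individual, in pedigree order."""
        sire, dam = self.ped.sire_idx, self.ped.dam_idx
        return np.array(
            [self.kinship_idx(sire[i], dam[i]) for i in range(self.ped.n)]
        )


def compute_kinship(
    ped: Pedigree, pairs: Iterable[tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Pairwise kinship for the given id pairs (default: all parent pairs)."""
    calc = KinshipCalculator(ped)
    if pairs is None:
        ids = ped.ids
        pairs = [
            (ids[i], ids[i])
            for i in range(ped.n)
        ]
    rows = [(a, b, calc.kinship(a, b)) for a, b in pairs]
    return pd.DataFrame(rows, columns=["a", "b", "kinship"])


def compute_F(ped: Pedigree) -> np.ndarray:
    """Wright's inbreeding coefficient per individual (pedigree order)."""
    return KinshipCalculator(ped).inbreeding()


def compute_Fa(ped: Pedigree, F: np.ndarray | None = None) -> np.ndarray:
    """Ancestral inbreeding per individual (Ballou's recursion).

    Fa_i = 1/2 * [Fa_s + (1 - Fa_s) F_s + Fa_d + (1 - Fa_d) F_d], an unknown
    parent contributing 0 to its half.  The recursion treats a parent's own
    inbreeding and its ancestral exposure as independent events; the
    gene-dropping engine estimates the exact probability, and the two agree
    closely except in long closed lines that are inbred every generation.
    """
    ped.require_sorted()
    if F is None:
        F = compute_F(ped)
    n = ped.n
    Fa = np.zeros(n)
    sire, dam = ped.sire_idx, ped.dam_idx
    for i in range(n):
        acc = 0.0
        for p in (sire[i], dam[i]):
            if p != UNKNOWN_IDX:
                acc += Fa[p] + (1.0 - Fa[p]) * F[p]
        Fa[i] = 0.5 * acc
    return Fa


# ---------------------------------------------------------------------------
# partial inbreeding F_i(j)
# ---------------------------------------------------------------------------
@njit(cache=False)
def _partial_F_kernel(sire, dam, F, anc_idx, phi, a, out):  # pragma: no cover - jitted
    """Fill out[i, jj] = F_i(anc_idx[jj]) by a label-at-j kinship recursion.

    phi is an (n, n) scratch matrix, a an (n,) scratch vector.  Entries are
    only read where the single-allele descent probability ``a`` is positive,
    so no per-ancestor zero fill is needed.
    """
    n = sire.shape[0]
    for jj in range(anc_idx.shape[0]):
        j = anc_idx[jj]
        for k in range(n):
            a[k] = 0.0
        a[j] = 1.0
        phi[j, j] = 0.5 * (1.0 + F[j])
        for x in range(j + 1, n):
            s = sire[x]
            d = dam[x]
            ax = 0.0
            if s >= 0:
                ax += 0.5 * a[s]
            if d >= 0:
                ax += 0.5 * a[d]
            a[x] = ax
            if ax == 0.0:
                continue
            for y in range(j, x):
                if a[y] == 0.0:
                    continue
                v = 0.0
                if s >= 0 and a[s] > 0.0:
                    v += 0.5 * phi[s, y]
                if d >= 0 and a[d] > 0.0:
                    v += 0.5 * phi[d, y]
                phi[x, y] = v
                phi[y, x] = v
            # self entry: same-allele draw (prob 1/2, from-j with prob a[x])
            # plus distinct parental alleles
            v = 0.0
            if s >= 0 and d >= 0 and a[s] > 0.0 and a[d] > 0.0:
                v = phi[s, d]
            phi[x, x] = 0.5 * (ax + v)
        for i in range(j + 1, n):
            s = sire[i]
            d = dam[i]
            if s >= 0 and d >= 0 and a[s] > 0.0 and a[d] > 0.0:
                out[i, jj] = phi[s, d]
            else:
                out[i, jj] = 0.0


def partial_F_matrix(ped: Pedigree, ancestors: Sequence[str] | None = None) -> pd.DataFrame:
    """F_i(j) for every individual i and every requested ancestor j.

    Returns a DataFrame (index = individual ids, columns = ancestor ids).
    ``ancestors`` defaults to every founder *line*: the founders themselves
    plus, for each non-founder with a single unknown parent, that unknown
    side (treated throughout the package as an unrelated, non-inbred
    founder; its column is labelled ``<id/sire>`` or ``<id/dam>``).  Over
    this default set the columns partition F exactly.
    """
    ped.require_sorted()
    n = ped.n
    sire = ped.sire_idx.astype(np.int64).copy()
    dam = ped.dam_idx.astype(np.int64).copy()
    F = compute_F(ped)

    # materialize unknown-parent slots of non-founders as phantom founders,
    # placed ahead of the pedigree so parents still precede offspring
    phantom_names: list[str] = []
    founder = ped.founder_mask
    for i in range(n):
        if founder[i]:
            continue
        if sire[i] == UNKNOWN_IDX:
            sire[i] = len(phantom_names)
            phantom_names.append(f"<{ped.ids[i]}/sire>")
        if dam[i] == UNKNOWN_IDX:
            dam[i] = len(phantom_names)
            phantom_names.append(f"<{ped.ids[i]}/dam>")
    k = len(phantom_names)
    # augmented parent indices: phantoms occupy 0..k-1, originals shift by k
    sire_aug = np.full(n + k, -1, dtype=np.int64)
    dam_aug = np.full(n + k, -1, dtype=np.int64)
    for i in range(n):
        s_orig, d_orig = ped.sire_idx[i], ped.dam_idx[i]
        sire_aug[k + i] = s_orig + k if s_orig >= 0 else (sire[i] if sire[i] != UNKNOWN_IDX else -1)
        dam_aug[k + i] = d_orig + k if d_orig >= 0 else (dam[i] if dam[i] != UNKNOWN_IDX else -1)
    F_aug = np.concatenate([np.zeros(k), F])

    if ancestors is None:
        col_names = [ped.ids[j] for j in np.flatnonzero(founder)] + phantom_names
        anc_idx = np.array(
            [ped.position(a) + k for a in col_names[: int(founder.sum())]]
            + list(range(k)),
            dtype=np.int64,
        )
    else:
        col_names = list(ancestors)
        anc_idx = np.array([ped.position(a) + k for a in col_names], dtype=np.int64)

    out = np.zeros((n + k, len(anc_idx)))
    if len(anc_idx):
        phi = np.zeros((n + k, n + k))
        scratch = np.zeros(n + k)
        _partial_F_kernel(sire_aug, dam_aug, F_aug, anc_idx, phi, scratch, out)
    return pd.DataFrame(out[k:], index=ped.ids, columns=col_names)


def compute_partial_F(
    ped: Pedigree, j: str, targets: Sequence[str] | None = None
) -> pd.Series:
    """Partial inbreeding of each individual with respect to ancestor ``j``."""
    col = partial_F_matrix(ped, [j])[j]
    if targets is not None:
        col = col.loc[list(targets)]
    return col


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class GeneDropEstimate:
    """A Monte Carlo IBD probability with its binomial standard error."""

    estimate: float
    reps: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.estimate * (1.0 - self.estimate) / self.reps))


def gene_drop(
    ped: Pedigree,
    statistic: str = "F",
    reps: int = 100_000,
    seed: int = 0,
    ancestor: str | None = None,
) -> pd.DataFrame:
    """Estimate F, Fa or F_i(j) by dropping labelled founder alleles.

    Each founder receives two unique allele labels; transmission is Mendelian.
    For ``statistic="Fij"`` descent from the two alleles present in
    ``ancestor`` is tracked, matching the label-at-j semantics of the exact
    recursion.  Per-individual random streams are derived from the master seed
    (identical seed + reps give bit-identical output).

    Returns a DataFrame indexed by id with columns estimate, se, reps.
    """
    ped.require_sorted()
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if statistic not in {"F", "Fa", "Fij"}:
        raise ValueError(f"unknown statistic {statistic!r}")
    if statistic == "Fij":
        if ancestor is None:
            raise ValueError("statistic 'Fij' needs an ancestor")
        j = ped.position(ancestor)
    n = ped.n
    sire, dam = ped.sire_idx, ped.dam_idx
    streams = np.random.SeedSequence(seed).spawn(n)

    al = np.empty((n, 2, reps), dtype=np.int32)
    flag = np.zeros((n, 2, reps), dtype=bool)  # allele was IBD-homozygous in an ancestor
    if statistic == "Fij":
        slot = np.empty((n, 2, reps), dtype=np.int8)  # -1 none, 0/1 = ancestor's alleles
    next_virtual = 2 * n  # labels for unknown-parent founder lines

    for i in range(n):
        rng = np.random.default_rng(streams[i])
        for side, parent in ((0, sire[i]), (1, dam[i])):
            if parent == UNKNOWN_IDX:
                if sire[i] == UNKNOWN_IDX and dam[i] == UNKNOWN_IDX:
                    al[i, side] = 2 * i + side  # true founder: own label pair
                else:
                    al[i, side] = next_virtual  # unknown side: unique virtual line
                    next_virtual += 1
                if statistic == "Fij":
                    slot[i, side] = -1
            else:
                pick = rng.integers(0, 2, size=reps)
                al[i, side] = np.where(pick, al[parent, 1], al[parent, 0])
                par_auto = al[parent, 0] == al[parent, 1]
                flag[i, side] = np.where(pick, flag[parent, 1], flag[parent, 0]) | par_auto
                if statistic == "Fij":
                    slot[i, side] = np.where(pick, slot[parent, 1], slot[parent, 0])
        if statistic == "Fij" and i == j:
            slot[i, 0] = 0
            slot[i, 1] = 1

    if statistic == "F":
        vals = (al[:, 0] == al[:, 1]).mean(axis=1)
    elif statistic == "Fa":
        # mean over the two allele slots (bool arrays must not be added:
        # numpy bool + bool is logical OR)
        vals = 0.5 * (flag[:, 0].mean(axis=1) + flag[:, 1].mean(axis=1))
    else:
        j_auto = al[j, 0] == al[j, 1]
        both = (slot[:, 0] >= 0) & (slot[:, 1] >= 0)
        hit = both & ((slot[:, 0] == slot[:, 1]) | j_auto[None, :])
        vals = hit.mean(axis=1)

    se = np.sqrt(vals * (1.0 - vals) / reps)
    return pd.DataFrame({"estimate": vals, "se": se, "reps": reps}, index=ped.ids)
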