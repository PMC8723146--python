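"""Opportunity of purging and purged inbreeding.

The opportunity-of-purging coefficients quantify, from pedigree structure
alone, how much of an individual's inbreeding load is expected to have been
exposed to selection in its inbred ancestors:

* total opportunity   O(i)  = sum_j sum_k (1/2)^(n-1) * F_j
* expressed opportunity Oe(i) = sum_j 2 * F_i(j) * F_j

where j runs over all inbred ancestors of i, k over all single-parent-link
paths from i up to j (n individuals on the path, i and j included), and
F_i(j) is the partial inbreeding of i with respect to j.

In complex pedigrees the same IBD exposure can be counted through several
autozygous ancestors on one line of descent.  Instead of the exact nested
corrections, a heuristic is applied: the entire contribution of a far
ancestor k to O(i) and Oe(i) is dropped whenever some intermediate ancestor j
(on a path from i through to k) is itself autozygous for k's alleles,
F_j(k) > 0.  The heuristic can overshoot in lines that are inbred every
generation, yielding O > 1 or Oe > F; those estimates are capped at O = 1 and
Oe = F and flagged.  Raw and corrected values act as upper and lower bounds
of the expected load decline, so both are always reported.

Purged inbreeding g(d) discounts F for the expected removal of deleterious
recessives by purging, controlled by the purging coefficient d in [0, 0.5].
See :func:`compute_g` for the pedigree recursion used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inbreeding import compute_F, partial_F_matrix
from .pedigree import Pedigree

#: strict-positivity tolerance for F_j(k) > 0 in the heuristic correction
ZERO_TOL = 1e-12


@dataclass(frozen=True)
class PurgingParams:
    """The purging coefficient d: the recessive component of deleterious effects."""

    d: float

    def __post_init__(self):
        if not 0.0 <= self.d <= 0.5:
            raise ValueError(f"purging coefficient d must lie in [0, 0.5], got {self.d}")


# ---------------------------------------------------------------------------
# opportunity of purging
# ---------------------------------------------------------------------------
@dataclass
class OpportunityResult:
    """Per-individual opportunity-of-purging coefficients (pedigree order)."""

    ids: list[str]
    F: np.ndarray
    O_raw: np.ndarray
    Oe_raw: np.ndarray
    O_corrected: np.ndarray
    Oe_corrected: np.ndarray
    #: per-(individual, ancestor) bookkeeping for the audit export
    _audit: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def O_capped(self) -> np.ndarray:
        return np.minimum(self.O_corrected, 1.0)

    @property
    def Oe_capped(self) -> np.ndarray:
        return np.minimum(self.Oe_corrected, self.F)

    @property
    def capped_flag(self) -> np.ndarray:
        return (self.O_corrected > 1.0) | (self.Oe_corrected > self.F)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "O_raw": self.O_raw,
                "O": self.O_corrected,
                "O_capped": self.O_capped,
                "Oe_raw": self.Oe_raw,
                "Oe": self.Oe_corrected,
                "Oe_capped": self.Oe_capped,
                "capped_flag": self.capped_flag,
            },
            index=self.ids,
        )

    def contributions(self) -> pd.DataFrame:
        """Long-format per-ancestor audit: id, ancestor, O/Oe terms, kept flag."""
        if self._audit is None:
            raise ValueError("opportunity was computed with audit=False")
        return self._audit


def path_weight_matrix(ped: Pedigree) -> np.ndarray:
    """W[i, j] = sum over all paths from i up to ancestor j of (1/2)^(n-1).

    Computed by the downward recursion W[i] = (W[sire] + W[dam]) / 2 with
    W[j, j] = 1; equals the expected genetic contribution of j to i.
    """
    ped.require_sorted()
    n = ped.n
    W = np.zeros((n + 1, n + 1))
    sire, dam = ped.sire_idx, ped.dam_idx
    for i in range(n):
        s = sire[i] if sire[i] >= 0 else n
        d = dam[i] if dam[i] >= 0 else n
        W[i, :n] = 0.5 * (W[s, :n] + W[d, :n])
        W[i, i] = 1.0
    return W[:n, :n]


def compute_opportunity(
    ped: Pedigree,
    F: np.ndarray | None = None,
    *,
    audit: bool = False,
) -> OpportunityResult:
    """Raw, heuristically corrected and capped O and Oe for every individual.

    ``audit=True`` additionally records every per-ancestor term and whether the
    correction kept or dropped it (quadratic in pedigree size; intended for
    small pedigrees).
    """
    ped.require_sorted()
    if F is None:
        F = compute_F(ped)
    n = ped.n
    ids = ped.ids
    inbred = np.flatnonzero(F > ZERO_TOL)
    if len(inbred) == 0:
        zero = np.zeros(n)
        return OpportunityResult(ids, F, zero, zero.copy(), zero.copy(), zero.copy(),
                                 _audit=_empty_audit() if audit else None)

    W = path_weight_matrix(ped)
    anc = ped.ancestor_matrix()
    inbred_ids = [ids[k] for k in inbred]
    P = partial_F_matrix(ped, inbred_ids).to_numpy()  # (n, m) partial F wrt inbred ancestors

    Fj = F[inbred]
    # per-(i, ancestor) raw terms
    is_anc = anc[:, inbred]
    termO = W[:, inbred] * Fj[None, :] * is_anc
    termOe = 2.0 * P * Fj[None, :] * is_anc

    # heuristic correction: drop ancestor k for focal i when some intermediate
    # j (ancestor of i, descendant of k) has F_j(k) > 0
    M = (P > ZERO_TOL).astype(np.float32)  # M[j, kk]: j autozygous for ancestor k's alleles
    A = anc.astype(np.float32)
    drop = (A @ M) > 0.5  # (n, m)
    keep = ~drop

    O_raw = termO.sum(axis=1)
    Oe_raw = termOe.sum(axis=1)
    O_corr = (termO * keep).sum(axis=1)
    Oe_corr = (termOe * keep).sum(axis=1)

    audit_df = None
    if audit:
        rows = []
        for col, k in enumerate(inbred):
            focal = np.flatnonzero(is_anc[:, col])
            for i in focal:
                rows.append(
                    (
                        ids[i],
                        ids[k],
                        termO[i, col],
                        termOe[i, col],
                        bool(keep[i, col]),
                        "" if keep[i, col] else "intermediate ancestor autozygous for this line",
                    )
                )
        audit_df = pd.DataFrame(
            rows, columns=["id", "ancestor", "O_term", "Oe_term", "kept", "reason"]
        )
    return OpportunityResult(ids, F, O_raw, Oe_raw, O_corr, Oe_corr, _audit=audit_df)


def _empty_audit() -> pd.DataFrame:
    return pd.DataFrame(columns=["id", "ancestor", "O_term", "Oe_term", "kept", "reason"])


def compute_O_raw(ped: Pedigree, F: np.ndarray | None = None) -> np.ndarray:
    """Total opportunity of purging, uncorrected (see :func:`compute_opportunity`)."""
    return compute_opportunity(ped, F).O_raw


def compute_Oe_raw(ped: Pedigree, F: np.ndarray | None = None) -> np.ndarray:
    """Expressed opportunity of purging, uncorrected (see :func:`compute_opportunity`)."""
    return compute_opportunity(ped, F).Oe_raw


def cap_opportunity(
    O_corrected: np.ndarray, Oe_corrected: np.ndarray, F: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Clamp corrected values to their theoretical bounds O <= 1, Oe <= F.

    Returns (O_capped, Oe_capped, capped_flag).
    """
    O_capped = np.minimum(O_corrected, 1.0)
    Oe_capped = np.minimum(Oe_corrected, F)
    flag = (O_corrected > 1.0) | (Oe_corrected > F)
    return O_capped, Oe_capped, flag


# ---------------------------------------------------------------------------
# purged inbreeding
# ---------------------------------------------------------------------------
def purged_kinship_matrix(ped: Pedigree, d: float) -> tuple[np.ndarray, np.ndarray]:
    """Purged kinship matrix and per-individual purged inbreeding g.

    The table is filled in sorted order.  For a pair in which neither member
    is an ancestor of the other, both are expanded into their parents at once
    and the transmitted value is attenuated by (1 - 2d * gbar), gbar being the
    mean purged inbreeding of the pair — one attenuation per generation step.
    When one member is an ancestor of the other, only the descendant is
    expanded and its own purged inbreeding drives the attenuation.  Purged
    self-kinship is (1 + g_x)(1 - 2 d g_x) / 2.  At d = 0 every factor is 1
    and the table is exactly the ordinary kinship matrix; in a Wright-Fisher
    population the cohort mean of g reproduces the discrete-generation series
    of :func:`g_recursion` in expectation.
    """
    ped.require_sorted()
    PurgingParams(d)
    n = ped.n
    anc = ped.ancestor_matrix()
    G = np.zeros((n + 1, n + 1))
    g = np.zeros(n)
    sire = np.where(ped.sire_idx >= 0, ped.sire_idx, n)
    dam = np.where(ped.dam_idx >= 0, ped.dam_idx, n)
    spad = np.append(sire, n)
    dpad = np.append(dam, n)
    for x in range(n):
        s, dm = sire[x], dam[x]
        gx = G[s, dm]
        g[x] = gx
        if x > 0:
            rs, rd = G[s], G[dm]
            sy = spad[:x]
            dy = dpad[:x]
            v3 = 0.25 * (rs[sy] + rs[dy] + rd[sy] + rd[dy]) * (1.0 - d * (gx + g[:x]))
            v2 = 0.5 * (rs[:x] + rd[:x]) * (1.0 - 2.0 * d * gx)
            row = np.where(anc[x, :x], v2, v3)
            G[x, :x] = row
            G[:x, x] = row
        G[x, x] = 0.5 * (1.0 + gx) * (1.0 - 2.0 * d * gx)
    return G[:n, :n], g


def compute_g(ped: Pedigree, d: float) -> np.ndarray:
    """Purged inbreeding coefficient g(d) per individual (pedigree order).

    g(0) equals Wright's F exactly, and 0 <= g(d) <= F with g non-increasing
    in d.
    """
    return purged_kinship_matrix(ped, d)[1]


def g_recursion(N: int, d: float, t: int) -> np.ndarray:
    """Discrete-generation purged-inbreeding series for an ideal population.

    g_t = [1/(2N) + (1 - 1/(2N)) g_{t-1}] * (1 - 2 d g_{t-1}), with g_0 = 0.
    Returns the full series g_0 .. g_t.  At d = 0 this is Wright's
    F_t = 1 - (1 - 1/(2N))^t.
    """
    if N < 2 or int(N) != N:
        raise ValueError("N must be an integer >= 2")
    if t < 0:
        raise ValueError("t must be >= 0")
    PurgingParams(d)
    out = np.zeros(t + 1)
    for k in range(1, t + 1):
        prev = out[k - 1]
        out[k] = (1.0 / (2 * N) + (1.0 - 1.0 / (2 * N)) * prev) * (1.0 - 2.0 * d * prev)
    return out


# ---------------------------------------------------------------------------
# expected inbreeding-load decline
# ---------------------------------------------------------------------------
def expected_load(
    B0: float, Oe: np.ndarray, F: np.ndarray
) -> np.ndarray:
    """Predicted inbreeding load B = B0 * (1 - Oe/F) per individual.

    Oe/F is the normalized opportunity of purging; individuals with F = 0 have
    had no opportunity, so their predicted load stays at B0.  Computed with
    raw Oe this is an upper-bound decline curve, with corrected/capped Oe a
    lower bound.
    """
    if B0 < 0:
        raise ValueError("base inbreeding load B0 must be >= 0")
    Oe = np.asarray(Oe, dtype=float)
    F = np.asarray(F, dtype=float)
    norm = np.divide(Oe, F, out=np.zeros_like(Oe), where=F > 0)
    return B0 * (1.0 - norm)
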