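"""Pedigree demography: depth, realized effective size, founder statistics.

These statistics contextualize inbreeding and purging coefficients in terms of
the population's demographic history: how complete the pedigree is (equivalent
complete generations t), how fast inbreeding accumulated (per-individual
deltaF and the realized Ne it implies), and how founder genomes are
represented in the living population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import Pedigree, UNKNOWN_IDX


def equivalent_generations(ped: Pedigree) -> np.ndarray:
    """Equivalent complete generations t per individual.

    t_i = sum over known ancestors of (1/2)^(generation distance), via the
    recursion t_i = ((t_s + 1) + (t_d + 1)) / 2 with an unknown parent's term
    contributing 0.  Founders have t = 0; a fully known, non-overlapping
    pedigree of depth k gives t = k.
    """
    ped.require_sorted()
    n = ped.n
    t = np.zeros(n)
    sire, dam = ped.sire_idx, ped.dam_idx
    for i in range(n):
        acc = 0.0
        for p in (sire[i], dam[i]):
            if p != UNKNOWN_IDX:
                acc += (t[p] + 1.0) / 2.0
        t[i] = acc
    return t


@dataclass(frozen=True)
class NeEstimate:
    """Realized effective population size from individual increases in inbreeding."""

    Ne: float
    se: float
    n_used: int
    mean_deltaF: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if np.isinf(self.Ne):
            return "Ne = inf (no inbreeding accumulated)"
        return f"Ne = {self.Ne:.2f} +/- {self.se:.2f} (n = {self.n_used})"


def delta_F(F: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Per-individual rate of inbreeding deltaF = 1 - (1 - F)^(1/(t-1)).

    Defined for individuals with pedigree depth t > 1; others are NaN.
    """
    F = np.asarray(F, dtype=float)
    t = np.asarray(t, dtype=float)
    out = np.full_like(F, np.nan)
    ok = t > 1.0
    out[ok] = 1.0 - np.power(1.0 - F[ok], 1.0 / (t[ok] - 1.0))
    return out


def realized_Ne(ped: Pedigree, F: np.ndarray, t: np.ndarray | None = None) -> NeEstimate:
    """Realized Ne = 1 / (2 * mean(deltaF)) over individuals with t > 1.

    The standard error is propagated from the sample variance of deltaF by the
    delta method.  A pedigree in which no individual has t > 1 is too shallow
    to estimate a rate of inbreeding and raises a ValueError.
    """
    if t is None:
        t = equivalent_generations(ped)
    dF = delta_F(F, t)
    dF = dF[~np.isnan(dF)]
    if dF.size == 0:
        raise ValueError(
            "no individual has equivalent generations t > 1: "
            "the pedigree is too shallow to estimate a rate of inbreeding"
        )
    m = float(dF.mean())
    se_m = float(dF.std(ddof=1) / np.sqrt(dF.size)) if dF.size > 1 else float("nan")
    if m <= 0.0:
        return NeEstimate(float("inf"), float("nan"), int(dF.size), m)
    Ne = 1.0 / (2.0 * m)
    se = 2.0 * Ne * Ne * se_m  # |dNe/dm| = 1/(2 m^2)
    return NeEstimate(Ne, se, int(dF.size), m)


def founder_contributions(ped: Pedigree) -> pd.DataFrame:
    """Expected founder genome proportions per individual.

    Each individual's vector is the mean of its parents'; founders are
    indicator vectors.  An unknown parent is treated as an anonymous founder
    line pooled into an ``<unknown>`` column so every row sums to 1.
    """
    ped.require_sorted()
    n = ped.n
    founders = np.flatnonzero(ped.founder_mask)
    cols = [ped.ids[k] for k in founders] + ["<unknown>"]
    nf = len(founders)
    Q = np.zeros((n, nf + 1))
    col_of = {k: c for c, k in enumerate(founders)}
    sire, dam = ped.sire_idx, ped.dam_idx
    for i in range(n):
        if i in col_of:
            Q[i, col_of[i]] = 1.0
            continue
        for p in (sire[i], dam[i]):
            if p == UNKNOWN_IDX:
                Q[i, nf] += 0.5
            else:
                Q[i] += 0.5 * Q[p]
    return pd.DataFrame(Q, index=ped.ids, columns=cols)


@dataclass(frozen=True)
class FounderStats:
    founder_count: int
    effective_founders: float


def founder_stats(ped: Pedigree, reference: list[str] | None = None) -> FounderStats:
    """Founder count and effective number of founders for a reference set.

    founder_count counts founders with descendants in the reference set (a
    reference founder counts itself).  effective_founders = 1 / sum_k q_k^2
    where q_k is founder k's mean expected genome proportion across the
    reference individuals.
    """
    if reference is None:
        reference = ped.ids
    if len(reference) == 0:
        raise ValueError("reference set must not be empty")
    Q = founder_contributions(ped).loc[list(reference)]
    # anonymous unknown-parent lines are excluded from the effective-founder
    # sum: they are all distinct, so pooling them would understate diversity
    q = Q.drop(columns="<unknown>").mean(axis=0).to_numpy()
    count = int((q > 0).sum())
    denom = float((q**2).sum())
    fe = 1.0 / denom if denom > 0 else float("nan")
    return FounderStats(count, fe)


def cohort_summary(
    ped: Pedigree,
    coeffs: pd.DataFrame | None = None,
    t: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-cohort census and mean +/- SD of every available coefficient.

    The cohort is the ``time`` column when present, otherwise the rounded
    equivalent-generations depth (documented approximation).  ``coeffs`` is
    any per-individual numeric table aligned with pedigree order (e.g. the
    coefficient table with F, Fa, O, Oe, g columns, or fitness and load).
    """
    df = ped.df
    if "time" in df.columns and df["time"].notna().all():
        cohort = df["time"].astype(int).to_numpy()
    else:
        if t is None:
            t = equivalent_generations(ped)
        cohort = np.round(t).astype(int)
    data = pd.DataFrame({"cohort": cohort})
    if "fitness" in df.columns:
        data["fitness"] = pd.to_numeric(df["fitness"], errors="coerce").to_numpy()
    if coeffs is not None:
        for col in coeffs.columns:
            vals = pd.to_numeric(coeffs[col], errors="coerce")
            if vals.notna().any():
                data[col] = vals.to_numpy()
    grouped = data.groupby("cohort")
    out = pd.DataFrame({"census": grouped.size()})
    for col in data.columns:
        if col == "cohort":
            continue
        out[f"{col}_mean"] = grouped[col].mean()
        out[f"{col}_sd"] = grouped[col].std(ddof=1)
    return out.reset_index()
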