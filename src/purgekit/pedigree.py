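"""Pedigree container, I/O, validation, sorting and ancestor queries.

A pedigree is a table of individuals with sire and dam identities.  Identities
are opaque strings compared exactly (after whitespace trimming).  Unknown
parents may be written ``0``, ``NA``, ``*`` or an empty field on input and are
normalised to a single internal sentinel; on output they are always ``NA``.

All coefficient code in this package operates on a *sorted* pedigree
(parents before offspring) in which individuals are renumbered to dense
0-based indices; results are always mapped back to the original identities.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Internal sentinel for an unknown parent (index form is -1).
UNKNOWN = ""

#: Strings normalised to UNKNOWN on input under the default dialect.
DEFAULT_MISSING = ("0", "NA", "", "*", "NaN", "nan")

UNKNOWN_IDX = -1


class PedigreeError(ValueError):
    """Raised for malformed or inconsistent pedigrees."""


@dataclass(frozen=True)
class PedigreeRecord:
    """One individual: its identity, parent identities and optional attributes."""

    id: str
    sire: str = UNKNOWN
    dam: str = UNKNOWN
    sex: str | None = None
    fitness: float | None = None
    time: int | None = None


@dataclass(frozen=True)
class AncestorPath:
    """A chain of single-parent links from a focal individual up to an ancestor.

    ``nodes`` runs from the focal individual to the ancestor inclusive; ``n``
    is the number of individuals on the path (focal and ancestor included).
    """

    nodes: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.nodes)


@dataclass
class Issue:
    """A machine-readable validation finding."""

    code: str  # CYCLE, SELF_PARENT, DUP_ID, SEX_CONFLICT, MISSING_PARENT
    message: str
    ids: tuple[str, ...] = ()

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.code}: {self.message}"


class Pedigree:
    """An ordered collection of pedigree records with index-based parent links.

    Parameters
    ----------
    df : pandas.DataFrame
        Must contain string columns ``id``, ``sire``, ``dam`` (unknown parents
        as the empty-string sentinel); optional columns ``sex``, ``fitness``,
        ``time`` are carried through.
    """

    def __init__(self, df: pd.DataFrame):
        if not {"id", "sire", "dam"}.issubset(df.columns):
            raise PedigreeError("pedigree frame needs columns id, sire, dam")
        self._df = df.reset_index(drop=True).copy()
        ids = self._df["id"]
        dup = ids[ids.duplicated()]
        if len(dup):
            raise PedigreeError(f"duplicate id: {dup.iloc[0]!r}")
        self._pos = {i: k for k, i in enumerate(ids)}
        self._sire_idx = np.array(
            [self._lookup(s, row) for row, s in enumerate(self._df["sire"])], dtype=np.int64
        )
        self._dam_idx = np.array(
            [self._lookup(d, row) for row, d in enumerate(self._df["dam"])], dtype=np.int64
        )
        self._anc_cache: np.ndarray | None = None

    def _lookup(self, parent: str, row: int) -> int:
        if parent == UNKNOWN:
            return UNKNOWN_IDX
        if parent not in self._pos:
            raise PedigreeError(
                f"row {row}: parent {parent!r} does not appear in the id column "
                "(read with permissive=True to auto-insert founders)"
            )
        return self._pos[parent]

    # -- basic accessors ---------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        """The underlying table (copy-safe view)."""
        return self._df

    @property
    def n(self) -> int:
        return len(self._df)

    @property
    def ids(self) -> list[str]:
        return list(self._df["id"])

    @property
    def sire_idx(self) -> np.ndarray:
        """Sire index per individual; -1 for unknown."""
        return self._sire_idx

    @property
    def dam_idx(self) -> np.ndarray:
        return self._dam_idx

    def position(self, identity: str) -> int:
        try:
            return self._pos[identity]
        except KeyError:
            raise PedigreeError(f"unknown identity: {identity!r}") from None

    def __len__(self) -> int:
        return self.n

    def __contains__(self, identity: str) -> bool:
        return identity in self._pos

    def records(self) -> Iterable[PedigreeRecord]:
        for row in self._df.itertuples(index=False):
            yield PedigreeRecord(
                id=row.id,
                sire=row.sire,
                dam=row.dam,
                sex=getattr(row, "sex", None),
                fitness=getattr(row, "fitness", None),
                time=getattr(row, "time", None),
            )

    @property
    def founder_mask(self) -> np.ndarray:
        """True where both parents are unknown."""
        return (self._sire_idx == UNKNOWN_IDX) & (self._dam_idx == UNKNOWN_IDX)

    # -- ordering ----------------------------------------------------------
    @property
    def is_sorted(self) -> bool:
        order = np.arange(self.n)
        ok_s = (self._sire_idx == UNKNOWN_IDX) | (self._sire_idx < order)
        ok_d = (self._dam_idx == UNKNOWN_IDX) | (self._dam_idx < order)
        return bool(ok_s.all() and ok_d.all())

    def require_sorted(self) -> None:
        if not self.is_sorted:
            raise PedigreeError(
                "pedigree is not sorted parents-before-offspring; call sort_pedigree() first"
            )

    # -- relations ---------------------------------------------------------
    def ancestor_matrix(self) -> np.ndarray:
        """Boolean (n, n) matrix: entry [i, j] is True iff j is a strict ancestor of i.

        Requires a sorted pedigree.
        """
        self.require_sorted()
        if self._anc_cache is None:
            n = self.n
            anc = np.zeros((n, n), dtype=bool)
            for i in range(n):
                for p in (self._sire_idx[i], self._dam_idx[i]):
                    if p != UNKNOWN_IDX:
                        anc[i] |= anc[p]
                        anc[i, p] = True
            self._anc_cache = anc
        return self._anc_cache

    def ancestors(self, identity: str) -> set[str]:
        """All strict ancestors of ``identity`` (works on unsorted pedigrees)."""
        start = self.position(identity)
        seen: set[int] = set()
        stack = [start]
        while stack:
            k = stack.pop()
            for p in (self._sire_idx[k], self._dam_idx[k]):
                if p != UNKNOWN_IDX and p not in seen:
                    seen.add(p)
                    stack.append(p)
        ids = self._df["id"]
        return {ids.iloc[k] for k in seen}


def _normalise(value, missing: Sequence[str]) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return UNKNOWN
    s = str(value).strip()
    return UNKNOWN if s in missing else s


def read_pedigree(
    source,
    *,
    sep: str = "\t",
    id_col: str = "id",
    sire_col: str = "sire",
    dam_col: str = "dam",
    sex_col: str = "sex",
    fitness_col: str = "fitness",
    time_col: str = "time",
    missing: Sequence[str] = DEFAULT_MISSING,
    permissive: bool = False,
) -> Pedigree:
    """Read a studbook-style delimited table into a :class:`Pedigree`.

    The header must name at least the three identity columns.  Unknown-parent
    codes listed in ``missing`` are normalised to a single sentinel.  Row order
    is preserved (sorting is a separate, explicit step).

    With ``permissive=True``, parents referenced but absent from the id column
    are appended as founders (with a warning) instead of raising.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep=sep, dtype=str, keep_default_na=False)
    for col in (id_col, sire_col, dam_col):
        if col not in df.columns:
            raise PedigreeError(f"missing required column {col!r} in header")
    out = pd.DataFrame(
        {
            "id": [_normalise(v, ()) for v in df[id_col]],
            "sire": [_normalise(v, missing) for v in df[sire_col]],
            "dam": [_normalise(v, missing) for v in df[dam_col]],
        }
    )
    if (out["id"] == UNKNOWN).any():
        bad = int(np.argmax((out["id"] == UNKNOWN).to_numpy()))
        raise PedigreeError(f"line {bad + 2}: empty or missing individual id")
    if sex_col in df.columns:
        out["sex"] = [_normalise(v, missing) or None for v in df[sex_col]]
    if fitness_col in df.columns:
        out["fitness"] = pd.to_numeric(
            df[fitness_col].replace(list(missing), np.nan), errors="coerce"
        )
    if time_col in df.columns:
        out["time"] = pd.to_numeric(
            df[time_col].replace(list(missing), np.nan), errors="coerce"
        ).astype("Int64")
    # any further attribute columns are carried through, numeric when possible
    handled = {id_col, sire_col, dam_col, sex_col, fitness_col, time_col}
    for col in df.columns:
        if col in handled:
            continue
        try:
            out[col] = pd.to_numeric(df[col].replace("NA", np.nan))
        except (ValueError, TypeError):
            out[col] = df[col]
    if permissive:
        known = set(out["id"])
        extras: list[str] = []
        for col in ("sire", "dam"):
            for v in out[col]:
                if v != UNKNOWN and v not in known:
                    known.add(v)
                    extras.append(v)
        if extras:
            warnings.warn(
                f"auto-inserted {len(extras)} referenced-but-absent parents as founders: "
                + ", ".join(extras[:5])
            )
            pad = pd.DataFrame({"id": extras, "sire": UNKNOWN, "dam": UNKNOWN})
            out = pd.concat([pad, out], ignore_index=True)
    return Pedigree(out)


def write_pedigree(ped: Pedigree, path, *, sep: str = "\t") -> None:
    """Write a pedigree as delimited text; unknown parents become ``NA``."""
    df = ped.df.copy()
    for col in ("sire", "dam"):
        df[col] = df[col].replace(UNKNOWN, "NA")
    df.to_csv(path, sep=sep, index=False, na_rep="NA")


def validate_pedigree(ped: Pedigree) -> list[Issue]:
    """Check pedigree invariants; returns an empty list iff all hold.

    Issues are data, not exceptions: DUP_ID and MISSING_PARENT are raised at
    construction time and cannot occur here, but the codes are reserved.
    """
    issues: list[Issue] = []
    df = ped.df
    ids = df["id"].to_numpy()
    for i in range(ped.n):
        if ped.sire_idx[i] == i or ped.dam_idx[i] == i:
            issues.append(Issue("SELF_PARENT", f"{ids[i]!r} is its own parent", (ids[i],)))
        if ped.sire_idx[i] != UNKNOWN_IDX and ped.sire_idx[i] == ped.dam_idx[i]:
            warnings.warn(f"selfing: {ids[i]!r} has the same sire and dam")
    cycle = _find_cycle(ped)
    if cycle:
        issues.append(
            Issue("CYCLE", "parent relation contains a cycle: " + " -> ".join(cycle), tuple(cycle))
        )
    if "sex" in df.columns:
        as_sire = set(ped.sire_idx[ped.sire_idx != UNKNOWN_IDX])
        as_dam = set(ped.dam_idx[ped.dam_idx != UNKNOWN_IDX])
        sex = df["sex"]
        for k in as_sire:
            if sex.iloc[k] == "female":
                issues.append(Issue("SEX_CONFLICT", f"{ids[k]!r} recorded female but used as sire", (ids[k],)))
        for k in as_dam:
            if sex.iloc[k] == "male":
                issues.append(Issue("SEX_CONFLICT", f"{ids[k]!r} recorded male but used as dam", (ids[k],)))
    return issues


def _find_cycle(ped: Pedigree) -> list[str] | None:
    n = ped.n
    color = np.zeros(n, dtype=np.int8)  # 0 unseen, 1 active, 2 done
    parent_of = [ped.sire_idx, ped.dam_idx]
    ids = ped.df["id"].to_numpy()
    for start in range(n):
        if color[start]:
            continue
        stack: list[tuple[int, int]] = [(start, 0)]
        trail = [start]
        color[start] = 1
        while stack:
            node, branch = stack[-1]
            if branch < 2:
                stack[-1] = (node, branch + 1)
                p = parent_of[branch][node]
                if p == UNKNOWN_IDX or p == node:  # self-parenting reported separately
                    continue
                if color[p] == 1:
                    k = trail.index(p)
                    return [ids[x] for x in trail[k:]] + [ids[p]]
                if color[p] == 0:
                    color[p] = 1
                    trail.append(p)
                    stack.append((p, 0))
            else:
                color[node] = 2
                trail.pop()
                stack.pop()
    return None


def sort_pedigree(ped: Pedigree) -> Pedigree:
    """Topologically sort so every parent precedes all of its offspring.

    The sort is stable: ties are broken by original input order, and an
    already-sorted pedigree is returned in identical order.
    """
    n = ped.n
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=np.int64)
    for i in range(n):
        for p in (ped.sire_idx[i], ped.dam_idx[i]):
            if p != UNKNOWN_IDX and p != i:
                children[p].append(i)
                indeg[i] += 1
    import heapq

    ready = [i for i in range(n) if indeg[i] == 0]
    heapq.heapify(ready)
    order: list[int] = []
    while ready:
        i = heapq.heappop(ready)
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(ready, c)
    if len(order) < n:
        cycle = _find_cycle(ped)
        raise PedigreeError(
            "cannot sort: parent relation is cyclic ("
            + " -> ".join(cycle or ["?"])
            + ")"
        )
    return Pedigree(ped.df.iloc[order].reset_index(drop=True))


def ancestor_paths(
    ped: Pedigree, i: str, j: str, max_depth: int | None = None
) -> list[AncestorPath]:
    """Every distinct chain of single-parent links from ``i`` up to ancestor ``j``.

    Returns an empty list when ``j`` is not an ancestor of ``i``.  Each path
    carries ``n``, the count of individuals on it (``i`` and ``j`` included).
    """
    pi, pj = ped.position(i), ped.position(j)
    ids = ped.df["id"].to_numpy()
    out: list[AncestorPath] = []

    def walk(node: int, trail: list[int]) -> None:
        if max_depth is not None and len(trail) > max_depth:
            return
        if node == pj and len(trail) > 1:
            out.append(AncestorPath(tuple(ids[k] for k in trail)))
            return
        if node == pj:
            # i == j: an individual is not its own proper ancestor, but paths
            # looping through parents back to j are impossible in a DAG.
            return
        for p in (ped.sire_idx[node], ped.dam_idx[node]):
            if p != UNKNOWN_IDX:
                walk(p, trail + [p])

    if pi == pj:
        return []
    walk(pi, [pi])
    # under selfing the sire and dam slots trace the same chain: paths are
    # distinct as node sequences, so drop duplicates (order-preserving)
    seen: set[tuple[str, ...]] = set()
    unique = []
    for p in out:
        if p.nodes not in seen:
            seen.add(p.nodes)
            unique.append(p)
    return unique
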