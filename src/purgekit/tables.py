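"""Assembly of per-individual coefficient tables and long-format exports."""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .inbreeding import compute_F, compute_Fa, partial_F_matrix
from .pedigree import Pedigree
from .purging import compute_g, compute_opportunity

KNOWN_COEFFICIENTS = ("F", "Fa", "O", "Oe", "g")


def coefficient_table(
    ped: Pedigree,
    what: Sequence[str] = ("F", "Fa", "O", "Oe"),
    d_values: Iterable[float] = (),
) -> pd.DataFrame:
    """Compute the requested coefficients for every individual.

    ``what`` selects among F, Fa, O (total opportunity of purging, which also
    yields Oe), Oe, and g (one column ``g_d<value>`` per entry of
    ``d_values``).  Returns a DataFrame indexed by id, in pedigree order.
    """
    ped.require_sorted()
    unknown = set(what) - set(KNOWN_COEFFICIENTS)
    if unknown:
        raise ValueError(f"unknown coefficient(s): {sorted(unknown)}")
    out = pd.DataFrame(index=ped.ids)
    F = compute_F(ped)
    if "F" in what:
        out["F"] = F
    if "Fa" in what:
        out["Fa"] = compute_Fa(ped, F)
    if "O" in what or "Oe" in what:
        opp = compute_opportunity(ped, F)
        frame = opp.frame()
        cols = [c for c in frame.columns if ("O" in what) or c.startswith("Oe")]
        if "O" not in what:
            cols = [c for c in frame.columns if c.startswith("Oe")]
        out = out.join(frame[cols] if "O" not in what else frame)
    if "g" in what:
        for d in d_values:
            out[f"g_d{d:g}"] = compute_g(ped, float(d))
    return out


def fij_long(ped: Pedigree, ancestors: Sequence[str] | None = None) -> pd.DataFrame:
    """Partial inbreeding in long format: one row per (id, ancestor), F_i(j) > 0.

    ``ancestors`` defaults to all founders.
    """
    P = partial_F_matrix(ped, ancestors)
    long = (
        P.rename_axis("id")
        .reset_index()
        .melt(id_vars="id", var_name="ancestor", value_name="Fij")
    )
    return long[long["Fij"] > 0].reset_index(drop=True)
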