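"""Shared fixture pedigrees.

The classic-mating suite doubles as the gene-drop concordance panel: textbook
matings with closed-form coefficients, the named multi-generation fixtures
used by the opportunity-of-purging examples, and two shallow random
pedigrees.  The deep full-sib line (inbred every generation) is kept separate:
it is the stress case for the correction/capping logic.
"""

from __future__ import annotations

import pandas as pd
import pytest

from purgekit import Pedigree, UNKNOWN, random_pedigree, sort_pedigree


def ped(rows: list[tuple[str, str, str]]) -> Pedigree:
    df = pd.DataFrame(rows, columns=["id", "sire", "dam"])
    df = df.replace({"sire": {"-": UNKNOWN}, "dam": {"-": UNKNOWN}})
    return sort_pedigree(Pedigree(df))


def fullsib_line(generations: int) -> Pedigree:
    """A closed line propagated by full-sib mating for the given generations."""
    rows = [("S0a", "-", "-"), ("S0b", "-", "-")]
    for t in range(1, generations + 1):
        rows.append((f"S{t}a", f"S{t-1}a", f"S{t-1}b"))
        rows.append((f"S{t}b", f"S{t-1}a", f"S{t-1}b"))
    return ped(rows)


def correction_fixture() -> Pedigree:
    """A line where a far inbred ancestor K is re-counted through an
    intermediate J that is autozygous for K's alleles (F_J(K) = 5/32 > 0)."""
    return ped(
        [
            ("A0", "-", "-"),
            ("B0", "-", "-"),
            ("P", "A0", "B0"),
            ("Q", "A0", "B0"),
            ("K", "P", "Q"),  # F = 1/4
            ("M1", "-", "-"),
            ("M2", "-", "-"),
            ("A", "K", "M1"),
            ("B", "K", "M2"),
            ("J", "A", "B"),  # F = 5/32, all of it from K
            ("R", "-", "-"),
            ("X1", "J", "R"),  # non-inbred focal: O correction only
            ("X2", "J", "A"),  # inbred focal (F = 21/64): Oe correction too
        ]
    )


def classic_suite() -> dict[str, Pedigree]:
    return {
        "selfed": ped([("A", "-", "-"), ("S", "A", "A")]),
        "full_sib": ped(
            [("A", "-", "-"), ("B", "-", "-"), ("C", "A", "B"), ("D", "A", "B"), ("E", "C", "D")]
        ),
        "half_sib": ped(
            [
                ("J", "-", "-"),
                ("M1", "-", "-"),
                ("M2", "-", "-"),
                ("H1", "J", "M1"),
                ("H2", "J", "M2"),
                ("I", "H1", "H2"),
            ]
        ),
        "parent_offspring": ped(
            [("A", "-", "-"), ("B", "-", "-"), ("C", "A", "B"), ("X", "A", "C")]
        ),
        "first_cousins": ped(
            [
                ("A", "-", "-"),
                ("B", "-", "-"),
                ("P", "A", "B"),
                ("Q", "A", "B"),
                ("M1", "-", "-"),
                ("M2", "-", "-"),
                ("U", "P", "M1"),
                ("V", "Q", "M2"),
                ("X", "U", "V"),
            ]
        ),
        "double_first_cousins": ped(
            [
                ("A", "-", "-"),
                ("B", "-", "-"),
                ("C", "-", "-"),
                ("D", "-", "-"),
                ("S1", "A", "B"),
                ("S2", "A", "B"),
                ("T1", "C", "D"),
                ("T2", "C", "D"),
                ("U", "S1", "T1"),
                ("V", "S2", "T2"),
                ("X", "U", "V"),
            ]
        ),
        "sib_then_mate": ped(
            [
                ("A", "-", "-"),
                ("B", "-", "-"),
                ("C", "A", "B"),
                ("D", "A", "B"),
                ("E", "C", "D"),
                ("E2", "C", "D"),
                ("X", "E", "E2"),
            ]
        ),
        "inbred_far_ancestor": correction_fixture(),
        "random_a": sort_pedigree(random_pedigree(20, seed=11)),
        "random_b": sort_pedigree(random_pedigree(22, seed=23)),
    }


@pytest.fixture(scope="session")
def fixtures() -> dict[str, Pedigree]:
    return classic_suite()


@pytest.fixture(scope="session")
def sib_line() -> Pedigree:
    return fullsib_line(8)
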