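"""Opportunity of purging (raw, corrected, capped), purged inbreeding, load."""

import numpy as np
import pytest

import purgekit as pk
from oracles import brute_opportunity, tabular_relationship


class TestOpportunityRaw:
    def test_inbred_sire_single_path(self, fixtures):
        """Sire with F = 1/4 one link away contributes (1/2)^1 * 1/4."""
        ped = fixtures["sib_then_mate"]
        opp = pk.compute_opportunity(ped)
        x = ped.position("X")
        # X's parents E and E2 each have F = 1/4, one path each of n = 2
        assert opp.O_raw[x] == pytest.approx(2 * 0.5 * 0.25, abs=1e-15)

    def test_no_inbred_ancestors_gives_zero(self, fixtures):
        ped = fixtures["full_sib"]
        opp = pk.compute_opportunity(ped)
        assert np.all(opp.O_raw == 0.0) and np.all(opp.Oe_raw == 0.0)

    def test_inbred_grandparent_through_both_parents(self):
        """Grandparent with F = 1/4 reachable via both parents: two n = 3
        paths, O = 2 * (1/2)^2 * 1/4 = 1/8."""
        import pandas as pd

        rows = [
            ("A", "", ""), ("B", "", ""), ("C", "A", "B"), ("D", "A", "B"),
            ("J", "C", "D"), ("M1", "", ""), ("M2", "", ""),
            ("P", "J", "M1"), ("Q", "J", "M2"), ("X", "P", "Q"),
        ]
        ped = pk.sort_pedigree(pk.Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam"])))
        opp = pk.compute_opportunity(ped)
        assert opp.O_raw[ped.position("X")] == pytest.approx(0.125, abs=1e-15)

    def test_oe_zero_when_common_ancestors_not_inbred(self, fixtures):
        """F > 0 but every common ancestor non-inbred: Oe = 0."""
        ped = fixtures["full_sib"]
        opp = pk.compute_opportunity(ped)
        assert opp.Oe_raw[ped.position("E")] == 0.0

    def test_oe_fixture_matches_exact_partial_F_terms(self, fixtures):
        ped = fixtures["sib_then_mate"]
        F = pk.compute_F(ped)
        P = pk.partial_F_matrix(ped, ["E", "E2"])
        x = ped.position("X")
        expected = sum(2 * P[j].iloc[x] * F[ped.position(j)] for j in ("E", "E2"))
        opp = pk.compute_opportunity(ped)
        assert opp.Oe_raw[x] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", [5, 77, 123])
    def test_matches_bruteforce_enumeration(self, seed):
        ped = pk.random_pedigree(22, seed=seed)
        opp = pk.compute_opportunity(ped)
        O_exp, Oe_exp = brute_opportunity(ped)
        np.testing.assert_allclose(opp.O_raw, O_exp, atol=1e-12)
        np.testing.assert_allclose(opp.Oe_raw, Oe_exp, atol=1e-12)


class TestCorrection:
    def test_no_autozygous_intermediate_keeps_everything(self, fixtures):
        ped = fixtures["sib_then_mate"]
        opp = pk.compute_opportunity(ped)
        np.testing.assert_array_equal(opp.O_corrected, opp.O_raw)
        np.testing.assert_array_equal(opp.Oe_corrected, opp.Oe_raw)

    def test_far_ancestor_dropped_when_intermediate_autozygous(self, fixtures):
        """K (F = 1/4) is dropped for descendants of J because F_J(K) > 0;
        the remaining terms are the hand-enumerated close-ancestor ones."""
        ped = fixtures["inbred_far_ancestor"]
        P = pk.partial_F_matrix(ped, ["K"])
        assert P["K"].loc["J"] == pytest.approx(5 / 32, abs=1e-15)
        opp = pk.compute_opportunity(ped, audit=True)
        x1, x2 = ped.position("X1"), ped.position("X2")
        # X1 = J x R: raw O = 1/2 * 5/32 + 1/4 * 1/4; corrected keeps only J
        assert opp.O_raw[x1] == pytest.approx(9 / 64, abs=1e-15)
        assert opp.O_corrected[x1] == pytest.approx(5 / 64, abs=1e-15)
        # X2 = J x A: raw O = 1/2 * 5/32 + 1/2 * 1/4; raw Oe = 2 * 13/64 * 1/4
        assert opp.O_raw[x2] == pytest.approx(13 / 64, abs=1e-15)
        assert opp.Oe_raw[x2] == pytest.approx(13 / 128, abs=1e-15)
        assert opp.O_corrected[x2] == pytest.approx(5 / 64, abs=1e-15)
        # X2's autozygosity traces to K only, so correcting removes all of Oe
        assert opp.Oe_corrected[x2] == 0.0
        audit = opp.contributions()
        dropped = audit[(audit["id"] == "X2") & (~audit["kept"])]["ancestor"].tolist()
        assert dropped == ["K"]

    def test_correction_never_increases(self, fixtures, sib_line):
        for ped in list(fixtures.values()) + [sib_line]:
            opp = pk.compute_opportunity(ped)
            assert np.all(opp.O_corrected <= opp.O_raw + 1e-15)
            assert np.all(opp.Oe_corrected <= opp.Oe_raw + 1e-15)
            assert np.all(opp.O_corrected >= -1e-15)


class TestCapping:
    def test_cap_function_contracts(self):
        O_cap, Oe_cap, flag = pk.cap_opportunity(
            np.array([0.4, 1.3]), np.array([0.1, 0.6]), np.array([0.5, 0.5])
        )
        assert O_cap.tolist() == [0.4, 1.0]
        assert Oe_cap.tolist() == [0.1, 0.5]
        assert flag.tolist() == [False, True]

    def test_consecutive_fullsib_line_produces_oe_above_F(self, sib_line):
        """A line inbred every generation defeats the heuristic (F_j(k) = 0
        between consecutive generations): raw Oe eventually exceeds F, and
        capping restores Oe <= F."""
        opp = pk.compute_opportunity(sib_line)
        assert np.any(opp.Oe_raw > opp.F + 1e-12)
        assert np.all(opp.Oe_capped <= opp.F + 1e-15)
        assert np.all(opp.O_capped <= 1.0 + 1e-15)
        assert np.any(opp.capped_flag)


class TestPurgedInbreeding:
    def test_d_zero_degenerates_to_F(self, fixtures, sib_line):
        for ped in list(fixtures.values()) + [sib_line]:
            np.testing.assert_allclose(
                pk.compute_g(ped, 0.0), pk.compute_F(ped), atol=1e-12
            )

    def test_purged_kinship_matrix_at_d0_is_tabular_kinship(self):
        ped = pk.random_pedigree(25, seed=8)
        G, _ = pk.purged_kinship_matrix(ped, 0.0)
        A = np.array(tabular_relationship(ped))
        np.testing.assert_allclose(G, A / 2, atol=1e-12)

    def test_founders_zero_for_any_d(self, fixtures):
        for ped in fixtures.values():
            for d in (0.0, 0.25, 0.5):
                assert np.all(pk.compute_g(ped, d)[ped.founder_mask] == 0.0)

    @pytest.mark.parametrize("seed", [1, 13, 55])
    def test_monotone_decreasing_in_d_and_bounded_by_F(self, seed):
        ped = pk.random_pedigree(30, seed=seed)
        F = pk.compute_F(ped)
        g25 = pk.compute_g(ped, 0.25)
        g50 = pk.compute_g(ped, 0.5)
        assert np.all(g50 <= g25 + 1e-12)
        assert np.all(g25 <= F + 1e-12)
        assert np.all(g50 >= -1e-15)

    def test_invalid_d_rejected(self, fixtures):
        ped = fixtures["full_sib"]
        for d in (-0.1, 0.6):
            with pytest.raises(ValueError, match="purging coefficient"):
                pk.compute_g(ped, d)


class TestGRecursion:
    def test_d_zero_is_wrights_closed_form(self):
        N, t = 25, 50
        series = pk.g_recursion(N, 0.0, t)
        expected = 1 - (1 - 1 / (2 * N)) ** np.arange(t + 1)
        np.testing.assert_allclose(series, expected, atol=1e-14)

    def test_first_generation_is_1_over_2N(self):
        for d in (0.0, 0.25, 0.5):
            assert pk.g_recursion(10, d, 1)[1] == pytest.approx(0.05, abs=1e-15)

    def test_frozen_series_N25_d05(self):
        """Regression values frozen from straightforward one-off iteration."""
        series = pk.g_recursion(25, 0.5, 50)
        frozen = {
            1: 0.02,
            2: 0.038807999999999995,
            5: 0.08280866099866947,
            10: 0.11467869416356899,
            25: 0.1238335042802536,
            50: 0.12389932691921944,
        }
        for t, val in frozen.items():
            assert series[t] == pytest.approx(val, rel=0, abs=1e-15)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            pk.g_recursion(1, 0.25, 10)
        with pytest.raises(ValueError):
            pk.g_recursion(25, 0.7, 10)


class TestExpectedLoad:
    def test_limits_and_F_zero_convention(self):
        B = pk.expected_load(4.4, np.array([0.0, 0.25, 0.0]), np.array([0.5, 0.25, 0.0]))
        assert B.tolist() == [4.4, 0.0, 4.4]

    def test_negative_B0_rejected(self):
        with pytest.raises(ValueError, match="B0"):
            pk.expected_load(-1.0, np.array([0.0]), np.array([0.0]))


class TestRawWrappers:
    def test_wrappers_match_full_result(self, fixtures):
        ped = fixtures["sib_then_mate"]
        opp = pk.compute_opportunity(ped)
        np.testing.assert_array_equal(pk.compute_O_raw(ped), opp.O_raw)
        np.testing.assert_array_equal(pk.compute_Oe_raw(ped), opp.Oe_raw)
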