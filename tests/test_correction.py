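"""Deconfounding algebra: worked arithmetic, clamping, exact inversion."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hubseek.correction import (
    ReferenceBaselines,
    basal_fraction,
    build_baselines,
    correct_population,
    deconfound_basal,
    eec_fraction,
    rank_by_hub_proximity,
    total_ancestry,
    wec_source_coordinate,
)
from hubseek.errors import (
    ConfigurationError,
    DegenerateBaselineError,
    UndefinedValueError,
)


def baselines(U_K=0.32, U_T=0.28, basal=(0.2, 0.2, 0.25), T_WEC=0.50,
              eec=None):
    return ReferenceBaselines(
        U_K=U_K, U_T=U_T, basal_proxy=basal, T_WEC=T_WEC,
        eec_sources=eec or {"EastAsian": (0.40, 0.60), "Andamanese": (0.38, 0.55)},
    )


class TestBasalFraction:
    def test_at_u_mean_is_zero(self):
        b = baselines()
        assert basal_fraction(b.U_mean, b) == (0.0, False)

    def test_at_proxy_is_one(self):
        b = baselines()
        frac, clamped = basal_fraction(b.U_BEA, b)
        assert frac == pytest.approx(1.0) and not clamped

    def test_worked_arithmetic(self):
        b = baselines(U_K=0.32, U_T=0.28, basal=(0.2, 0.2, 0.25))
        # (0.28 - 0.30) / (0.25 - 0.30) = 0.4
        frac, clamped = basal_fraction(0.28, b)
        assert frac == pytest.approx(0.4) and not clamped

    def test_negative_clamps_to_zero_with_flag(self):
        b = baselines(U_K=0.32, U_T=0.28, basal=(0.2, 0.2, 0.25))
        frac, clamped = basal_fraction(0.31, b)  # raw -0.2
        assert frac == 0.0 and clamped

    def test_degenerate_proxy_rejected_at_construction(self):
        with pytest.raises(DegenerateBaselineError, match="basal"):
            baselines(basal=(0.2, 0.2, 0.31))  # U_BEA above U_mean


class TestDeconfound:
    def test_zero_basal_is_identity(self):
        assert deconfound_basal(0.5, 0.4, 0.0, baselines()) == (0.5, 0.4)

    def test_worked_arithmetic(self):
        b = baselines(basal=(0.2, 0.1, 0.25))
        K_BR, _ = deconfound_basal(0.5, 0.4, 0.4, b)
        assert K_BR == pytest.approx(0.7)  # (0.5 - 0.2*0.4) / 0.6

    def test_roundtrip_with_weighted_mean(self):
        b = baselines()
        K_BR, T_BR = 0.63, 0.52
        p = 0.37
        K_X = (1 - p) * K_BR + p * b.K_BEA
        T_X = (1 - p) * T_BR + p * b.T_BEA
        out = deconfound_basal(K_X, T_X, p, b)
        assert out[0] == pytest.approx(K_BR) and out[1] == pytest.approx(T_BR)

    def test_fully_basal_rejected(self):
        with pytest.raises(UndefinedValueError, match="fully Basal"):
            deconfound_basal(0.5, 0.4, 1.0, baselines())


class TestEecFraction:
    @pytest.mark.parametrize(
        "T_BR, expected, flags",
        [
            (0.50, 0.0, set()),                      # at T_WEC
            (0.60, 1.0, set()),                      # at T_EEC
            (0.55, 0.5, set()),                      # worked arithmetic
            (0.45, 0.0, {"pEEC_clamped_low"}),
            (0.70, 1.0, {"pEEC_clamped_high"}),
        ],
    )
    def test_values_and_clamps(self, T_BR, expected, flags):
        frac, got_flags = eec_fraction(T_BR, 0.50, 0.60)
        assert frac == pytest.approx(expected)
        assert got_flags == flags

    def test_degenerate_baseline(self):
        with pytest.raises(DegenerateBaselineError):
            eec_fraction(0.5, 0.6, 0.6)


class TestWecSource:
    def test_zero_eec_is_identity(self):
        assert wec_source_coordinate(0.6, 0.4, 0.0) == 0.6

    def test_worked_arithmetic(self):
        assert wec_source_coordinate(0.6, 0.4, 0.5) == pytest.approx(0.8)

    def test_fully_eec_undefined(self):
        with pytest.raises(UndefinedValueError, match="fully EEC"):
            wec_source_coordinate(0.6, 0.4, 1.0)


class TestTotalAncestry:
    def test_worked_arithmetic(self):
        assert total_ancestry(0.5, 0.2) == (pytest.approx(0.4), pytest.approx(0.4))

    def test_fully_basal_leaves_nothing(self):
        assert total_ancestry(0.5, 1.0) == (0.0, 0.0)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_conservation(self, pEEC_BR, pBEA):
        pEEC_X, pWEC_X = total_ancestry(pEEC_BR, pBEA)
        assert pBEA + pEEC_X + pWEC_X == pytest.approx(1.0, abs=1e-12)


class TestBuildBaselines:
    def _coords(self):
        return pd.DataFrame(
            {
                "population": ["Kostenki14", "Tianyuan", "Gumuz", "Sunghir",
                               "Vestonice16", "Muierii2", "Krems", "Han", "Onge"],
                "K": [1.0, 0.59, 0.48, 0.9, 0.88, 0.86, 0.84, 0.50, 0.48],
                "T": [0.60, 1.0, 0.47, 0.52, 0.50, 0.48, 0.46, 0.57, 0.55],
                "U": [0.62, 0.61, 0.49, 0.60, 0.60, 0.61, 0.60, 0.52, 0.51],
            }
        )

    def test_four_member_mean_and_u_mean(self):
        b = build_baselines(self._coords())
        assert b.T_WEC == pytest.approx(np.mean([0.52, 0.50, 0.48, 0.46]))
        assert b.U_mean == pytest.approx((0.62 + 0.61) / 2)
        assert b.basal_proxy == (0.48, 0.47, 0.49)
        assert b.eec_sources["EastAsian"] == (0.50, 0.57)

    def test_single_member_baseline(self):
        b = build_baselines(self._coords(), wec_members=("Sunghir",))
        assert b.T_WEC == pytest.approx(0.52)

    def test_missing_member_is_configuration_error(self):
        with pytest.raises(ConfigurationError, match="missing"):
            build_baselines(self._coords(), wec_members=("Sunghir", "NoSuchPop"))

    def test_non_basal_proxy_violates_invariant(self):
        coords = self._coords()
        coords.loc[coords.population == "Gumuz", "U"] = 0.63
        with pytest.raises(DegenerateBaselineError):
            build_baselines(coords)


class TestCorrectPopulation:
    def test_analytic_three_way_mixture_recovered_exactly(self):
        b = baselines()
        K_B_true, pEEC_true, pBEA_true = 0.78, 0.3 / 0.8, 0.2
        K_EEC, T_EEC = b.eec_sources["EastAsian"]
        # nested weighted means: first WEC+EEC, then with the Basal proxy
        K_BR = (1 - pEEC_true) * K_B_true + pEEC_true * K_EEC
        T_BR = (1 - pEEC_true) * b.T_WEC + pEEC_true * T_EEC
        K_X = (1 - pBEA_true) * K_BR + pBEA_true * b.K_BEA
        T_X = (1 - pBEA_true) * T_BR + pBEA_true * b.T_BEA
        U_X = (1 - pBEA_true) * b.U_mean + pBEA_true * b.U_BEA
        d = correct_population("mix", K_X, T_X, U_X, b, "EastAsian")
        assert d.pBEA_X == pytest.approx(pBEA_true, abs=1e-12)
        assert d.pEEC_BR == pytest.approx(pEEC_true, abs=1e-12)
        assert d.K_B == pytest.approx(K_B_true, abs=1e-12)
        assert d.pEEC_X == pytest.approx(0.3, abs=1e-12)
        assert d.pWEC_X == pytest.approx(0.5, abs=1e-12)

    def test_unadmixed_reference_boundary(self):
        b = baselines()
        d = correct_population("K14", 1.0, b.T_WEC, b.U_mean, b, "EastAsian")
        assert d.pBEA_X == 0.0 and d.pEEC_BR == 0.0
        assert d.K_B == pytest.approx(1.0)

    def test_fully_eec_population_flagged_undefined(self):
        b = baselines()
        K_EEC, T_EEC = b.eec_sources["EastAsian"]
        d = correct_population("eec", K_EEC, T_EEC + 0.05, b.U_mean, b, "EastAsian")
        assert not d.K_B_defined and math.isnan(d.K_B)

    @given(
        pBEA=st.floats(0.0, 0.95),
        pEEC=st.floats(0.0, 0.95),
        K_B=st.floats(0.3, 1.0),
        data=st.data(),
    )
    @settings(max_examples=200, deadline=None)
    def test_exact_inversion_property(self, pBEA, pEEC, K_B, data):
        """Nested weighted-mean construction inverts to machine precision."""
        U_K = data.draw(st.floats(0.3, 0.7))
        U_T = data.draw(st.floats(0.3, 0.7))
        U_mean = (U_K + U_T) / 2
        U_BEA = data.draw(st.floats(0.01, max(U_mean - 0.05, 0.02)))
        T_WEC = data.draw(st.floats(0.2, 0.5))
        T_EEC = data.draw(st.floats(T_WEC + 0.05, 0.9))
        b = ReferenceBaselines(
            U_K=U_K, U_T=U_T, basal_proxy=(0.2, 0.15, U_BEA), T_WEC=T_WEC,
            eec_sources={"EastAsian": (0.45, T_EEC)},
        )
        K_BR = (1 - pEEC) * K_B + pEEC * 0.45
        T_BR = (1 - pEEC) * T_WEC + pEEC * T_EEC
        K_X = (1 - pBEA) * K_BR + pBEA * b.K_BEA
        T_X = (1 - pBEA) * T_BR + pBEA * b.T_BEA
        U_X = (1 - pBEA) * U_mean + pBEA * U_BEA
        d = correct_population("x", K_X, T_X, U_X, b, "EastAsian")
        assert d.pBEA_X == pytest.approx(pBEA, abs=1e-9)
        assert d.pEEC_BR == pytest.approx(pEEC, abs=1e-9)
        assert d.K_B == pytest.approx(K_B, abs=1e-9)
        assert d.pBEA_X + d.pEEC_X + d.pWEC_X == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_source_coordinate(self):
        b = baselines()
        kbs = []
        for K_B_true in (0.6, 0.7, 0.8):
            K_BR = 0.5 * K_B_true + 0.5 * b.eec_sources["EastAsian"][0]
            T_BR = 0.5 * b.T_WEC + 0.5 * b.eec_sources["EastAsian"][1]
            d = correct_population("x", K_BR, T_BR, b.U_mean, b, "EastAsian")
            kbs.append(d.K_B)
        assert kbs == sorted(kbs)


class TestRanking:
    def _decomp(self, pop, K_B, pWEC=0.9, undefined=False):
        from hubseek.correction import AncestryDecomposition

        return AncestryDecomposition(
            population=pop, pBEA_X=0.05, K_BR=K_B, T_BR=0.5, pEEC_BR=0.05,
            K_B=float("nan") if undefined else K_B, pEEC_X=1 - pWEC - 0.05,
            pWEC_X=pWEC, clamp_flags={"K_B_undefined"} if undefined else set(),
        )

    def test_sorted_ascending_by_kb(self):
        out = rank_by_hub_proximity(
            [self._decomp("a", 0.8), self._decomp("b", 0.7)]
        )
        assert list(out["population"]) == ["b", "a"]

    def test_low_wec_excluded_at_threshold(self):
        out = rank_by_hub_proximity(
            [self._decomp("a", 0.7, pWEC=0.5), self._decomp("b", 0.8)],
            min_wec=0.75,
        )
        assert list(out["population"]) == ["b"]

    def test_undefined_kb_excluded_and_counted(self):
        out = rank_by_hub_proximity(
            [self._decomp("a", 0.7, undefined=True), self._decomp("b", 0.8)]
        )
        assert list(out["population"]) == ["b"]
        assert out.attrs["n_undefined"] == 1

    def test_ties_break_by_label(self):
        out = rank_by_hub_proximity(
            [self._decomp("zeta", 0.7), self._decomp("alpha", 0.7)]
        )
        assert list(out["population"]) == ["alpha", "zeta"]

    def test_empty_result_is_empty_table(self):
        out = rank_by_hub_proximity([self._decomp("a", 0.7, pWEC=0.1)])
        assert out.empty
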