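import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canopylai import (
    GapGrid,
    ImprovedCoefficients,
    LeafAngleModel,
    LeafMask,
    TABLE_COEFFICIENTS,
    clumping_index,
    coefficients_A,
    f_gap,
    fvc,
    gap_grid,
    lai_classical,
    lai_improved,
)
from canopylai.gaps import ZeroGapError


def sympy_f_gap(P, ratio, log_base="natural"):
    """Independent high-precision evaluation of the improved formula."""
    import sympy as sp

    x = sp.Rational(ratio)
    logx = sp.log(x) if log_base == "natural" else sp.log(x, 10)
    A = [
        sp.Float(a1, 30) + sp.Float(a2, 30) * x + sp.Float(a3, 30) * logx
        for a1, a2, a3 in TABLE_COEFFICIENTS
    ]
    p = sp.Rational(P)
    expr = (1 - p) * p ** (1 / A[0]) + ((1 - p ** (1 / A[1])) * (1 - p) ** (1 / A[2])) / (
        1 / A[3] + A[4] * p ** A[5]
    )
    return float(sp.N(expr, 30))


class TestFvcAndGapGrid:
    def test_fvc_extremes_and_checkerboard(self):
        all_bg = LeafMask(np.zeros((4, 4), dtype=bool))
        all_leaf = LeafMask(np.ones((4, 4), dtype=bool))
        checker = LeafMask(np.indices((4, 4)).sum(axis=0) % 2 == 0)
        assert fvc(all_bg) == 0.0
        assert fvc(all_leaf) == 1.0
        assert fvc(checker) == 0.5

    def test_all_background_gaps_are_one(self):
        grid = gap_grid(LeafMask(np.zeros((10, 10), dtype=bool)), 3)
        assert grid.m == 9
        np.testing.assert_array_equal(grid.gaps, 1.0)

    def test_checkerboard_half_gap(self):
        checker = LeafMask(np.indices((6, 6)).sum(axis=0) % 2 == 0)
        grid = gap_grid(checker, 2)
        np.testing.assert_array_equal(grid.gaps, 0.5)

    def test_matches_brute_force_counts(self, rng):
        mask = LeafMask(rng.random((64, 64)) < 0.4)
        grid = gap_grid(mask, 10)
        assert grid.m == 36
        expected = [
            1.0 - mask.grid[r : r + 10, c : c + 10].sum() / 100
            for r in range(0, 60, 10)
            for c in range(0, 60, 10)
        ]
        np.testing.assert_allclose(grid.gaps, expected)

    def test_leaf_pixel_conservation_exact(self, rng):
        mask = LeafMask(rng.random((50, 50)) < 0.3)
        W = 10  # divides both sides: tiling covers the whole mask
        grid = gap_grid(mask, W)
        assert int(round(np.sum((1 - grid.gaps) * W * W))) == mask.leaf_count

    def test_partial_edge_squares_discarded(self):
        mask = LeafMask(np.ones((25, 17), dtype=bool))
        grid = gap_grid(mask, 10)
        assert grid.m == 2  # 2 rows x 1 col of full squares

    def test_mask_smaller_than_square_rejected(self):
        with pytest.raises(ValueError):
            gap_grid(LeafMask(np.ones((4, 4), dtype=bool)), 5)


class TestLaiClassical:
    def test_all_gap_is_zero_lai(self):
        grid = GapGrid(np.ones(9), W_px=10)
        est = lai_classical(grid)
        assert est.L == 0.0
        assert est.omega == 1.0
        assert est.fvc == 0.0

    def test_single_square_analytic(self):
        # m = 1, P = e^-1, theta = 0, spherical G = 0.5 -> L = 2 exactly
        grid = GapGrid([math.exp(-1)], W_px=10)
        est = lai_classical(grid, LeafAngleModel("spherical"))
        assert est.L == pytest.approx(2.0, rel=1e-12)

    @given(st.floats(min_value=0.01, max_value=0.99))
    @settings(max_examples=50, deadline=None)
    def test_single_square_is_beer_lambert_inversion(self, p):
        grid = GapGrid([p], W_px=10, theta=25.0)
        lad = LeafAngleModel("horizontal")
        est = lai_classical(grid, lad)
        theta = math.radians(25.0)
        expected = -math.cos(theta) * math.log(p) / math.cos(theta)
        assert est.L == pytest.approx(expected, rel=1e-12)

    def test_zero_gap_substitution_policy(self):
        grid = GapGrid([0.0, 0.5], W_px=10)
        est = lai_classical(grid, LeafAngleModel("horizontal"))
        p_min = 1.0 / 200.0
        assert est.zero_gap_squares == 1
        assert est.L == pytest.approx(-(math.log(p_min) + math.log(0.5)) / 2)

    def test_zero_gap_strict_policy_raises(self):
        grid = GapGrid([0.0, 0.5], W_px=10)
        with pytest.raises(ZeroGapError):
            lai_classical(grid, zero_gap="error")


class TestClumpingIndex:
    def test_equal_gaps_give_unity(self):
        assert clumping_index(GapGrid([0.3] * 7, W_px=5)) == pytest.approx(1.0)

    def test_two_square_analytic_value(self):
        omega = clumping_index(GapGrid([0.9, 0.1], W_px=5))
        expected = 2 * math.log(0.5) / (math.log(0.9) + math.log(0.1))
        assert omega == pytest.approx(expected, rel=1e-12)
        assert omega == pytest.approx(0.5757, abs=1e-4)

    def test_jensen_bound_on_random_grids(self, rng):
        # concavity of log: Omega in (0, 1] whenever all P_i in (0, 1)
        for _ in range(1000):
            gaps = rng.uniform(0.01, 0.99, size=rng.integers(2, 30))
            omega = clumping_index(GapGrid(gaps, W_px=5))
            assert 0.0 < omega <= 1.0 + 1e-12

    def test_full_gap_squares_kept_in_mean(self):
        omega = clumping_index(GapGrid([1.0, 0.5], W_px=5))
        expected = 2 * math.log(0.75) / math.log(0.5)
        assert omega == pytest.approx(expected, rel=1e-12)


class TestImprovedCoefficients:
    def test_log_term_vanishes_at_unit_ratio(self):
        coeff = ImprovedCoefficients(W=3.0, D=3.0)
        np.testing.assert_allclose(
            coeff.A, TABLE_COEFFICIENTS[:, 0] + TABLE_COEFFICIENTS[:, 1]
        )

    def test_natural_log_values_at_ratio_three(self):
        A = coefficients_A(ImprovedCoefficients(W=3.0, D=1.0))
        assert A[0] == pytest.approx(9.9898, abs=1e-4)
        assert A[3] == pytest.approx(5.5379, abs=1e-4)

    def test_base10_log_values_at_ratio_three(self):
        A = coefficients_A(ImprovedCoefficients(W=3.0, D=1.0, log_base="base10"))
        assert A[0] == pytest.approx(17.156, abs=1e-3)

    def test_all_A_positive_over_validity_range(self):
        for ratio in np.linspace(1.0, 20.0, 40):
            A = coefficients_A(ImprovedCoefficients(W=ratio, D=1.0))
            assert np.all(A > 0)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            ImprovedCoefficients(W=-1.0, D=1.0)


class TestFGap:
    COEFF = ImprovedCoefficients(W=3.0, D=1.0)

    def test_endpoints(self):
        assert f_gap(1.0, self.COEFF) == 0.0
        assert f_gap(0.0, self.COEFF) == pytest.approx(self.COEFF.A[3], rel=1e-12)

    def test_continuous_at_endpoints(self):
        # the P -> 0 limit converges like P^(1/A1), so probe it much closer
        assert f_gap(1.0 - 1e-9, self.COEFF) == pytest.approx(0.0, abs=1e-3)
        assert f_gap(1e-30, self.COEFF) == pytest.approx(self.COEFF.A[3], rel=1e-2)

    def test_against_independent_high_precision_oracle(self):
        for p in (0.1, 0.5, 0.9):
            assert f_gap(p, self.COEFF) == pytest.approx(
                sympy_f_gap(p, 3), rel=1e-10
            )

    @pytest.mark.parametrize("ratio", [2.0, 3.0, 5.0, 10.0])
    def test_monotone_non_increasing(self, ratio):
        coeff = ImprovedCoefficients(W=ratio, D=1.0)
        p = np.linspace(0.0, 1.0, 1000)
        vals = f_gap(p, coeff)
        assert np.all(np.diff(vals) <= 1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            f_gap(1.5, self.COEFF)


class TestLaiImproved:
    def test_all_gap_is_zero(self):
        coeff = ImprovedCoefficients(W=30.0, D=10.0)
        est = lai_improved(GapGrid(np.ones(4), W_px=30), coeff)
        assert est.L == 0.0

    def test_fully_covered_scene_hits_finite_cap(self):
        # every square closed: L = 2 A_4 with spherical G = 0.5 at nadir
        coeff = ImprovedCoefficients(W=30.0, D=10.0)
        est = lai_improved(GapGrid(np.zeros(4), W_px=30), coeff, LeafAngleModel("spherical"))
        assert est.L == pytest.approx(2.0 * coeff.A[3], rel=1e-12)
        assert est.zero_gap_squares == 4

    def test_out_of_validity_range_warns_in_notes(self):
        coeff = ImprovedCoefficients(W=50.0, D=1.0)
        est = lai_improved(GapGrid([0.5], W_px=50), coeff)
        assert any("outside" in n for n in est.notes)
        assert math.isfinite(est.L)
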