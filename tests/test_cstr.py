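"""Chemostat steady states, washout, productivity optima and sweeps."""

import math
import warnings

import numpy as np
import pytest

from logimonod import (
    CSTRConditions,
    FeasibilityWarning,
    GrowthParameters,
    InfeasibleOperationError,
    ModelKind,
    dilution_sweep,
    optimal_dilution,
    steady_state,
    washout_dilution,
)
from logimonod.cstr import integrate_cstr, steady_state_residuals


def low_yield(p: GrowthParameters) -> GrowthParameters:
    return GrowthParameters(mu_max=p.mu_max, K_s=p.K_s, X_m=p.X_m, Y_xs=0.3)


class TestSteadyState:
    def test_monod_low_dilution_limit(self, cstr_params, feed_substrate):
        ss = steady_state(ModelKind.MONOD, cstr_params, CSTRConditions(D=1e-9, S_F=feed_substrate))
        assert ss.S_star == pytest.approx(0.0, abs=1e-8)
        assert ss.X_star == pytest.approx(0.8 * 20.0, abs=1e-7)

    def test_logistic_half_mu_gives_half_capacity(self, cstr_params, feed_substrate):
        ss = steady_state(ModelKind.LOGISTIC, cstr_params, CSTRConditions(D=0.8, S_F=feed_substrate))
        assert ss.X_star == pytest.approx(10.0 / 2.0, rel=1e-12)

    def test_hybrid_capacity_binds_at_low_dilution(self, cstr_params, feed_substrate):
        # Y_xs * S_F = 16 > X_m = 10: the carrying capacity is the binding limit
        ss = steady_state(ModelKind.HYBRID, cstr_params, CSTRConditions(D=1e-10, S_F=feed_substrate))
        assert ss.X_star == pytest.approx(10.0, abs=1e-6)

    def test_mass_balance_residuals_and_root_rejection(self, feed_substrate):
        """Over a (D, Y_xs) grid the selected hybrid root satisfies both balances
        while the other quadratic root lies outside [0, S_F]."""
        worst = 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FeasibilityWarning)
            for Y in np.linspace(0.15, 1.0, 10):
                p = GrowthParameters(mu_max=1.6, K_s=1.0, X_m=10.0, Y_xs=Y)
                D_w = washout_dilution(ModelKind.HYBRID, p, feed_substrate)
                for D in np.linspace(0.05, 0.98, 12) * D_w:
                    c = CSTRConditions(D=float(D), S_F=feed_substrate)
                    ss = steady_state(ModelKind.HYBRID, p, c)
                    r1, r2 = steady_state_residuals(ModelKind.HYBRID, p, c, ss)
                    worst = max(worst, abs(r1), abs(r2))
                    # the rejected quadratic root
                    a = p.mu_max * p.Y_xs
                    b = p.mu_max * (p.X_m - p.Y_xs * feed_substrate) - D * p.X_m
                    other = (-b - math.sqrt(b * b + 4.0 * a * D * p.K_s * p.X_m)) / (2.0 * a)
                    assert other < 0.0 or other > feed_substrate
        assert worst <= 1e-10

    def test_state_bounds(self, cstr_params, feed_substrate):
        for D in np.linspace(0.0, 2.0, 21):
            ss = steady_state(ModelKind.HYBRID, cstr_params, CSTRConditions(D=float(D), S_F=feed_substrate))
            assert -1e-9 <= ss.S_star <= feed_substrate + 1e-9
            assert -1e-9 <= ss.X_star <= cstr_params.Y_xs * feed_substrate + 1e-9

    def test_logistic_infeasible_feed_raises(self, feed_substrate):
        p = low_yield(GrowthParameters(mu_max=1.6, K_s=1.0, X_m=10.0, Y_xs=0.8))
        with pytest.warns(FeasibilityWarning):
            with pytest.raises(InfeasibleOperationError, match="Y_xs"):
                steady_state(ModelKind.LOGISTIC, p, CSTRConditions(D=0.1, S_F=feed_substrate))

    def test_steady_state_is_dynamic_attractor(self, cstr_params, feed_substrate):
        c = CSTRConditions(D=0.8, S_F=feed_substrate)
        ss = steady_state(ModelKind.HYBRID, cstr_params, c)
        X, S = integrate_cstr(
            ModelKind.HYBRID, cstr_params, c,
            (ss.X_star * 1.5, max(ss.S_star * 0.5, 0.05)), horizon=300.0,
        )
        assert abs(X - ss.X_star) <= 1e-6
        assert abs(S - ss.S_star) <= 1e-6


class TestWashout:
    def test_logistic_washout_is_mu_max(self, cstr_params, feed_substrate):
        assert washout_dilution(ModelKind.LOGISTIC, cstr_params, feed_substrate) == 1.6

    def test_monod_closed_form(self, cstr_params, feed_substrate):
        assert washout_dilution(ModelKind.MONOD, cstr_params, feed_substrate) == pytest.approx(1.6 * 20 / 21)

    def test_hybrid_equals_monod_for_any_capacity(self, feed_substrate):
        """At X = 0 the self-inhibition factor is 1, so hybrid washout is Monod washout."""
        for X_m in (0.5, 5.0, 50.0, 1e6):
            for mu, Ks in ((0.4, 0.5), (1.6, 1.0), (2.2, 8.0)):
                p = GrowthParameters(mu_max=mu, K_s=Ks, X_m=X_m, Y_xs=0.5)
                assert washout_dilution(ModelKind.HYBRID, p, feed_substrate) == washout_dilution(
                    ModelKind.MONOD, p, feed_substrate
                )

    @pytest.mark.parametrize("model", list(ModelKind))
    def test_branch_switches_exactly_at_washout(self, cstr_params, feed_substrate, model):
        D_w = washout_dilution(model, cstr_params, feed_substrate)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FeasibilityWarning)
            below = steady_state(model, cstr_params, CSTRConditions(D=D_w * (1 - 1e-9), S_F=feed_substrate))
            above = steady_state(model, cstr_params, CSTRConditions(D=D_w * (1 + 1e-9), S_F=feed_substrate))
        assert below.branch == "nontrivial" and above.branch == "washout"
        assert above.X_star == 0.0 and above.S_star == feed_substrate

    @pytest.mark.parametrize("model", list(ModelKind))
    def test_bisection_on_biomass_reproduces_closed_form(self, cstr_params, feed_substrate, model):
        """Locate the smallest washed-out D by bisection on the branch indicator."""
        lo, hi = 0.0, 4.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FeasibilityWarning)
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                ss = steady_state(model, cstr_params, CSTRConditions(D=mid, S_F=feed_substrate))
                if ss.X_star > 0.0:
                    lo = mid
                else:
                    hi = mid
        assert 0.5 * (lo + hi) == pytest.approx(
            washout_dilution(model, cstr_params, feed_substrate), abs=1e-9
        )


class TestOptimalDilution:
    def test_logistic_parabola_vertex(self, cstr_params, feed_substrate):
        analysis = optimal_dilution(ModelKind.LOGISTIC, cstr_params, feed_substrate)
        assert analysis.D_optimal == pytest.approx(0.8)
        assert analysis.P_max == pytest.approx(1.6 * 10.0 / 4.0)

    def test_monod_closed_form_agrees_with_grid(self, cstr_params, feed_substrate):
        analysis = optimal_dilution(ModelKind.MONOD, cstr_params, feed_substrate)
        assert analysis.D_optimal == pytest.approx(1.6 * (1 - math.sqrt(1 / 21)), rel=1e-12)

    def test_hybrid_with_huge_capacity_matches_monod(self, feed_substrate):
        p = GrowthParameters(mu_max=1.6, K_s=1.0, X_m=1e9, Y_xs=0.8)
        analysis = optimal_dilution(ModelKind.HYBRID, p, feed_substrate)
        assert analysis.D_optimal == pytest.approx(1.6 * (1 - math.sqrt(1 / 21)), rel=1e-6)

    @pytest.mark.parametrize("model", list(ModelKind))
    def test_optimum_dominates_dense_grid(self, cstr_params, feed_substrate, model):
        analysis = optimal_dilution(model, cstr_params, feed_substrate)
        assert 0.0 < analysis.D_optimal < analysis.D_washout
        grid = np.linspace(1e-6, analysis.D_washout * (1 - 1e-9), 1000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FeasibilityWarning)
            productivities = [
                steady_state(model, cstr_params, CSTRConditions(D=float(D), S_F=feed_substrate)).productivity
                for D in grid
            ]
        assert analysis.P_max >= max(productivities) - 1e-9


class TestDilutionSweep:
    def test_washout_rows_flagged(self, cstr_params, feed_substrate):
        table = dilution_sweep(ModelKind.MONOD, cstr_params, feed_substrate, np.linspace(0.0, 2.0, 9))
        washed = table[table["D_per_hr"] >= 1.6 * 20 / 21]
        assert (washed["branch"] == "washout").all()
        assert (washed["X_star_g_L"] == 0.0).all()
        assert (washed["S_star_g_L"] == feed_substrate).all()

    def test_monotone_on_nontrivial_branch(self, cstr_params, feed_substrate):
        for model in ModelKind:
            table = dilution_sweep(model, cstr_params, feed_substrate, np.linspace(1e-3, 1.4, 30))
            live = table[table["branch"] == "nontrivial"]
            assert np.all(np.diff(live["S_star_g_L"]) >= -1e-12)
            assert np.all(np.diff(live["X_star_g_L"]) <= 1e-12)

    def test_logistic_biomass_is_exactly_linear_in_dilution(self, cstr_params, feed_substrate):
        table = dilution_sweep(ModelKind.LOGISTIC, cstr_params, feed_substrate, np.linspace(0.3, 1.5, 25))
        second_diffs = np.diff(table["X_star_g_L"].to_numpy(), n=2)
        assert np.max(np.abs(second_diffs)) <= 1e-12

    def test_hybrid_yield_ratio_identity(self, cstr_params, feed_substrate):
        """On the nontrivial branch X*/(S_F - S*) equals Y_xs by mass balance."""
        table = dilution_sweep(ModelKind.HYBRID, cstr_params, feed_substrate, np.linspace(0.1, 1.5, 20))
        live = table[table["branch"] == "nontrivial"]
        ratios = live["X_star_g_L"] / (feed_substrate - live["S_star_g_L"])
        np.testing.assert_allclose(ratios, 0.8, rtol=1e-12)

    def test_decreasing_grid_rejected(self, cstr_params, feed_substrate):
        with pytest.raises(ValueError):
            dilution_sweep(ModelKind.MONOD, cstr_params, feed_substrate, [0.5, 0.2])
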