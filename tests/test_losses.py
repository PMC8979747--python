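"""Regression-loss family: branch formulas, continuity constants, dynamics."""

import numpy as np
import pytest
from scipy.optimize import brentq

from dyndet.exceptions import InvalidParameterError, InvalidStateError
from dyndet.losses import (
    DynamicLossState,
    dbs_l1,
    dbs_l1_gradient,
    ds_l1,
    smooth_l1,
    solve_bc,
    update_alpha,
)

ALPHA_GRID = np.arange(0.1, 2.01, 0.1)


def solve_b_numeric(alpha):
    """Independent oracle: bracketed root solve of alpha*ln(b*alpha+1) = 1."""
    f = lambda b: alpha * np.log(b * alpha + 1.0) - 1.0
    hi = (np.exp(1.0 / alpha) - 1.0) / alpha * 2 + 1.0
    return brentq(f, 1e-8, hi, xtol=1e-14, rtol=1e-15)


class TestSmoothL1:
    @pytest.mark.parametrize("x,beta,expected", [
        (0.0, 1.0, 0.0),
        (1.0, 1.0, 0.5),        # boundary: both branches agree
        (2.5, 1.0, 2.0),        # linear branch: 2.5 - 0.5
        (0.3, 0.5, 0.09),       # quadratic branch: 0.5*0.09/0.5
    ])
    def test_values(self, x, beta, expected):
        assert smooth_l1(x, beta) == pytest.approx(expected, abs=1e-12)

    def test_rejects_nonpositive_beta(self):
        with pytest.raises(InvalidParameterError):
            smooth_l1(1.0, 0.0)
        with pytest.raises(InvalidParameterError):
            smooth_l1(1.0, -2.0)

    def test_ds_l1_is_smooth_l1_with_alpha_branch_point(self, rng):
        xs = rng.uniform(0, 3, size=200)
        for alpha in (0.2, 0.7, 1.3):
            np.testing.assert_array_equal(ds_l1(xs, alpha), smooth_l1(xs, alpha))

    def test_ds_l1_boundary_agreement(self):
        for alpha in ALPHA_GRID:
            assert ds_l1(alpha, alpha) == pytest.approx(0.5 * alpha)


class TestContinuityConstants:
    @pytest.mark.parametrize("alpha,b_exp,c_exp", [
        (1.0, 1.718282, -0.418023),
        (0.5, 12.778112, -0.171741),
    ])
    def test_frozen_values(self, alpha, b_exp, c_exp):
        b, c = solve_bc(alpha)
        assert b == pytest.approx(b_exp, abs=5e-6)
        assert c == pytest.approx(c_exp, abs=5e-6)

    @pytest.mark.parametrize("alpha", ALPHA_GRID)
    def test_matches_bracketed_root_solve(self, alpha):
        b, _ = solve_bc(alpha)
        assert b == pytest.approx(solve_b_numeric(alpha), rel=1e-10)

    @pytest.mark.parametrize("alpha", ALPHA_GRID)
    def test_slope_constraint_holds(self, alpha):
        b, _ = solve_bc(alpha)
        assert alpha * np.log(b * alpha + 1.0) == pytest.approx(1.0, abs=1e-10)

    def test_rejects_nonpositive_alpha(self):
        for bad in (0.0, -1.0):
            with pytest.raises(InvalidParameterError):
                solve_bc(bad)


class TestDBSL1:
    def test_zero_error_gives_zero_loss(self):
        for alpha in ALPHA_GRID:
            assert dbs_l1(0.0, alpha) == 0.0

    def test_frozen_values_alpha_one(self):
        # both branch formulas evaluated with the solved constants agree
        b, c = solve_bc(1.0)
        inner = (1.0 / b) * (b + 1.0) * np.log(b + 1.0) - 1.0
        assert inner == pytest.approx(1.0 + c, abs=1e-12)
        assert dbs_l1(1.0, 1.0) == pytest.approx(0.581977, abs=1e-6)
        assert dbs_l1(10.0, 1.0) == pytest.approx(9.581977, abs=1e-6)

    @pytest.mark.parametrize("alpha", ALPHA_GRID)
    def test_c0_and_c1_continuity_at_branch_point(self, alpha):
        eps = 1e-9
        below = dbs_l1(alpha - eps, alpha)
        above = dbs_l1(alpha + eps, alpha)
        assert abs(above - below) < 1e-8
        g_below = dbs_l1_gradient(alpha - eps, alpha)
        g_above = dbs_l1_gradient(alpha + eps, alpha)
        assert abs(g_above - g_below) < 1e-8
        assert dbs_l1_gradient(alpha, alpha) == pytest.approx(1.0, abs=1e-9)

    def test_nonnegative_and_strictly_increasing(self, rng):
        xs = np.sort(rng.uniform(1e-4, 3.0, size=500))
        for alpha in (0.1, 0.5, 1.0, 2.0):
            vals = dbs_l1(xs, alpha)
            assert np.all(vals >= 0)
            assert np.all(np.diff(vals) > 0)

    def test_gradient_matches_finite_differences(self, rng):
        xs = rng.uniform(1e-3, 2.5, size=1000)
        h = 1e-7
        for alpha in (0.3, 1.0):
            xs_safe = xs[np.abs(xs - alpha) > 2 * h]  # FD straddles the kink there
            fd = (dbs_l1(xs_safe + h, alpha) - dbs_l1(xs_safe - h, alpha)) / (2 * h)
            np.testing.assert_allclose(dbs_l1_gradient(xs_safe, alpha), fd, atol=1e-6)

    def test_gradient_value_small_x(self):
        # analytic alpha*ln(b*x+1) at x=0.1, alpha=1, cross-checked by FD
        h = 1e-7
        fd = (dbs_l1(0.1 + h, 1.0) - dbs_l1(0.1 - h, 1.0)) / (2 * h)
        g = dbs_l1_gradient(0.1, 1.0)
        assert g == pytest.approx(fd, abs=1e-6)
        assert g == pytest.approx(np.log(solve_bc(1.0)[0] * 0.1 + 1.0), abs=1e-12)

    def test_small_error_gradient_grows_as_alpha_shrinks(self):
        """Shrinking alpha steepens the loss on small errors, so well-localized
        samples contribute more as training sharpens the factor."""
        x = 0.05
        grads = [dbs_l1_gradient(x, a) for a in ALPHA_GRID]
        # grid is ascending in alpha, so gradients must be strictly descending
        assert np.all(np.diff(grads) < 0)

    def test_stale_state_rejected(self):
        state = DynamicLossState.create(alpha_init=1.0)
        state.alpha_now = 0.5  # without re-solving b, C
        with pytest.raises(InvalidStateError):
            dbs_l1(0.3, state)


class TestAlphaUpdate:
    def test_records_order_statistic(self):
        state = DynamicLossState.create(k_alpha=1, cadence=100)
        update_alpha(state, [0.9, 0.1, 0.5])
        assert state.error_buffer == [pytest.approx(0.1)]
        state2 = DynamicLossState.create(k_alpha=2, cadence=100)
        update_alpha(state2, [0.9, 0.1, 0.5])
        assert state2.error_buffer == [pytest.approx(0.5)]

    def test_cadence_update_sets_median_and_resolves_constants(self):
        state = DynamicLossState.create(k_alpha=2, cadence=1)
        update_alpha(state, [0.4] * 10)
        assert state.alpha_now == pytest.approx(0.4)
        state.check_consistent()
        assert state.error_buffer == []

    def test_short_sample_falls_back_with_warning(self, caplog):
        import dyndet.losses as losses_mod
        losses_mod._FALLBACK_WARNED.clear()
        state = DynamicLossState.create(k_alpha=10, cadence=100)
        with caplog.at_level("WARNING", logger="dyndet.losses"):
            update_alpha(state, [0.3, 0.6])
        assert state.error_buffer == [pytest.approx(0.6)]
        assert any("K_alpha" in r.message for r in caplog.records)

    def test_clamped_to_bounds(self):
        state = DynamicLossState.create(k_alpha=1, cadence=1, clamp=(0.05, 1.0))
        update_alpha(state, [5.0])
        assert state.alpha_now == pytest.approx(1.0)
        update_alpha(state, [1e-6])
        assert state.alpha_now == pytest.approx(0.05)

    def test_shrinking_errors_drive_alpha_down_monotonically(self, rng):
        """Feeding steadily shrinking error streams across many cadences
        produces a non-increasing alpha sequence."""
        state = DynamicLossState.create(k_alpha=5, cadence=10)
        alphas = [state.alpha_now]
        for step in range(10):
            scale = 0.8 / (step + 1)
            for _ in range(10):
                update_alpha(state, rng.uniform(0.5, 1.0, size=50) * scale)
            alphas.append(state.alpha_now)
        assert all(a2 <= a1 + 1e-12 for a1, a2 in zip(alphas, alphas[1:]))
        assert alphas[-1] < alphas[0]
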