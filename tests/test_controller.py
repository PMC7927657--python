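"""Operating-point solving, experiment planning and the full iterative loop."""

import warnings

import numpy as np
import pytest
from conftest import bisect_terminal_re

import sinkscale as sk
from sinkscale.controller import _solve_scale_for_target
from sinkscale.core import InsufficientDataError, NoIntersectionError
from sinkscale.tank import NoiseModel, VirtualParticleTruth, VirtualTank


def quiet_tank(geom, material, oil, resin, drag=None, cv=0.0, bias=0.0, seed=0,
               D=0.9):
    truth = VirtualParticleTruth(geom, drag or sk.MORRISON, material)
    noise = NoiseModel(velocity_cv=cv, volume_bias_c=bias, seed=seed)
    return VirtualTank(truth, D, oil, resin, noise)


class TestInitialGuess:
    def test_matches_bisection_oracle(self, foram_sphere, test_material, seawater):
        op = sk.initial_operating_guess(foram_sphere, seawater, test_material)
        re_oracle = bisect_terminal_re(foram_sphere, test_material, seawater,
                                       sk.morrison_cd)
        u_oracle = sk.speed_from_reynolds(re_oracle, foram_sphere.L, seawater)
        assert op.Re_O == pytest.approx(re_oracle, rel=1e-4)
        assert op.U_O == pytest.approx(u_oracle, rel=1e-3)

    def test_stokes_limit(self):
        d = 20e-6
        fluid = sk.FluidSpec(1000.0, 1e-3, "water")
        mat = sk.MaterialSpec(2650.0, "quartz")
        geom = sk.ParticleGeometry.sphere(d)
        op = sk.initial_operating_guess(geom, fluid, mat)
        u_stokes = sk.G_STANDARD * d**2 * (2650.0 - 1000.0) / (18 * 1e-3)
        assert op.Re_O < 0.1
        assert op.U_O == pytest.approx(u_stokes, rel=0.02)

    def test_consistent_triple(self, foram_sphere, test_material, seawater):
        op = sk.initial_operating_guess(foram_sphere, seawater, test_material)
        assert op.U_O == pytest.approx(
            sk.speed_from_reynolds(op.Re_O, foram_sphere.L, seawater), rel=1e-12
        )
        assert op.C_D_O == pytest.approx(
            sk.cd_force_balance(op.Re_O, foram_sphere, test_material, seawater),
            rel=1e-12,
        )


class TestPlanning:
    def test_ordering(self, foram_sphere, test_material, seawater, oil, resin):
        guess = sk.initial_operating_guess(foram_sphere, seawater, test_material)
        s2, s1, s3 = sk.plan_first_scales(guess, foram_sphere, 0.9, oil, resin)
        assert s2 < s1 < s3

    def test_no_wall_limit(self, foram_sphere, test_material, seawater, oil, resin):
        """With a huge tank the planned S1 solves the pure (wall-free) model
        constraint at the guessed operating point."""
        guess = sk.initial_operating_guess(foram_sphere, seawater, test_material)
        _, s1, _ = sk.plan_first_scales(guess, foram_sphere, 1e9, oil, resin)

        def residual(S):
            cdf = sk.cd_constraint_at_scale(
                guess.Re_O, S, foram_sphere, S**3 * foram_sphere.V, resin, oil
            )
            return cdf - guess.C_D_O

        assert residual(s1) == pytest.approx(0.0, abs=1e-8 * guess.C_D_O)

    def test_planned_s1_lands_near_guess(
        self, foram_sphere, test_material, seawater, oil, resin
    ):
        guess = sk.initial_operating_guess(foram_sphere, seawater, test_material)
        _, s1, _ = sk.plan_first_scales(guess, foram_sphere, 0.9, oil, resin)
        tank = quiet_tank(foram_sphere, test_material, oil, resin)
        rec = tank.sink(s1, "probe")
        point = sk.reduce_record(rec, foram_sphere, 0.9, oil, resin)
        assert point.Re == pytest.approx(guess.Re_O, rel=0.10)


class TestVolumePredictor:
    def test_cubic_scaling_from_single_pair(self):
        p = sk.VolumePredictor()
        p.add(10.0, 2.0e-6)
        assert p.predict(20.0) == pytest.approx(1.6e-5, rel=1e-12)

    def test_measured_scale_returns_measured_volume(self):
        p = sk.VolumePredictor()
        for s, v in [(5.0, 1.1e-7), (8.0, 4.9e-7), (11.0, 1.4e-6), (14.0, 2.9e-6)]:
            p.add(s, v)
        assert sk.predict_volume(p, 8.0) == 4.9e-7

    def test_spline_tracks_generating_rule(self):
        rule = lambda s: 1e-9 * s**3 * (1 + 0.5 / s)
        p = sk.VolumePredictor()
        for s in [4.0, 7.0, 10.0, 13.0, 16.0]:
            p.add(s, rule(s))
        for s in [5.5, 9.0, 12.0, 15.0]:
            assert p.predict(s) == pytest.approx(rule(s), rel=0.01)

    def test_no_data(self):
        with pytest.raises(InsufficientDataError):
            sk.VolumePredictor().predict(5.0)


class TestOperatingPoint:
    def _morrison_curve(self, lo=10.0, hi=100.0, n=7):
        res = np.logspace(np.log10(lo), np.log10(hi), n)
        return sk.fit_drag_spline(
            [sk.DragDataPoint(r, sk.morrison_cd(r)) for r in res], "cubic"
        )

    def test_sphere_recovery_oracle(self, foram_sphere, test_material, seawater):
        curve = self._morrison_curve()
        op = sk.solve_operating_point(curve, foram_sphere, seawater, test_material)
        re_oracle = bisect_terminal_re(foram_sphere, test_material, seawater,
                                       sk.morrison_cd)
        u_oracle = sk.speed_from_reynolds(re_oracle, foram_sphere.L, seawater)
        assert op.U_O == pytest.approx(u_oracle, rel=0.01)

    def test_more_drag_slower_sinking(self, foram_sphere, test_material, seawater):
        curve = self._morrison_curve()
        doubled = sk.fit_drag_spline(
            [sk.DragDataPoint(r, 2 * sk.morrison_cd(r))
             for r in np.logspace(1, 2, 7)],
            "cubic",
        )
        op = sk.solve_operating_point(curve, foram_sphere, seawater, test_material)
        op2 = sk.solve_operating_point(doubled, foram_sphere, seawater, test_material)
        assert op2.Re_O < op.Re_O

    def test_root_residual(self, foram_sphere, test_material, seawater):
        curve = self._morrison_curve()
        op = sk.solve_operating_point(curve, foram_sphere, seawater, test_material)
        cdf = sk.cd_force_balance(op.Re_O, foram_sphere, test_material, seawater)
        assert abs(cdf - curve.evaluate(op.Re_O)) / op.C_D_O < 1e-8

    def test_no_intersection(self, seawater):
        # a near-neutral dust grain never reaches the fitted high-Re curve
        grain = sk.ParticleGeometry.sphere(1e-6)
        light = sk.MaterialSpec(density=seawater.density + 0.1)
        curve = self._morrison_curve(lo=50.0, hi=100.0, n=5)
        with pytest.raises(NoIntersectionError):
            sk.solve_operating_point(curve, grain, seawater, light)


class TestNextScale:
    def test_deterministic(self, foram_sphere, test_material, seawater, oil, resin):
        op = sk.initial_operating_guess(foram_sphere, seawater, test_material)
        p = sk.VolumePredictor()
        p.add(8.0, 8.0**3 * foram_sphere.V)
        s_a = sk.next_scale(op, p, foram_sphere, 0.9, oil, resin)
        s_b = sk.next_scale(op, p, foram_sphere, 0.9, oil, resin)
        assert s_a == s_b

    def test_closed_loop_lands_on_target(
        self, foram_sphere, test_material, seawater, oil, resin
    ):
        op = sk.initial_operating_guess(foram_sphere, seawater, test_material)
        p = sk.VolumePredictor()
        p.add(8.0, 8.0**3 * foram_sphere.V)
        s = sk.next_scale(op, p, foram_sphere, 0.9, oil, resin)
        tank = quiet_tank(foram_sphere, test_material, oil, resin)
        rec = tank.sink(s, "probe")
        point = sk.reduce_record(rec, foram_sphere, 0.9, oil, resin)
        assert point.Re == pytest.approx(op.Re_O, rel=0.05)

    def test_weak_wall_sensitivity(
        self, foram_sphere, test_material, seawater, oil, resin
    ):
        op = sk.initial_operating_guess(foram_sphere, seawater, test_material)
        p = sk.VolumePredictor()
        p.add(8.0, 8.0**3 * foram_sphere.V)
        s_small_tank = sk.next_scale(op, p, foram_sphere, 0.9, oil, resin)
        s_big_tank = sk.next_scale(op, p, foram_sphere, 9.0, oil, resin)
        lam = s_small_tank * foram_sphere.L / 0.9
        assert lam < 0.02
        assert abs(s_small_tank - s_big_tank) / s_big_tank < 0.01


class TestConvergenceReport:
    def _op(self, re, extrapolated=False):
        return sk.OperatingPoint(Re_O=re, C_D_O=1.0, U_O=1.0,
                                 extrapolated=extrapolated)

    def _points(self, *res):
        return [sk.DragDataPoint(r, 1.0) for r in res]

    def test_clean_convergence(self):
        rep = sk.check_convergence(self._op(30.0), self._points(20, 30, 50),
                                   cubic_U=1.0, linear_U=1.0)
        assert rep.converged
        assert rep.criterion3_re_gap == 0.0

    def test_spline_variation_boundary(self):
        rep = sk.check_convergence(self._op(30.0), self._points(20, 30, 50),
                                   cubic_U=1.0, linear_U=1.06)
        assert rep.criterion2_spline_variation == pytest.approx(0.06)
        assert not rep.converged

    def test_extrapolated_blocks_convergence(self):
        rep = sk.check_convergence(self._op(30.0, extrapolated=True),
                                   self._points(20, 30, 50), 1.0, 1.0)
        assert not rep.converged

    def test_re_gap_criterion(self):
        rep = sk.check_convergence(self._op(100.0), self._points(20, 30, 50),
                                   1.0, 1.0)
        assert rep.criterion3_re_gap == pytest.approx(0.5)
        assert not rep.converged

    def test_needs_three_points(self):
        with pytest.raises(InsufficientDataError):
            sk.check_convergence(self._op(30.0), self._points(20, 30), 1.0, 1.0)


class TestRunEstimation:
    def test_noiseless_sphere_recovery(
        self, foram_sphere, test_material, seawater, oil, resin
    ):
        """Primary recovery oracle: the closed loop on a noiseless sphere
        reproduces the analytic terminal velocity to better than 0.5%."""
        tank = quiet_tank(foram_sphere, test_material, oil, resin)
        res = sk.run_estimation(foram_sphere, seawater, test_material, 0.9, oil,
                                resin, tank)
        re_oracle = bisect_terminal_re(foram_sphere, test_material, seawater,
                                       sk.morrison_cd)
        u_oracle = sk.speed_from_reynolds(re_oracle, foram_sphere.L, seawater)
        assert res.converged
        assert res.models_sunk >= 3
        assert res.operating_point.U_O == pytest.approx(u_oracle, rel=0.005)

    @pytest.mark.parametrize("factor,shift", [(0.7, 0.0), (1.5, 0.0),
                                              (1.0, 0.1), (1.0, -0.1)])
    def test_noiseless_perturbed_recovery(
        self, foram_sphere, test_material, seawater, oil, resin, factor, shift
    ):
        """Across perturbed ground truths, noiseless recovery is within 1%."""
        drag = sk.perturbed_cd(sk.MORRISON, factor, shift)
        tank = quiet_tank(foram_sphere, test_material, oil, resin, drag=drag)
        res = sk.run_estimation(foram_sphere, seawater, test_material, 0.9, oil,
                                resin, tank)
        _, _, u_true = sk.terminal_state(foram_sphere, test_material, seawater, drag)
        assert abs(res.operating_point.U_O - u_true) / u_true < 0.01

    def test_noiseless_converges_by_iteration_four(
        self, foram_sphere, test_material, seawater, oil, resin
    ):
        tank = quiet_tank(foram_sphere, test_material, oil, resin)
        res = sk.run_estimation(foram_sphere, seawater, test_material, 0.9, oil,
                                resin, tank)
        assert res.converged and res.models_sunk <= 4

    def test_deterministic_history(
        self, foram_sphere, test_material, seawater, oil, resin
    ):
        def run():
            tank = quiet_tank(foram_sphere, test_material, oil, resin,
                              cv=0.02, bias=0.3, seed=42)
            return sk.run_estimation(foram_sphere, seawater, test_material, 0.9,
                                     oil, resin, tank)

        a, b = run(), run()
        assert a.models_sunk == b.models_sunk
        assert a.operating_point == b.operating_point
        for ra, rb in zip(a.records, b.records):
            assert ra.replicate_speeds == rb.replicate_speeds

    def test_operating_point_is_true_root(
        self, foram_sphere, test_material, seawater, oil, resin
    ):
        tank = quiet_tank(foram_sphere, test_material, oil, resin, cv=0.01,
                          bias=0.3, seed=3)
        res = sk.run_estimation(foram_sphere, seawater, test_material, 0.9, oil,
                                resin, tank)
        op = res.operating_point
        curve = res.history[-1].curve_cubic
        cdf = sk.cd_force_balance(op.Re_O, foram_sphere, test_material, seawater)
        assert abs(cdf - curve.evaluate(op.Re_O)) / op.C_D_O < 1e-6

    def test_nonconvergence_flagged_not_silent(
        self, foram_sphere, test_material, seawater, oil, resin
    ):
        # an extreme printing-volume bias makes every model land far from its
        # planned Re, so the 15% criterion cannot be met within 3 models
        tank = quiet_tank(foram_sphere, test_material, oil, resin, cv=0.0,
                          bias=5.0)
        with pytest.warns(UserWarning, match="did not converge"):
            res = sk.run_estimation(foram_sphere, seawater, test_material, 0.9,
                                    oil, resin, tank, max_iter=3)
        assert not res.converged
        assert res.models_sunk == 3


class TestScaleSolver:
    def test_target_with_measured_volume_bias(
        self, foram_sphere, test_material, oil, resin
    ):
        """The scale solver accounts for a biased volume predictor."""
        rule = lambda s: s**3 * foram_sphere.V * (1 + 0.3 / s)
        s = _solve_scale_for_target(
            35.0, 1.8, rule, foram_sphere, 0.9, oil, resin
        )
        cdf = sk.cd_constraint_at_scale(35.0, s, foram_sphere, rule(s), resin, oil)
        lam = s * foram_sphere.L / 0.9
        assert cdf == pytest.approx(1.8 * sk.wall_factor_K(lam), rel=1e-9)
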