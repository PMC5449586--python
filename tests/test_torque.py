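"""Trap calibration, torque extraction and C_eff fitting."""

import math

import numpy as np
import pytest

from torquetweezers.containers import AngleTrace, RotationCurve
from torquetweezers.errors import FitError, InvalidInputError
from torquetweezers.params import BeadParams
from torquetweezers.pipeline import trace_to_curve
from torquetweezers.synthetic import (model_rotation_response,
                                      simulate_angle_segment,
                                      simulate_molecule,
                                      simulate_transverse_fluctuations)
from torquetweezers.torque import (TrapCalibration, build_torque_curve,
                                   calibrate_trap, equipartition_std,
                                   fit_ceff, force_from_transverse,
                                   torque_at_step)

from conftest import make_sim_config


def _segment(theta, turns=0.0, frame_rate=60.0, z=None):
    n = len(theta)
    return AngleTrace(t=np.arange(n) / frame_rate, theta=np.asarray(theta, float),
                      step_index=np.zeros(n, int), center=(0, 0), radius=300,
                      flags=np.zeros(n, bool), turns=turns, z=z,
                      frame_rate=frame_rate)


class TestCalibrateTrap:
    def test_unit_variance_gives_kbt(self, rng):
        theta = rng.choice([-1.0, 1.0], size=2000)   # Var = 1 exactly
        theta -= theta.mean()
        theta /= theta.std()
        cal = calibrate_trap(_segment(theta), kBT=4.1)
        assert cal.k_rot == pytest.approx(4.1, rel=1e-12)

    def test_instrument_stiffness_bounds_in_degrees(self):
        # the workable angular-trap range: stiff traps fluctuate < 4 deg,
        # soft traps > 20 deg
        assert math.degrees(equipartition_std(1000.0)) < 4.0
        assert math.degrees(equipartition_std(30.0)) > 20.0

    def test_recovers_generator_stiffness(self, rng):
        bead = BeadParams(k_rot=200.0, tau_c=0.5)
        seg = simulate_angle_segment(bead, 0.0, duration=200, frame_rate=60,
                                     seed=rng, kBT=4.1)
        seg.turns = 0.0
        cal = calibrate_trap(seg)
        assert cal.k_rot == pytest.approx(200.0, rel=0.10)
        assert cal.tau_c == pytest.approx(0.5, rel=0.3)

    def test_zero_variance_is_an_error(self):
        with pytest.raises(InvalidInputError, match="degenerate"):
            calibrate_trap(_segment(np.ones(500)))


class TestTorqueAtStep:
    def test_shift_times_stiffness(self):
        cal = TrapCalibration(k_rot=100.0, theta0=0.0, n_samples=1000,
                              std_theta=0.1, frame_rate=60.0)
        theta = -0.10 + 0.001 * np.sin(np.arange(500))
        tp = torque_at_step(_segment(theta - np.mean(theta) - 0.10), cal)
        assert tp.gamma == pytest.approx(10.0, rel=1e-9)

    def test_zero_shift_zero_torque(self):
        cal = TrapCalibration(k_rot=100.0, theta0=0.0, n_samples=1000,
                              std_theta=0.1)
        theta = 0.05 * np.sin(np.arange(500))
        theta -= theta.mean()
        tp = torque_at_step(_segment(theta), cal)
        assert tp.gamma == pytest.approx(0.0, abs=1e-9)

    def test_magnet_frame_correction(self):
        # a dwell at N = 2 whose mean sits exactly at theta0 + 2 pi N
        cal = TrapCalibration(k_rot=100.0, theta0=0.3, n_samples=1000,
                              std_theta=0.1)
        theta = 0.3 + 4 * math.pi + 0.01 * np.sin(np.arange(500))
        theta -= 0.01 * np.mean(np.sin(np.arange(500)))
        tp = torque_at_step(_segment(theta, turns=2.0), cal)
        assert tp.gamma == pytest.approx(0.0, abs=1e-6)

    def test_missing_calibration_raises(self):
        with pytest.raises(InvalidInputError):
            torque_at_step(_segment(np.zeros(10)), None)


class TestBuildTorqueCurve:
    def test_full_loop_recovery_against_generator(self, params, bead, rng):
        cfg = make_sim_config(force=3.5, turn_schedule=tuple(range(-10, 31)))
        trace, truth = simulate_molecule(params, bead, cfg, rng=rng)
        curve = trace_to_curve(trace, force=3.5)
        _, tau_true = model_rotation_response(params, 3.5,
                                              np.arange(-10, 31))
        z = (curve.torque - tau_true) / curve.torque_se
        # per-step agreement with the generator truth; the reference-step
        # error is a common offset shared by all steps
        z -= np.median(z)
        assert np.mean(np.abs(z) < 2.0) > 0.85
        assert np.max(np.abs(z)) < 5.0

    def test_nicked_tether_gives_zero_torque(self, params, bead, rng):
        cfg = make_sim_config(force=2.0, turn_schedule=tuple(range(-10, 11)),
                              dwell=50.0)
        trace, _ = simulate_molecule(params, bead, cfg, rng=rng,
                                     tether_class="nicked")
        curve = trace_to_curve(trace, force=2.0)
        z = curve.torque / curve.torque_se
        z -= np.median(z)
        assert np.mean(np.abs(z) < 3.0) > 0.9

    def test_strategies_identical_when_variances_equal(self):
        # hand-built segments with bit-identical variance: per-step and
        # reference-only calibration must coincide exactly
        pattern = np.tile([0.1, -0.1], 300)
        segs = []
        for N, shift in [(0, 0.0), (1, -0.02), (2, -0.04)]:
            theta = 2 * math.pi * N + shift + pattern
            segs.append(_segment(theta, turns=float(N),
                                 z=np.full(600, 2500.0)))
        c1 = build_torque_curve(segs, force=2.0, strategy="per-step")
        c2 = build_torque_curve(segs, force=2.0, strategy="reference-only")
        assert np.allclose(c1.torque, c2.torque, rtol=1e-9, atol=1e-9)
        # gamma = -k * shift with k = kBT / Var(pattern)
        k = 4.1 / np.var(pattern)
        assert c1.torque[1] == pytest.approx(k * 0.02, rel=1e-9)

    def test_unknown_strategy_raises(self):
        with pytest.raises(InvalidInputError):
            build_torque_curve([_segment(np.zeros(5))], force=1.0,
                               strategy="bogus")


class TestFitCeff:
    def _linear_curve(self, slope, n_points=21, se=0.01):
        N = np.arange(-(n_points // 2), n_points // 2 + 1, dtype=float)
        return RotationCurve(bead_id="t", N=N, extension=np.full_like(N, 2500),
                             extension_se=np.full_like(N, 1.0),
                             torque=slope * N,
                             torque_se=np.full_like(N, se), force=2.0)

    def test_exact_slope_inversion(self, params):
        # 0.9591 pN·nm/turn over L_C = 2686 nm at kBT = 4.1 -> C_eff = 100 nm
        est = fit_ceff(self._linear_curve(0.9591), params,
                       fit_region=(-10, 10))
        assert est.c_eff == pytest.approx(100.0, abs=0.01)
        assert "C_eff" in est.summary()

    def test_zero_torque_gives_zero(self, params):
        est = fit_ceff(self._linear_curve(0.0), params, fit_region=(-10, 10))
        assert est.c_eff == pytest.approx(0.0, abs=1e-9)

    def test_invariant_under_torque_offset(self, params):
        c = self._linear_curve(0.9591)
        c_off = self._linear_curve(0.9591)
        c_off.torque = c_off.torque + 3.7
        a = fit_ceff(c, params, fit_region=(-10, 10))
        b = fit_ceff(c_off, params, fit_region=(-10, 10))
        assert a.c_eff == pytest.approx(b.c_eff, rel=1e-12)
        assert b.intercept == pytest.approx(3.7, abs=1e-9)

    def test_auto_region_excludes_melting_plateau(self, params):
        N = np.arange(-30, 31, dtype=float)
        _, tau = model_rotation_response(params, 2.0, N)
        curve = RotationCurve(bead_id="t", N=N,
                              extension=np.full_like(N, 2500),
                              extension_se=np.ones_like(N),
                              torque=tau, torque_se=np.full(N.shape, 0.3),
                              force=2.0)
        est = fit_ceff(curve, params)
        lo, hi = est.fit_region
        # melting saturates torque beyond ~10.75 turns; the window must
        # exclude the deep plateau (2-turn onset resolution)
        assert hi <= 13.5
        assert est.c_eff == pytest.approx(
            97.0, rel=0.05)     # MN value at 2 pN

    def test_too_few_points_raises(self, params):
        with pytest.raises(FitError):
            fit_ceff(self._linear_curve(1.0), params, fit_region=(-0.5, 0.5))

    def test_monotone_torque_magnitude_in_linear_regime(self, params):
        N = np.arange(0, 11, dtype=float)
        _, tau = model_rotation_response(params, 2.0, N)
        assert np.all(np.diff(np.abs(tau)) >= 0)


class TestForceFromTransverse:
    def test_defining_formula(self):
        x = np.tile([-1.0, 1.0], 500) * math.sqrt(10250)
        x -= x.mean()
        assert force_from_transverse(x, extension=2500, kBT=4.1) == \
            pytest.approx(4.1 * 2500 / np.var(x), rel=1e-12)
        assert force_from_transverse(x, 2500) == pytest.approx(1.0, rel=1e-9)

    def test_halving_variance_doubles_force(self, rng):
        x = rng.normal(0, 10, 4000)
        f1 = force_from_transverse(x, 2500)
        f2 = force_from_transverse(x / math.sqrt(2), 2500)
        assert f2 == pytest.approx(2 * f1, rel=1e-9)

    def test_recovery_from_simulated_pendulum(self):
        x = simulate_transverse_fluctuations(force=3.5, extension=2500,
                                             duration=600, frame_rate=60,
                                             seed=4)
        assert force_from_transverse(x, 2500) == pytest.approx(3.5, rel=0.10)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(InvalidInputError):
            force_from_transverse(np.zeros(100), 2500)
        with pytest.raises(InvalidInputError):
            force_from_transverse(np.ones(100), -1.0)
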