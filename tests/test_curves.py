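"""Curve averaging, buckling observables, QC and power-law fits."""

import numpy as np
import pytest

from torquetweezers.containers import AveragedCurve, RotationCurve
from torquetweezers.curves import (align_and_average, buckling_torque,
                                   _bin_center, detect_buckling, extract_features,
                                   fit_lk0, fit_power_law, post_buckling_slope,
                                   qc_classify, supercoiling_density,
                                   torque_plateau)
from torquetweezers.errors import FitError, InvalidInputError
from torquetweezers.synthetic import model_rotation_response
from torquetweezers.wlc import marko_coexistence


def model_curve(params, force, N, bead_id="m", lk0=0.0, z_off=0.0,
                ext_noise=0.0, rng=None, se=0.5):
    """RotationCurve from the noiseless model response (+ optional noise)."""
    N = np.asarray(N, float)
    ext, tau = model_rotation_response(params, force, N - lk0)
    tau = tau - np.interp(0.0, N - lk0, tau)  # reference-subtracted
    if ext_noise and rng is not None:
        ext = ext + rng.normal(0, ext_noise, len(N))
    return RotationCurve(bead_id=bead_id, N=N, extension=ext + z_off,
                         extension_se=np.full(len(N), max(ext_noise, se)),
                         torque=tau, torque_se=np.full(len(N), se),
                         force=force)


class TestFitLk0:
    def test_symmetric_curve_centered_at_three(self, params):
        c = model_curve(params, 0.4, np.arange(-22, 23), lk0=3.0)
        assert fit_lk0(c) == pytest.approx(3.0, abs=0.05)

    def test_monte_carlo_stability_under_noise(self, params):
        rng = np.random.default_rng(1)
        centers = []
        for _ in range(20):
            c = model_curve(params, 0.4, np.arange(-22, 23), lk0=2.0,
                            ext_noise=10.0, rng=rng)
            centers.append(fit_lk0(c))
        assert np.std(centers) < 0.5
        assert np.mean(centers) == pytest.approx(2.0, abs=0.3)

    def test_flat_curve_raises(self, params):
        N = np.arange(-20, 21, dtype=float)
        flat = RotationCurve(bead_id="nick", N=N,
                             extension=np.full_like(N, 2500.0),
                             extension_se=np.ones_like(N),
                             torque=np.zeros_like(N),
                             torque_se=np.ones_like(N), force=0.4)
        with pytest.raises(FitError, match="flat|degenerate"):
            fit_lk0(flat)

    def test_shift_returns_centered_curve(self, params):
        c = model_curve(params, 0.4, np.arange(-22, 23), lk0=-4.0)
        lk0, shifted = fit_lk0(c, shift=True)
        assert lk0 == pytest.approx(-4.0, abs=0.05)
        i0 = np.argmin(np.abs(shifted.N))
        assert shifted.extension[i0] == pytest.approx(
            shifted.extension.max(), abs=1e-6)


class TestDetectBuckling:
    def test_first_departing_point_on_toy_curve(self):
        N = np.arange(0, 31, dtype=float)
        ext = np.where(N <= 15, 2500.0, 2500.0 - 40.0 * (N - 15))
        toy = AveragedCurve(N=N, extension=ext,
                            extension_std=np.zeros_like(N),
                            extension_sem=np.zeros_like(N),
                            torque=np.zeros_like(N),
                            torque_std=np.zeros_like(N),
                            torque_sem=np.zeros_like(N),
                            n_molecules=np.ones_like(N, int), force=2.0)
        assert detect_buckling(toy, side="positive") == 16.0

    def test_two_pn_model_curve_within_one_turn(self, params):
        c = model_curve(params, 2.0, np.arange(-30, 31), se=0.1)
        nb = detect_buckling(c, side="positive")
        assert abs(nb - marko_coexistence(params, 2.0).n_buck) <= 1.0
        nb_ref = detect_buckling(c, side="positive", refine=True)
        assert nb_ref == pytest.approx(19.47, abs=0.3)

    def test_no_buckling_at_high_force(self, params):
        c = model_curve(params, 6.5, np.arange(-15, 61), se=0.1)
        assert detect_buckling(c, side="positive") is None
        assert detect_buckling(c, side="positive", refine=True) is None

    def test_negative_side_at_low_force(self, params):
        c = model_curve(params, 0.4, np.arange(-25, 26), se=0.1)
        nb = detect_buckling(c, side="negative", refine=True)
        assert nb == pytest.approx(-marko_coexistence(params, 0.4).n_buck,
                                   abs=1.0)

    def test_invalid_side_raises(self, params):
        c = model_curve(params, 2.0, np.arange(-30, 31))
        with pytest.raises(InvalidInputError):
            detect_buckling(c, side="sideways")


class TestAlignAndAverage:
    def test_integer_offsets_are_removed_exactly(self, params):
        rng = np.random.default_rng(3)
        offsets = rng.integers(-5, 6, size=10)
        # each molecule's schedule is centered on its own (unknown) offset
        # so the curve is sampled symmetrically about its Lk0
        curves = [model_curve(params, 0.4, np.arange(-25, 26) + int(o),
                              lk0=int(o), bead_id=f"m{i}")
                  for i, o in enumerate(offsets)]
        avg = align_and_average(curves, force_regime="low")
        ref = model_curve(params, 0.4, np.arange(-25, 26))
        checked = 0
        for Nb, e, sem in zip(avg.N, avg.extension, avg.extension_sem):
            if abs(Nb) > 18:     # edge bins are only partially sampled
                continue
            sel = _bin_center(ref.N) == Nb
            assert e == pytest.approx(ref.extension[sel].mean(), abs=0.05)
            assert sem < 0.05
            checked += 1
        assert checked >= 15

    def test_averaging_identical_curves_gives_zero_sem(self, params):
        curves = [model_curve(params, 2.0, np.arange(-30, 31),
                              bead_id=f"m{i}") for i in range(5)]
        avg = align_and_average(curves, force_regime="high")
        assert np.allclose(avg.extension_sem, 0.0, atol=1e-9)
        assert np.allclose(avg.torque_sem, 0.0, atol=1e-9)

    def test_alignment_idempotence(self, params):
        curves = [model_curve(params, 0.4, np.arange(-25, 26),
                              bead_id=f"m{i}") for i in range(3)]
        a1 = align_and_average(curves, force_regime="low")
        recentered = [model_curve(params, 0.4, np.arange(-25, 26))
                      for _ in range(3)]
        a2 = align_and_average(recentered, force_regime="low")
        assert np.allclose(a1.extension, a2.extension, atol=1e-6)

    def test_two_turn_bin_centers(self):
        N = np.arange(-19, 21)
        centers = np.unique(_bin_center(N))
        # edges [2k-1, 2k+1): integer turns -19..20 fall into 20 bins
        assert centers[0] == -18.0 and centers[-1] == 20.0
        assert len(centers) == 20
        assert np.all(_bin_center(np.array([-1.0, 0.0, 0.99])) == 0.0)

    def test_mixed_forces_raise(self, params):
        c1 = model_curve(params, 0.4, np.arange(-20, 21))
        c2 = model_curve(params, 2.0, np.arange(-20, 21))
        with pytest.raises(InvalidInputError, match="mixed"):
            align_and_average([c1, c2])

    def test_single_curve_raises(self, params):
        with pytest.raises(InvalidInputError):
            align_and_average([model_curve(params, 0.4, np.arange(-20, 21))])


class TestPostBucklingObservables:
    def _toy_avg(self, slope=-40.0, nb=15.0, plateau=18.1):
        N = np.arange(-30, 31, dtype=float)
        ext = np.where(N <= nb, 2500.0, 2500.0 + slope * (N - nb))
        tau = np.clip(0.93 * N, -10.0, plateau)
        z = np.zeros_like(N)
        return AveragedCurve(N=N, extension=ext, extension_std=z,
                             extension_sem=z + 0.1, torque=tau,
                             torque_std=z, torque_sem=z + 0.1,
                             n_molecules=np.full(len(N), 10), force=2.0)

    def test_exact_slope_recovered(self):
        slope, se = post_buckling_slope(self._toy_avg(), 15.0)
        assert slope == pytest.approx(-40.0, rel=1e-9)

    def test_insufficient_points_raise(self):
        with pytest.raises(FitError):
            post_buckling_slope(self._toy_avg(), 28.0)

    def test_slope_magnitude_decreases_with_force(self, params):
        # coexistence prediction: plectonemes absorb less length per turn
        # at higher force
        s04 = marko_coexistence(params, 0.4).slope
        s2 = marko_coexistence(params, 2.0).slope
        assert abs(s04) > abs(s2)

    def test_buckling_torque_is_plateau_mean(self):
        tau, se = buckling_torque(self._toy_avg(), 19.5)
        assert tau == pytest.approx(18.1, abs=1e-9)

    def test_buckling_torque_needs_plateau(self):
        with pytest.raises(FitError):
            buckling_torque(self._toy_avg(), 29.0)

    def test_melting_plateau_from_torque_channel(self):
        tau, se = torque_plateau(self._toy_avg(), side="negative")
        assert tau == pytest.approx(-10.0, abs=0.05)

    def test_torque_plateau_rejects_pure_linear_curve(self):
        N = np.arange(-15, 16, dtype=float)
        z = np.zeros_like(N)
        lin = AveragedCurve(N=N, extension=z + 2500, extension_std=z,
                            extension_sem=z + 0.1, torque=0.9 * N,
                            torque_std=z, torque_sem=z + 0.1,
                            n_molecules=np.full(len(N), 10), force=6.5)
        with pytest.raises(FitError):
            torque_plateau(lin, side="positive")


class TestSupercoilingDensity:
    def test_values_and_linearity(self, params):
        assert supercoiling_density(0.0, params) == 0.0
        # 7900 bp / 10.5 bp per turn = 752.4 turns in the relaxed helix
        assert supercoiling_density(7.524, params) == pytest.approx(
            0.01, abs=1e-4)
        N = np.arange(10)
        assert np.allclose(supercoiling_density(N, params),
                           N * supercoiling_density(1.0, params))


class TestQcClassify:
    def _responses(self, params, tether_class):
        z = {}
        for force, turns in ((5.0, (-20, 0)), (0.6, (-20, 0, 20))):
            if tether_class == "good":
                ext, _ = model_rotation_response(params, force, turns)
            else:
                from torquetweezers.synthetic import _class_response
                ext, _ = _class_response(params, force,
                                         np.asarray(turns, float),
                                         tether_class)
            z[force] = dict(zip(turns, ext))
        contour = (z[5.0][0], 30.0)                   # ~zero-force extension
        multi = (z[5.0][0], z[5.0][-20])
        coil = (z[0.6][0], z[0.6][20], z[0.6][-20])
        return contour, multi, coil

    @pytest.mark.parametrize("cls", ["good", "nicked", "multi_tether"])
    def test_generator_classes_recovered(self, params, cls):
        contour, multi, coil = self._responses(params, cls)
        assert qc_classify(contour, multi, coil, params) == cls

    def test_stuck_bead_detected(self, params):
        contour, multi, coil = self._responses(params, "good")
        assert qc_classify((500.0, 400.0), multi, coil, params) == "stuck"

    def test_missing_test_gives_unknown(self, params):
        contour, multi, coil = self._responses(params, "good")
        assert qc_classify(None, multi, coil, params) == "unknown"


class TestFitPowerLaw:
    def test_exact_power_law(self):
        F = np.array([0.3, 0.5, 1, 2, 4, 6.5])
        pre, expo, se = fit_power_law(F, 2.0 * F ** 0.5)
        assert pre == pytest.approx(2.0, rel=1e-9)
        assert expo == pytest.approx(0.5, abs=1e-12)

    def test_constant_gives_zero_exponent(self):
        pre, expo, _ = fit_power_law([1, 2, 4], [3.0, 3.0, 3.0])
        assert expo == pytest.approx(0.0, abs=1e-12)
        assert pre == pytest.approx(3.0, rel=1e-9)

    def test_monte_carlo_exponent_unbiased(self):
        rng = np.random.default_rng(9)
        F = np.array([0.3, 0.5, 1, 2, 4, 6.5])
        expos = []
        for _ in range(100):
            y = 1.7 * F ** 0.72 * (1 + 0.05 * rng.normal(size=6))
            expos.append(fit_power_law(F, y)[1])
        se_mean = np.std(expos) / 10
        assert np.mean(expos) == pytest.approx(0.72, abs=2 * max(se_mean, 0.01))

    def test_nonpositive_values_raise(self):
        with pytest.raises(InvalidInputError):
            fit_power_law([1, 2, 3], [1.0, -2.0, 3.0])
        with pytest.raises(InvalidInputError):
            fit_power_law([1, 2], [1.0, 2.0])


def test_extract_features_two_pn_model_curve(params):
    curves = [model_curve(params, 2.0, np.arange(-30, 31), bead_id=f"m{i}")
              for i in range(3)]
    avg = align_and_average(curves, force_regime="high")
    feats = extract_features(avg, params)
    mk = marko_coexistence(params, 2.0)
    assert feats.n_buck_pos == pytest.approx(mk.n_buck, abs=1.0)
    assert feats.slope_post == pytest.approx(mk.slope, rel=0.05)
    assert feats.tau_buck == pytest.approx(mk.tau_buck, abs=0.3)
    assert feats.tau_melt_obs == pytest.approx(-10.0, abs=0.3)
    assert feats.sigma_buck == pytest.approx(mk.sigma_s, rel=0.06)
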