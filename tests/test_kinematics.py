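"""Strain-rate, tortuosity and recoil statistics with synthetic ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from blastofold.kinematics import (
    KymographSeries,
    OutlineTrace,
    VelocityField,
    make_synthetic_kymograph,
    make_synthetic_outline,
    make_synthetic_velocity_field,
    read_velocity_field_csv,
    recoil_velocity,
    region_mean_strain,
    strain_rate,
    tortuosity,
    write_velocity_field_csv,
)


class TestStrainRate:
    @pytest.mark.parametrize("a", [0.5, -0.3, 2.0])
    def test_pure_dilation(self, a):
        field, _ = make_synthetic_velocity_field(divergence=2 * a)
        E = strain_rate(field).E
        np.testing.assert_allclose(E, abs(a), rtol=1e-10)

    @pytest.mark.parametrize("c", [0.4, -1.2])
    def test_simple_shear(self, c):
        # v = (c*y, 0): divergence 0, dvx/dy = c -> E = |c|/2
        ny, nx = 15, 17
        Y = np.arange(ny)[:, None] * np.ones((1, nx))
        field = VelocityField(vx=c * Y, vy=np.zeros((ny, nx)), spacing=1.0)
        np.testing.assert_allclose(strain_rate(field).E, abs(c) / 2, rtol=1e-10)

    def test_rigid_rotation_is_silent(self):
        field, E_true = make_synthetic_velocity_field(rotation=1.7)
        assert E_true == 0.0
        np.testing.assert_allclose(strain_rate(field).E, 0.0, atol=1e-12)

    def test_translation_invariance(self):
        field, _ = make_synthetic_velocity_field(divergence=0.6, shear=0.4, seed=1)
        shifted = VelocityField(vx=field.vx + 3.3, vy=field.vy - 1.1,
                                spacing=field.spacing)
        np.testing.assert_allclose(strain_rate(shifted).E, strain_rate(field).E,
                                   rtol=1e-12)

    def test_combined_components_ground_truth(self):
        field, E_true = make_synthetic_velocity_field(
            divergence=0.8, shear=-0.5, rotation=0.9)
        assert E_true == pytest.approx(abs(0.4 - 0.25))
        np.testing.assert_allclose(strain_rate(field).E, E_true, rtol=1e-9)

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            strain_rate(VelocityField(vx=np.zeros((2, 5)), vy=np.zeros((2, 5))))

    def test_noisy_monte_carlo_recovery(self):
        # mean recovered E over interior cells across seeds within 3 SE
        true_E = 0.5
        sigma = 0.05
        vals = []
        for seed in range(100):
            field, _ = make_synthetic_velocity_field(
                divergence=1.0, noise_sigma=sigma, grid=(21, 21), seed=seed)
            vals.append(strain_rate(field).E[5:-5, 5:-5].mean())
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        # noise inflates |.| slightly; the bias is far below 3 SE here
        assert abs(np.mean(vals) - true_E) < 3 * se + 0.01


class TestRegionMean:
    def test_uniform(self):
        m = strain_rate(make_synthetic_velocity_field(divergence=0.6)[0])
        assert region_mean_strain(m, (0, 5, 0, 7)) == pytest.approx(0.3)

    def test_split_region_average(self):
        from blastofold.kinematics import StrainRateMap
        E = np.zeros((10, 10))
        E[:, 5:] = 0.4
        assert region_mean_strain(StrainRateMap(E=E), (0, 10, 0, 10)) == pytest.approx(0.2)

    def test_matches_brute_force(self):
        from blastofold.kinematics import StrainRateMap
        rng = np.random.default_rng(7)
        E = np.abs(rng.normal(size=(12, 9)))
        region = (2, 8, 1, 7)
        total = sum(E[r, c] for r in range(2, 8) for c in range(1, 7))
        assert region_mean_strain(StrainRateMap(E=E), region) == pytest.approx(
            total / 36)

    def test_empty_region_rejected(self):
        from blastofold.kinematics import StrainRateMap
        with pytest.raises(ValueError):
            region_mean_strain(StrainRateMap(E=np.ones((5, 5))), (3, 3, 0, 5))


class TestTortuosity:
    def test_straight_line(self):
        pts = np.column_stack([np.linspace(0, 4, 50), np.linspace(0, 1, 50)])
        assert tortuosity(OutlineTrace(points=pts)) == pytest.approx(1.0, rel=1e-12)

    def test_half_circle(self):
        u = np.linspace(0, np.pi, 5001)
        pts = np.column_stack([np.cos(u), np.sin(u)])
        assert tortuosity(OutlineTrace(points=pts)) == pytest.approx(
            np.pi / 2, rel=1e-3)

    def test_sine_wave_against_quadrature(self):
        trace, true_tort = make_synthetic_outline(amplitude=0.3, wavelength=1.0,
                                                  n_periods=2)
        assert tortuosity(trace) == pytest.approx(true_tort, rel=1e-4)

    @given(angle=st.floats(0, 2 * np.pi), scale=st.floats(0.1, 10.0),
           tx=st.floats(-5, 5), ty=st.floats(-5, 5))
    @settings(max_examples=30, deadline=None)
    def test_rigid_motion_and_scaling_invariance(self, angle, scale, tx, ty):
        trace, _ = make_synthetic_outline(amplitude=0.25, n_points=301)
        R = np.array([[np.cos(angle), -np.sin(angle)],
                      [np.sin(angle), np.cos(angle)]])
        moved = OutlineTrace(points=scale * trace.points @ R.T + [tx, ty])
        assert tortuosity(moved) == pytest.approx(tortuosity(trace), rel=1e-9)

    def test_coincident_endpoints_rejected(self):
        u = np.linspace(0, 2 * np.pi, 100)
        pts = np.column_stack([np.cos(u), np.sin(u)])
        pts[-1] = pts[0]  # exactly closed loop
        loop = OutlineTrace(points=pts)
        with pytest.raises(ValueError):
            tortuosity(loop)


class TestRecoilVelocity:
    def test_noiseless_linear_exact(self):
        series = make_synthetic_kymograph(slope=0.2, intercept=5.0)
        assert recoil_velocity(series) == pytest.approx(0.2, rel=1e-12)

    def test_constant_series_zero(self):
        series = make_synthetic_kymograph(slope=0.0, intercept=3.0)
        assert recoil_velocity(series) == pytest.approx(0.0, abs=1e-14)

    def test_window_restricts_fit(self):
        # distance kinks after 30 s; the fit must ignore the late branch
        t = np.arange(0.0, 60.0, 1.0)
        d = np.where(t <= 30, 5 + 0.2 * t, 5 + 0.2 * 30 - 1.0 * (t - 30))
        assert recoil_velocity(KymographSeries(time=t, distance=d),
                               window=30.0) == pytest.approx(0.2, rel=1e-10)

    def test_too_few_samples_rejected(self):
        s = KymographSeries(time=np.array([0.0, 40.0, 80.0]),
                            distance=np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError):
            recoil_velocity(s, window=30.0)

    def test_monte_carlo_within_analytic_standard_error(self):
        # OLS sampling distribution: Var(slope) = sigma^2 / sum((t - tbar)^2)
        sigma, true_slope, n_trials = 0.3, 0.2, 100
        t = np.arange(0.0, 30.0 + 0.1, 0.2)
        se_single = sigma / np.sqrt(np.sum((t - t.mean()) ** 2))
        slopes = [recoil_velocity(make_synthetic_kymograph(
            slope=true_slope, noise_sigma=sigma, seed=s)) for s in range(n_trials)]
        assert abs(np.mean(slopes) - true_slope) < 3 * se_single / np.sqrt(n_trials)
        assert np.std(slopes, ddof=1) == pytest.approx(se_single, rel=0.35)


class TestFieldIO:
    def test_round_trip(self, tmp_path):
        field, _ = make_synthetic_velocity_field(divergence=0.4, shear=0.2,
                                                 noise_sigma=0.01, grid=(8, 11),
                                                 spacing=2.5, seed=3)
        path = tmp_path / "field.csv"
        write_velocity_field_csv(field, path)
        back = read_velocity_field_csv(path)
        np.testing.assert_allclose(back.vx, field.vx, rtol=1e-12)
        np.testing.assert_allclose(back.vy, field.vy, rtol=1e-12)
        assert back.spacing == pytest.approx(2.5)
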