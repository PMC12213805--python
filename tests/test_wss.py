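"""Wall shear stress, TAWSS, regional averaging and the voxel estimator."""

import numpy as np
import pytest

from pulmoflow import flowquant as fq, phantom, solver as sv, windkessel as wk, wss
from pulmoflow.segmentation import LPA, MPA, RPA

MU = 3.5e-3


@pytest.fixture(scope="module")
def steady_field():
    R, L, Q, T = 0.01, 0.08, 1e-4, 0.8
    t = np.arange(160) / 160 * T
    wf = fq.FlowWaveform(times=t, flow_rate=np.full(160, Q), period=T)
    cfg = sv.SolverConfig(nr=32, nz=32, dt=0.0025, periodicity_tolerance=0.05, n_cycles_max=8)
    res = sv.simulate_pulsatile_tube(
        R, L, wf, MU, wk.WindkesselParams(r1=5e6, r2=2e7, c=3e-8), cfg
    )
    return res.final_cycle, R, Q


class TestWallShearStress:
    def test_poiseuille_value(self, steady_field):
        field, R, Q = steady_field
        series = wss.wall_shear_stress(field, MU)
        # mu = 3.5e-3, Q = 1e-4, R = 0.01 -> 0.4456 Pa
        assert series[-1][16] == pytest.approx(0.4456, rel=0.02)

    def test_zero_flow_gives_zero_wss(self, steady_field):
        field, _, _ = steady_field
        import dataclasses

        quiet = dataclasses.replace(field, wall_shear_rate=np.zeros_like(field.wall_shear_rate))
        assert np.all(wss.wall_shear_stress(quiet, MU) == 0)

    def test_womersley_wall_series_within_5pct(self):
        R, L, T = 0.01, 0.08, 0.8
        c = np.array([8e-5 + 0j, 4e-5 + 0j])
        t = np.arange(200) / 200 * T
        wf = fq.FlowWaveform(
            times=t, flow_rate=phantom.waveform_from_harmonics(t, c, T), period=T
        )
        cfg = sv.SolverConfig(nr=64, nz=32, dt=0.0025, periodicity_tolerance=0.2, n_cycles_max=10)
        res = sv.simulate_pulsatile_tube(
            R, L, wf, MU, wk.WindkesselParams(r1=1e7, r2=6e7, c=1.2e-8), cfg
        )
        f = res.final_cycle
        series = wss.wall_shear_stress(f, MU)[:, f.u.shape[2] // 2]
        exact = MU * phantom.womersley_wall_shear_rate(f.times % T, c, R, MU / 1060.0, T)
        assert np.linalg.norm(series - exact) / np.linalg.norm(exact) < 0.05


class TestTawss:
    def test_constant_series(self):
        t = np.arange(100) / 100 * 0.8
        series = np.full((100, 5), 1.62)
        np.testing.assert_allclose(wss.tawss(series, t, 0.8), 1.62)

    def test_rectified_sine_mean(self):
        T, A = 0.8, 2.5
        t = np.arange(4000) / 4000 * T
        series = A * np.sin(2 * np.pi * t / T)[:, None]
        assert wss.tawss(series, t, T)[0] == pytest.approx(2 * A / np.pi, rel=1e-4)

    def test_invariant_to_time_origin_shift(self):
        T = 0.8
        t = np.arange(400) / 400 * T
        base = (1.0 + np.sin(2 * np.pi * t / T) + 0.3 * np.cos(4 * np.pi * t / T))[:, None]
        shifted = np.roll(base, 137, axis=0)
        assert wss.tawss(base, t, T)[0] == pytest.approx(wss.tawss(shifted, t, T)[0], rel=1e-9)

    def test_incomplete_cycle_rejected(self):
        t = np.arange(50) / 100 * 0.8  # half a cycle
        with pytest.raises(ValueError):
            wss.tawss(np.ones((50, 3)), t, 0.8)


class TestRegionalAverage:
    def test_uniform_map(self):
        vals = np.full(30, 1.7)
        regs = np.repeat([MPA, LPA, RPA], 10)
        assert wss.regional_average(vals, regs, "MPA") == pytest.approx(1.7)
        assert wss.regional_average(vals, regs, "MPA+LPA+RPA") == pytest.approx(1.7)

    def test_weighted_mean_example(self):
        # 1 Pa on the MPA, 2 Pa on branches with equal areas
        vals = np.array([1.0, 2.0, 2.0])
        regs = np.array([MPA, LPA, RPA])
        areas = np.array([2.0, 1.0, 1.0])
        assert wss.regional_average(vals, regs, "MPA", areas) == 1.0
        assert wss.regional_average(vals, regs, "MPA+LPA+RPA", areas) == pytest.approx(1.5)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            wss.regional_average(np.ones(3), np.full(3, LPA), "MPA")

    def test_printed_whole_geometry_always_exceeds_mpa_only(self, printed_cohort):
        assert (printed_cohort["tawss_whole_pa"] >= printed_cohort["tawss_mpa_pa"]).all()


class TestVoxelEstimator:
    def test_single_voxel_fit_underestimates_by_parabolic_factor(self):
        """For steady Poiseuille flow a one-voxel fit at wall distance d
        recovers slope = gamma_w (1 - d/(2R)) exactly."""
        q0 = 6e-5
        spec = phantom.PhantomSpec(waveform_harmonics=(q0 + 0j,), noise_sd=0.0)
        study = phantom.generate_flow_study(spec)
        geom = study.meta["geometry"]
        df = wss.voxel_wss_estimate(study, geom, fit_depth=1, mu_ref=MU)
        mpa = df[df.region == MPA]
        R_mm = spec.mpa_radius * 1000
        gamma_w = 4 * q0 / (np.pi * spec.mpa_radius**3)
        predicted = MU * gamma_w * (1 - mpa.mean_depth_mm / (2 * R_mm))
        # interior voxel centres sample the analytic parabola exactly
        np.testing.assert_allclose(mpa.tawss, predicted, rtol=0.06)

    def test_linear_shear_layer_recovered_exactly(self):
        """A velocity field linear in wall distance has no resolution
        bias: the regression recovers the slope at any voxel size."""
        spec = phantom.PhantomSpec()
        geom = phantom.generate_bifurcation_geometry(spec, (2.5, 2.5, 2.5))
        layout = geom.meta["layout"]
        coff = geom.meta["center_offset"]
        sp = np.asarray(geom.spacing)
        shape = geom.mask.shape
        slope = 50.0  # 1/s
        grids = np.meshgrid(*[(np.arange(n) + 0.5) * s for n, s in zip(shape, sp)], indexing="ij")
        pts = np.stack([g.ravel() for g in grids], axis=1) - coff
        region, rho_mm, radius_mm, axis_dir = phantom._classify_points(pts, layout)
        d_m = np.clip((radius_mm - rho_mm), 0, None) * 1e-3
        u = np.where(region > 0, slope * d_m, 0.0)
        vel = u[:, None] * axis_dir
        phase = np.tile(vel.T.reshape(1, 3, *shape), (12, 1, 1, 1, 1))
        study = phantom.FlowMRIStudy(
            voxel_spacing=tuple(sp),
            frame_times=np.arange(12) / 12 * spec.period,
            magnitude=np.ones((12, *shape)),
            phase_velocity=phase,
            venc=1.5,
            period=spec.period,
        )
        df = wss.voxel_wss_estimate(study, geom, fit_depth=2, mu_ref=MU)
        # recovery is exact for a planar wall; on a cylinder the only
        # residual is wall curvature (off-ray voxel centres sit closer
        # to the wall than their ray projection), tight on the
        # large-radius MPA and bounded on the branches
        np.testing.assert_allclose(df[df.region == MPA].tawss, MU * slope, rtol=0.01)
        np.testing.assert_allclose(df.tawss, MU * slope, rtol=0.10)

    def test_coarse_tawss_below_fine(self, default_study, default_geometry, default_spec):
        df = wss.voxel_wss_estimate(default_study, default_geometry, mu_ref=MU)
        for region in (MPA, LPA, RPA):
            coarse = df[df.region == region].tawss.mean()
            fine = wss.phantom_reference_tawss(default_spec, MU, region)
            assert coarse < fine

    def test_invalid_fit_depth_rejected(self, default_study, default_geometry):
        with pytest.raises(ValueError):
            wss.voxel_wss_estimate(default_study, default_geometry, fit_depth=0)


class TestResolutionBias:
    def test_equal_inputs(self):
        ratio, gap = wss.resolution_bias(1.5, 1.5)
        assert ratio == 1.0 and gap == 0.0

    def test_printed_plane_summary_ratio(self):
        t4 = phantom.load_plane_tawss_summary()
        ratio, _ = wss.resolution_bias(
            t4.loc["MPA", "cfd_mean_pa"], t4.loc["MPA", "flow4d_mean_pa"]
        )
        assert ratio == pytest.approx(0.11 / 1.72, rel=1e-9)

    def test_zero_fine_reported_as_nan(self):
        ratio, _ = wss.resolution_bias(0.0, 0.1)
        assert np.isnan(ratio)
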