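"""Phantom generator: Womersley analytics, geometry, study sampling, fixture."""

import numpy as np
import pytest

from pulmoflow import phantom
from pulmoflow.segmentation import LPA, MPA, OUTSIDE, RPA


class TestWomersleyVelocity:
    def test_poiseuille_limit_steady_harmonic(self):
        q0 = 1.0e-4
        R, nu, T = 0.01, 3.3e-6, 1.0
        r = np.linspace(0, R, 50)
        u = phantom.womersley_velocity(r, 0.3, np.array([q0 + 0j]), R, nu, T)
        expected = 2.0 * q0 / (np.pi * R**2) * (1 - (r / R) ** 2)
        np.testing.assert_allclose(u, expected, rtol=1e-12)

    def test_no_slip_at_wall(self, default_spec):
        c = default_spec.harmonics
        for t in np.linspace(0, default_spec.period, 7, endpoint=False):
            u = phantom.womersley_velocity(
                default_spec.mpa_radius, t, c, default_spec.mpa_radius, default_spec.nu, default_spec.period
            )
            assert abs(u) < 1e-12

    @pytest.mark.parametrize("t_frac", [0.05, 0.2, 0.5, 0.8])
    def test_cross_section_integral_recovers_flow(self, default_spec, t_frac):
        """Quadrature of the profile equals the prescribed Q(t) within 0.5%."""
        c = default_spec.harmonics
        R, nu, T = default_spec.mpa_radius, default_spec.nu, default_spec.period
        t = t_frac * T
        r = np.linspace(0, R, 4001)
        u = phantom.womersley_velocity(r, t, c, R, nu, T)
        q_int = np.trapezoid(u * 2 * np.pi * r, r)
        q_ref = phantom.waveform_from_harmonics(np.array([t]), c, T)[0]
        assert q_int == pytest.approx(q_ref, abs=0.005 * np.abs(c[0]))

    def test_wall_shear_rate_matches_numerical_derivative(self, default_spec):
        c = default_spec.harmonics
        R, nu, T = default_spec.mpa_radius, default_spec.nu, default_spec.period
        h = 1e-7
        ts = np.linspace(0, T, 9, endpoint=False)
        g_an = phantom.womersley_wall_shear_rate(ts, c, R, nu, T)
        for t, ga in zip(ts, g_an):
            gn = (
                phantom.womersley_velocity(R - h, t, c, R, nu, T)
                - phantom.womersley_velocity(R, t, c, R, nu, T)
            ) / h
            assert ga == pytest.approx(gn, rel=1e-3, abs=1e-2)

    def test_radial_domain_enforced(self, default_spec):
        with pytest.raises(ValueError):
            phantom.womersley_velocity(
                1.1 * default_spec.mpa_radius, 0.0, default_spec.harmonics,
                default_spec.mpa_radius, default_spec.nu, default_spec.period,
            )


class TestWaveform:
    def test_half_sine_integrates_to_stroke_volume(self):
        for sv, T in [(80.0, 0.8), (184.0, 0.92), (36.0, 0.69)]:
            c = phantom.half_sine_harmonics(sv, T)
            t = np.linspace(0, T, 4000, endpoint=False)
            q = phantom.waveform_from_harmonics(t, c, T)
            assert np.mean(q) * T * 1e6 == pytest.approx(sv, rel=1e-4)

    def test_half_sine_amplitude_closed_form(self):
        # peak of Q = A = 3*pi*SV/(2T), up to harmonic truncation
        sv, T = 95.0, 0.95
        c = phantom.half_sine_harmonics(sv, T, n_harmonics=40)
        t = np.linspace(0, T / 3, 2000)
        amp = 3 * np.pi * sv * 1e-6 / (2 * T)
        assert np.max(phantom.waveform_from_harmonics(t, c, T)) == pytest.approx(amp, rel=0.01)


class TestGeometry:
    def test_degenerate_straight_tube_is_all_mpa(self):
        spec = phantom.PhantomSpec(branch_radii=(0.0, 0.0175), branch_angles=(0.0, 0.0))
        geom = phantom.generate_bifurcation_geometry(spec)
        assert set(np.unique(geom.labels[geom.mask])) == {MPA}

    def test_cross_sectional_area_matches_circle(self):
        """Voxel-counted MPA cross-section within 10% of pi R^2."""
        spec = phantom.PhantomSpec(mpa_radius=0.015)
        geom = phantom.generate_bifurcation_geometry(spec, (2.5, 2.5, 2.5))
        k = 4  # slice inside the straight MPA segment
        count = geom.mask[k].sum()
        assert count * 2.5 * 2.5 == pytest.approx(np.pi * 15.0**2, rel=0.10)

    def test_labels_partition_mask(self, default_geometry):
        lab = default_geometry.labels
        mask = default_geometry.mask
        assert np.array_equal(lab != OUTSIDE, mask)
        assert set(np.unique(lab[mask])) == {MPA, LPA, RPA}

    def test_under_resolved_raises(self, default_spec):
        with pytest.raises(ValueError, match="under-resolved"):
            phantom.generate_bifurcation_geometry(default_spec, (8.0, 8.0, 8.0))


class TestStudyGeneration:
    def test_same_seed_is_bit_identical(self):
        spec = phantom.PhantomSpec(noise_sd=0.05, seed=7)
        a = phantom.generate_flow_study(spec)
        b = phantom.generate_flow_study(spec)
        np.testing.assert_array_equal(a.phase_velocity, b.phase_velocity)
        np.testing.assert_array_equal(a.magnitude, b.magnitude)

    def test_different_seed_changes_noise(self):
        a = phantom.generate_flow_study(phantom.PhantomSpec(noise_sd=0.05, seed=1))
        b = phantom.generate_flow_study(phantom.PhantomSpec(noise_sd=0.05, seed=2))
        assert not np.array_equal(a.phase_velocity, b.phase_velocity)

    def test_velocities_clipped_at_venc(self):
        spec = phantom.PhantomSpec(noise_sd=0.5, seed=3)
        study = phantom.generate_flow_study(spec)
        assert np.max(np.abs(study.phase_velocity)) <= spec.venc

    def test_peak_velocity_above_venc_fails(self):
        spec = phantom.PhantomSpec(stroke_volume_ml=184.0, period=0.92, venc=1.0)
        with pytest.raises(ValueError, match="venc"):
            phantom.generate_flow_study(spec)

    def test_too_few_frames_rejected(self, default_spec):
        with pytest.raises(ValueError):
            phantom.generate_flow_study(default_spec, n_frames=8)

    def test_magnitude_positive_inside_low_outside(self, default_study, default_geometry):
        inside = default_study.magnitude[0][default_geometry.mask]
        core = default_study.magnitude[0][default_geometry.labels == MPA]
        assert inside.max() == 1.0
        assert core.mean() > 0.8
        far_corner = default_study.magnitude[0][0, 0, 0]
        assert far_corner == 0.0

    def test_flux_balance_between_inlet_and_branches(self, default_study, default_geometry):
        """Net flux through inlet equals the branch fluxes combined
        (divergence-free phantom), within quadrature tolerance."""
        from pulmoflow import flowquant

        inlet = flowquant.flow_waveform(
            flowquant.extract_inlet_profile(default_study, default_geometry, weighting="support")
        )
        total_branch = 0.0
        for rid, name in ((RPA, "RPA"), (LPA, "LPA")):
            prof = flowquant.extract_inlet_profile(
                default_study, default_geometry, default_geometry.outlet_planes[name],
                region=None, weighting="support",
            )
            total_branch += abs(flowquant.flow_waveform(prof).mean_flow)
        assert total_branch == pytest.approx(inlet.mean_flow, rel=0.02)


class TestPrintedCohort:
    def test_selected_printed_values(self, printed_cohort):
        assert printed_cohort.loc["P1", "stroke_volume_ml"] == 95
        assert printed_cohort.loc["P3", "tawss_whole_pa"] == pytest.approx(3.62)
        assert printed_cohort.loc["P7", "rpa_fraction_4dflow"] == pytest.approx(0.69)
        assert printed_cohort.loc["P7", "rpa_fraction"] == pytest.approx(0.69)

    def test_cohort_shape_and_fraction_sums(self, printed_cohort):
        assert len(printed_cohort) == 7
        sums = printed_cohort["rpa_fraction_4dflow"] + printed_cohort["lpa_fraction_4dflow"]
        assert np.all(np.abs(sums - 1.0) <= 0.01)

    def test_plane_summary_regions(self):
        t4 = phantom.load_plane_tawss_summary()
        assert set(t4.index) == {"MPA", "RPA", "LPA"}
        assert (t4["flow4d_mean_pa"] < t4["cfd_mean_pa"]).all()
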