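"""Axisymmetric tube solver: analytic oracles and run control."""

import numpy as np
import pytest
from scipy.optimize import brentq

from pulmoflow import flowquant as fq, phantom, solver as sv, windkessel as wk
from pulmoflow.rheology import RheologyParams, quemada_viscosity

MU_N = 3.5e-3  # Newtonian reference viscosity, Pa s
RHO = 1060.0


def constant_waveform(q, period=0.8, n=160):
    t = np.arange(n) / n * period
    return fq.FlowWaveform(times=t, flow_rate=np.full(n, q), period=period)


def outlet_wk(r1=1e7, r2=6e7, c=1.2e-8):
    return wk.WindkesselParams(r1=r1, r2=r2, c=c)


@pytest.fixture(scope="module")
def steady_run():
    """Steady Newtonian flow, resistive (3EWK) outlet."""
    R, L, Q = 0.005, 0.06, 5e-6
    cfg = sv.SolverConfig(nr=32, nz=32, dt=0.005, periodicity_tolerance=0.05, n_cycles_max=8)
    res = sv.simulate_pulsatile_tube(R, L, constant_waveform(Q), MU_N, outlet_wk(), cfg)
    return res, R, L, Q


@pytest.fixture(scope="module")
def womersley_run():
    """Single-harmonic Newtonian pulsatile flow at the default grid."""
    R, L, T = 0.01, 0.08, 0.8
    c = np.array([8e-5 + 0j, 4e-5 + 0j])
    t = np.arange(200) / 200 * T
    wf = fq.FlowWaveform(times=t, flow_rate=phantom.waveform_from_harmonics(t, c, T), period=T)
    cfg = sv.SolverConfig(nr=64, nz=32, dt=0.0025, periodicity_tolerance=0.2, n_cycles_max=12)
    res = sv.simulate_pulsatile_tube(R, L, wf, MU_N, outlet_wk(), cfg)
    return res, R, T, c


class TestFlowRegime:
    def test_worked_example(self):
        rep = sv.assess_flow_regime(0.2, 0.03, 1060.0, 3.5e-3, 0.8)
        assert rep.re_peak == pytest.approx(1817, rel=0.01)
        assert rep.womersley_alpha == pytest.approx(23.1, rel=0.01)
        assert rep.critical_value == pytest.approx(150 * rep.womersley_alpha)
        assert rep.laminar

    def test_zero_velocity_is_laminar(self):
        assert sv.assess_flow_regime(0.0, 0.03).laminar

    def test_viscosity_scaling_law(self):
        a = sv.assess_flow_regime(0.2, 0.03, mu_ref=3.5e-3)
        b = sv.assess_flow_regime(0.2, 0.03, mu_ref=7.0e-3)
        assert a.re_peak / b.re_peak == pytest.approx(2.0)
        assert a.womersley_alpha / b.womersley_alpha == pytest.approx(np.sqrt(2.0))


class TestSteadyNewtonian:
    def test_velocity_profile_matches_poiseuille(self, steady_run):
        res, R, L, Q = steady_run
        f = res.final_cycle
        u = f.u[-1][:, f.u.shape[2] // 2]
        u_exact = 2 * Q / (np.pi * R**2) * (1 - (f.r / R) ** 2)
        assert np.linalg.norm(u - u_exact) / np.linalg.norm(u_exact) < 0.02

    def test_outlet_pressure_is_total_resistance_times_flow(self, steady_run):
        res, R, L, Q = steady_run
        p_out = res.final_cycle.outlet_pressure[-1]
        assert p_out == pytest.approx((1e7 + 6e7) * Q, rel=0.01)

    def test_wall_shear_stress_matches_4muQ_piR3(self, steady_run):
        res, R, L, Q = steady_run
        wss = MU_N * res.final_cycle.wall_shear_rate[-1][16]
        assert wss == pytest.approx(4 * MU_N * Q / (np.pi * R**3), rel=0.03)

    def test_poiseuille_wss_formula_value(self):
        # 4 mu Q / (pi R^3) for mu = 3.5e-3, Q = 1e-4, R = 0.01 -> 0.4456 Pa
        assert 4 * 3.5e-3 * 1e-4 / (np.pi * 0.01**3) == pytest.approx(0.4456, abs=5e-4)


class TestWomersleyOracle:
    def test_velocity_l2_within_5pct(self, womersley_run):
        res, R, T, c = womersley_run
        f = res.final_cycle
        k = f.u.shape[2] // 2
        u_exact = np.array(
            [phantom.womersley_velocity(f.r, t % T, c, R, MU_N / RHO, T) for t in f.times]
        )
        err = np.linalg.norm(f.u[:, :, k] - u_exact) / np.linalg.norm(u_exact)
        assert err < 0.05

    def test_wall_shear_l2_within_5pct(self, womersley_run):
        res, R, T, c = womersley_run
        f = res.final_cycle
        k = f.u.shape[2] // 2
        g_exact = phantom.womersley_wall_shear_rate(f.times % T, c, R, MU_N / RHO, T)
        err = np.linalg.norm(f.wall_shear_rate[:, k] - g_exact) / np.linalg.norm(g_exact)
        assert err < 0.05

    def test_instantaneous_mass_conservation(self, womersley_run):
        res, *_ = womersley_run
        f = res.final_cycle
        scale = np.max(np.abs(f.inlet_flow))
        assert np.max(np.abs(f.outlet_flow - f.inlet_flow)) / scale < 0.005


class TestQuemadaSteady:
    def test_wss_matches_1d_generalized_newtonian_bvp(self):
        """Independent oracle: steady pipe flow with tau(r) = G r/2;
        solve mu(g)g = tau pointwise, integrate for u, shoot on G to
        match the flow rate."""
        rp = RheologyParams()
        R, L, Q, T = 0.005, 0.06, 3e-6, 0.8

        rr = np.linspace(0, R, 401)

        def gam_of_tau(tau):
            return 0.0 if tau <= 0 else brentq(
                lambda g: quemada_viscosity(g, rp) * g - tau, 1e-9, 1e7
            )

        def flow_given_G(G):
            g = np.array([gam_of_tau(G * r / 2) for r in rr])
            u = np.concatenate(
                [[0.0], np.cumsum((g[::-1][:-1] + g[::-1][1:]) / 2 * np.diff(rr))]
            )[::-1]
            return np.trapezoid(u * 2 * np.pi * rr, rr), g[-1]

        G = brentq(lambda G: flow_given_G(G)[0] - Q, 1.0, 1e6)
        gw = flow_given_G(G)[1]
        wss_oracle = quemada_viscosity(gw, rp) * gw

        cfg = sv.SolverConfig(nr=64, nz=32, dt=0.005, periodicity_tolerance=0.05, n_cycles_max=10)
        res = sv.simulate_pulsatile_tube(R, L, constant_waveform(Q, T), rp, outlet_wk(), cfg)
        gw_num = np.abs(res.final_cycle.wall_shear_rate[-1][24])
        wss_num = quemada_viscosity(gw_num, rp) * gw_num
        assert wss_num == pytest.approx(wss_oracle, rel=0.03)

    def test_newtonian_limit_of_quemada(self):
        """phi = 0 Quemada reproduces the constant-viscosity solution."""
        rp0 = RheologyParams(hematocrit=0.0, plasma_viscosity=MU_N)
        R, L, Q = 0.005, 0.06, 5e-6
        cfg = sv.SolverConfig(nr=32, nz=32, dt=0.005, periodicity_tolerance=0.05, n_cycles_max=8)
        a = sv.simulate_pulsatile_tube(R, L, constant_waveform(Q), rp0, outlet_wk(), cfg)
        b = sv.simulate_pulsatile_tube(R, L, constant_waveform(Q), MU_N, outlet_wk(), cfg)
        np.testing.assert_allclose(a.final_cycle.u[-1], b.final_cycle.u[-1], atol=1e-10)


class TestRunControl:
    def test_periodicity_metric_decays_geometrically(self):
        R, L, T = 0.005, 0.06, 0.8
        spec = phantom.PhantomSpec(period=T, stroke_volume_ml=8.0)
        t = np.arange(160) / 160 * T
        wf = fq.FlowWaveform(
            times=t, flow_rate=phantom.waveform_from_harmonics(t, spec.harmonics, T), period=T
        )
        cfg = sv.SolverConfig(
            nr=24, nz=32, dt=0.002, periodicity_tolerance=1e-6, n_cycles_max=7
        )
        res = sv.simulate_pulsatile_tube(R, L, wf, MU_N, outlet_wk(), cfg, pc0=0.0)
        m = np.array(res.cycle_metrics)
        assert np.all(m[1:] < m[:-1])
        ratios = m[1:] / m[:-1]
        assert np.all(ratios < 0.6)  # geometric decay

    def test_converged_final_cycle_contract(self, steady_run):
        res = steady_run[0]
        field, metric = sv.converged_final_cycle(res)
        assert metric < res.config.periodicity_tolerance
        assert field.u.shape[0] == len(field.times)

    def test_converged_final_cycle_raises_when_not_periodic(self):
        R, L, T = 0.005, 0.06, 0.8
        wf = constant_waveform(5e-6, T)
        cfg = sv.SolverConfig(
            nr=16, nz=32, dt=0.005, periodicity_tolerance=1e-10, n_cycles_max=3
        )
        res = sv.simulate_pulsatile_tube(R, L, wf, MU_N, outlet_wk(), cfg, pc0=0.0)
        with pytest.raises(RuntimeError, match="not periodic"):
            sv.converged_final_cycle(res)

    def test_cfl_violation_named(self):
        R, L, T = 0.005, 0.03, 0.8
        wf = constant_waveform(1e-4, T)  # mean velocity ~1.3 m/s
        cfg = sv.SolverConfig(nr=16, nz=64, dt=0.005, n_cycles_max=3)
        with pytest.raises(RuntimeError, match="CFL"):
            sv.simulate_pulsatile_tube(R, L, wf, MU_N, outlet_wk(), cfg)

    def test_grid_convergence_on_womersley(self):
        """Halving the radial cell size reduces the wall-shear error."""
        R, L, T = 0.01, 0.08, 0.8
        c = np.array([8e-5 + 0j, 4e-5 + 0j])
        t = np.arange(200) / 200 * T
        wf = fq.FlowWaveform(
            times=t, flow_rate=phantom.waveform_from_harmonics(t, c, T), period=T
        )
        errs = []
        for nr in (16, 32):
            cfg = sv.SolverConfig(
                nr=nr, nz=32, dt=0.0025, periodicity_tolerance=0.2, n_cycles_max=8
            )
            res = sv.simulate_pulsatile_tube(R, L, wf, MU_N, outlet_wk(), cfg)
            f = res.final_cycle
            g_exact = phantom.womersley_wall_shear_rate(f.times % T, c, R, MU_N / RHO, T)
            k = f.u.shape[2] // 2
            errs.append(
                np.linalg.norm(f.wall_shear_rate[:, k] - g_exact) / np.linalg.norm(g_exact)
            )
        assert errs[1] < 0.5 * errs[0]
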