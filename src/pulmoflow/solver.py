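"""Pulsatile laminar flow in an axisymmetric rigid tube.

A desk-scale incompressible Navier–Stokes solver exercising the
methodology of a patient-specific pulmonary CFD workflow with exactly
verifiable oracles: prescribed inlet velocity profile, shear-thinning
(generalized-Newtonian) viscosity, a coupled three-element Windkessel
outlet, run-to-periodicity control, and wall-shear extraction.

Numerics
--------
Staggered (r, z) grid (axial velocity u at radial cell centres /
axial faces, radial velocity v at radial faces / axial cell centres,
pressure at cell centres); incremental pressure-projection
(predictor with the lagged pressure gradient, then a pressure-increment
Poisson solve enforcing discrete incompressibility); implicit
(θ-weighted) viscous terms with viscosity evaluated from the previous
step's shear-rate field; first-order upwind axial / central radial
explicit convection.  The Poisson matrix is factorised once; viscous
matrices are refactorised only when the viscosity field has drifted.

The laminar-regime check compares the peak Reynolds number against
the transition threshold 150·α, where α is the Womersley number
(D/2)·sqrt(ωρ/μ) with ω = 2π/T.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.sparse import coo_matrix, identity
from scipy.sparse.linalg import splu

from pulmoflow.flowquant import FlowWaveform
from pulmoflow.rheology import RheologyParams, quemada_viscosity, viscosity_bounds
from pulmoflow.windkessel import WindkesselParams, periodicity_metric

__all__ = [
    "SolverConfig",
    "HemoField",
    "FlowRegimeReport",
    "TubeRunResult",
    "assess_flow_regime",
    "simulate_pulsatile_tube",
    "converged_final_cycle",
]


@dataclass(frozen=True)
class SolverConfig:
    """Run-control and discretization parameters.

    ``dt`` defaults to 0.005 s; at least three cardiac cycles are run
    and the simulation continues until the outlet-pressure periodicity
    metric drops below ``periodicity_tolerance`` percent (or
    ``n_cycles_max`` is reached).  ``theta`` weights the implicit
    viscous step (1 = backward Euler, 0.5 = Crank–Nicolson).
    """

    dt: float = 0.005
    n_cycles_min: int = 3
    n_cycles_max: int = 10
    periodicity_tolerance: float = 1.0  # percent
    nr: int = 64
    nz: int = 32
    rho: float = 1060.0
    theta: float = 1.0
    mu_refresh_rtol: float = 5e-3
    inlet_shape: str = "womersley"  # reconstruction used for FlowWaveform inlets
    inlet_harmonics: int = 12
    raise_on_turbulent: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_cycles_min < 3:
            raise ValueError("at least three cardiac cycles are required")
        if self.nr < 16 or self.nz < 32:
            raise ValueError("grid must be at least 16 (radial) x 32 (axial)")


@dataclass
class FlowRegimeReport:
    """Peak-Reynolds laminar-flow assessment against the 150·α threshold."""

    re_peak: float
    womersley_alpha: float
    critical_value: float
    laminar: bool


@dataclass
class HemoField:
    """Velocity/pressure fields on the (r, z) grid over one cycle.

    ``u`` is the axial velocity at (time, r-centre, z-face), ``v`` the
    radial velocity at (time, r-face, z-centre), ``p`` the pressure at
    cell centres.  ``wall_shear_rate`` is the one-sided second-order
    estimate of −∂u/∂r at the wall per (time, z-face).  No-slip is
    imposed strongly, so the wall velocity is identically zero.
    """

    r: np.ndarray
    z_faces: np.ndarray
    times: np.ndarray
    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    wall_shear_rate: np.ndarray
    inlet_flow: np.ndarray
    outlet_flow: np.ndarray
    outlet_pressure: np.ndarray
    radius: float
    length: float
    period: float
    meta: dict = field(default_factory=dict)


@dataclass
class TubeRunResult:
    """Full run output: final two cycles plus convergence history."""

    final_cycle: HemoField
    previous_cycle: HemoField
    cycle_metrics: list
    achieved_periodicity: float
    n_cycles_run: int
    config: SolverConfig


def assess_flow_regime(
    peak_velocity: float,
    diameter: float,
    rho: float = 1060.0,
    mu_ref: float = 3.5e-3,
    period: float = 0.8,
) -> FlowRegimeReport:
    """Laminar-flow criterion: Re_peak < 150·α.

    Re_peak = ρ·U_peak·D/μ; α = (D/2)·sqrt(ωρ/μ) with ω = 2π/T.
    """
    if min(peak_velocity, diameter, rho, mu_ref, period) < 0 or diameter <= 0:
        raise ValueError("all inputs must be positive (peak velocity may be zero)")
    omega = 2.0 * np.pi / period
    re = rho * peak_velocity * diameter / mu_ref
    alpha = (diameter / 2.0) * np.sqrt(omega * rho / mu_ref)
    crit = 150.0 * alpha
    return FlowRegimeReport(re_peak=re, womersley_alpha=alpha, critical_value=crit, laminar=re < crit)


# --------------------------------------------------------------------------
# inlet profiles
# --------------------------------------------------------------------------

def _waveform_harmonics(waveform: FlowWaveform, n_harmonics: int) -> np.ndarray:
    m = 512
    t = np.arange(m) / m * waveform.period
    q = waveform(t)
    spec = np.fft.rfft(q) / m
    c = np.zeros(min(n_harmonics, m // 2 - 1) + 1, dtype=complex)
    c[0] = spec[0].real
    c[1:] = 2.0 * spec[1 : len(c)]
    return c


def _make_inlet(inlet, radius: float, nu_ref: float, config: SolverConfig) -> tuple[Callable, float]:
    """Return (profile(r, t) -> u, period)."""
    if not isinstance(inlet, FlowWaveform):
        if callable(inlet):
            period = getattr(inlet, "period", None)
            if period is None:
                raise ValueError("callable inlet must expose a .period attribute")
            return inlet, float(period)
        raise TypeError("inlet must be a FlowWaveform or a callable profile")
    period = inlet.period
    if config.inlet_shape == "parabolic":
        def profile(r, t, _wf=inlet, _R=radius):
            return 2.0 * _wf(t) / (np.pi * _R**2) * (1.0 - (np.asarray(r) / _R) ** 2)
        return profile, period
    if config.inlet_shape == "womersley":
        from pulmoflow.phantom import womersley_velocity

        c = _waveform_harmonics(inlet, config.inlet_harmonics)

        def profile(r, t, _c=c, _R=radius, _nu=nu_ref, _T=period):
            return womersley_velocity(np.asarray(r), t, _c, _R, _nu, _T)

        return profile, period
    raise ValueError("inlet_shape must be 'womersley' or 'parabolic'")


# --------------------------------------------------------------------------
# discrete operators
# --------------------------------------------------------------------------

def _wall_gradient_weights(dr: float, n_pts: int = 3) -> np.ndarray:
    """One-sided weights for −∂u/∂r at the wall from the nearest cell
    centres (distances (i−1/2)·Δr inside), with u(wall) = 0 built in.
    A polynomial fit through ``n_pts`` points gives order n_pts
    accuracy; returns weights for u[-1], u[-2], ..."""
    d = (np.arange(1, n_pts + 1) - 0.5) * dr
    V = np.column_stack([d ** (i + 1) for i in range(n_pts)])
    return np.linalg.inv(V)[0]


class _TubeGrid:
    def __init__(self, radius: float, length: float, nr: int, nz: int):
        self.R, self.L, self.nr, self.nz = radius, length, nr, nz
        self.dr = radius / nr
        self.dz = length / nz
        self.rc = (np.arange(nr) + 0.5) * self.dr  # u radial positions / cell centres
        self.rf = np.arange(nr + 1) * self.dr  # v radial positions / faces
        self.zf = np.arange(nz + 1) * self.dz
        self.zc = (np.arange(nz) + 0.5) * self.dz
        self.nu_dof = nr * (nz + 1)
        self.nv_dof = (nr + 1) * nz

    def uid(self, j, k):
        return j * (self.nz + 1) + k

    def vid(self, j, k):
        return j * self.nz + k

    def pid(self, j, k):
        return j * self.nz + k

    def flux(self, u_col: np.ndarray) -> float:
        """Volumetric flow through a z-face from the u column (nr,)."""
        return float(np.sum(u_col * 2.0 * np.pi * self.rc) * self.dr)


def _corner_mu(mu: np.ndarray, nz: int) -> np.ndarray:
    """mu at (r-face j=1..nr-1, z-face k=0..nz): 4-cell average with clamping."""
    nr = mu.shape[0]
    mu_k = np.empty((nr, nz + 1))
    mu_k[:, 1:nz] = 0.5 * (mu[:, :-1] + mu[:, 1:])
    mu_k[:, 0] = mu[:, 0]
    mu_k[:, nz] = mu[:, -1]
    out = 0.5 * (mu_k[:-1, :] + mu_k[1:, :])  # (nr-1, nz+1) at interior r-faces
    return out


def _build_Lu(grid: _TubeGrid, mu: np.ndarray, mu_wall: np.ndarray):
    """Sparse viscous operator for u (rows k>=1 only)."""
    nr, nz, dr, dz = grid.nr, grid.nz, grid.dr, grid.dz
    rows, cols, vals = [], [], []
    mu_rf = _corner_mu(mu, nz)  # (nr-1, nz+1) for faces j=1..nr-1

    jj, kk = np.meshgrid(np.arange(nr), np.arange(1, nz + 1), indexing="ij")
    jj = jj.ravel()
    kk = kk.ravel()
    rc = grid.rc[jj]
    m = grid.uid(jj, kk)

    diag = np.zeros(len(m))
    # radial upper neighbour
    has_up = jj < nr - 1
    a_p = np.zeros(len(m))
    a_p[has_up] = (
        grid.rf[jj[has_up] + 1]
        * mu_rf[jj[has_up], kk[has_up]]
        / (rc[has_up] * dr * dr)
    )
    rows.extend(m[has_up]); cols.extend(grid.uid(jj[has_up] + 1, kk[has_up])); vals.extend(a_p[has_up])
    diag -= a_p
    # wall flux for j = nr-1
    # wall face flux from the quadratic through u(nr-1), u(nr-2) and the
    # no-slip wall value: du/dr|_R = -(9u1 - u2)/(3dr), second order
    at_wall = ~has_up
    wcoef = grid.rf[nr] * mu_wall[kk[at_wall]] / (rc[at_wall] * dr * dr)
    diag[at_wall] -= 3.0 * wcoef
    rows.extend(m[at_wall])
    cols.extend(grid.uid(jj[at_wall] - 1, kk[at_wall]))
    vals.extend(wcoef / 3.0)
    # radial lower neighbour (zero flux at the axis: rf[0] = 0)
    has_dn = jj > 0
    a_m = np.zeros(len(m))
    a_m[has_dn] = grid.rf[jj[has_dn]] * mu_rf[jj[has_dn] - 1, kk[has_dn]] / (rc[has_dn] * dr * dr)
    rows.extend(m[has_dn]); cols.extend(grid.uid(jj[has_dn] - 1, kk[has_dn])); vals.extend(a_m[has_dn])
    diag -= a_m
    # axial upper (cell k exists for k <= nz-1)
    has_zu = kk <= nz - 1
    b_p = np.zeros(len(m))
    b_p[has_zu] = mu[jj[has_zu], kk[has_zu]] / (dz * dz)
    rows.extend(m[has_zu]); cols.extend(grid.uid(jj[has_zu], kk[has_zu] + 1)); vals.extend(b_p[has_zu])
    diag -= b_p
    # axial lower (cell k-1 always exists for k >= 1)
    b_m = mu[jj, kk - 1] / (dz * dz)
    rows.extend(m); cols.extend(grid.uid(jj, kk - 1)); vals.extend(b_m)
    diag -= b_m

    rows.extend(m); cols.extend(m); vals.extend(diag)
    return coo_matrix((vals, (rows, cols)), shape=(grid.nu_dof, grid.nu_dof)).tocsc()


def _build_Lv(grid: _TubeGrid, mu: np.ndarray):
    """Sparse viscous operator for v (rows j=1..nr-1 only)."""
    nr, nz, dr, dz = grid.nr, grid.nz, grid.dr, grid.dz
    rows, cols, vals = [], [], []
    # edge mu at (r-face j, z-face k'): average of adjacent cells, clamped
    mu_rf = _corner_mu(mu, nz)  # (nr-1, nz+1), faces j=1..nr-1

    jj, kk = np.meshgrid(np.arange(1, nr), np.arange(nz), indexing="ij")
    jj = jj.ravel()
    kk = kk.ravel()
    rj = grid.rf[jj]
    m = grid.vid(jj, kk)
    diag = np.zeros(len(m))

    # radial: flux through cell centres j (upper) and j-1 (lower)
    c_p = grid.rc[jj] * mu[jj, kk] / (rj * dr * dr)
    has_up = jj < nr - 1
    rows.extend(m[has_up]); cols.extend(grid.vid(jj[has_up] + 1, kk[has_up])); vals.extend(c_p[has_up])
    diag -= c_p  # at j = nr-1 the neighbour v(nr) = 0 (Dirichlet): flux still drains
    c_m = grid.rc[jj - 1] * mu[jj - 1, kk] / (rj * dr * dr)
    has_dn = jj > 1
    rows.extend(m[has_dn]); cols.extend(grid.vid(jj[has_dn] - 1, kk[has_dn])); vals.extend(c_m[has_dn])
    diag -= c_m  # at j = 1 the neighbour v(0) = 0 (axis)
    # azimuthal curvature term −mu v / r²
    diag -= 0.5 * (mu[jj - 1, kk] + mu[jj, kk]) / rj**2
    # axial
    has_zu = kk < nz - 1
    d_p = np.zeros(len(m))
    d_p[has_zu] = mu_rf[jj[has_zu] - 1, kk[has_zu] + 1] / (dz * dz)
    rows.extend(m[has_zu]); cols.extend(grid.vid(jj[has_zu], kk[has_zu] + 1)); vals.extend(d_p[has_zu])
    diag -= d_p  # outlet k = nz-1: zero-gradient, no flux
    d_m = np.zeros(len(m))
    interior_dn = kk > 0
    d_m[interior_dn] = mu_rf[jj[interior_dn] - 1, kk[interior_dn]] / (dz * dz)
    rows.extend(m[interior_dn]); cols.extend(grid.vid(jj[interior_dn], kk[interior_dn] - 1)); vals.extend(d_m[interior_dn])
    diag -= d_m
    at_inlet = ~interior_dn  # half-cell to the v = 0 inlet face
    diag[at_inlet] -= 2.0 * mu_rf[jj[at_inlet] - 1, 0] / (dz * dz)

    rows.extend(m); cols.extend(m); vals.extend(diag)
    return coo_matrix((vals, (rows, cols)), shape=(grid.nv_dof, grid.nv_dof)).tocsc()


def _build_poisson(grid: _TubeGrid):
    """Axisymmetric Laplacian for the pressure increment.

    Neumann at inlet, wall and axis; Dirichlet (face value) at the
    outlet.  Returns (matrix, outlet_rhs_coeff) where the coefficient
    multiplies the prescribed outlet face value into the RHS.
    """
    nr, nz, dr, dz = grid.nr, grid.nz, grid.dr, grid.dz
    rows, cols, vals = [], [], []
    jj, kk = np.meshgrid(np.arange(nr), np.arange(nz), indexing="ij")
    jj = jj.ravel()
    kk = kk.ravel()
    rc = grid.rc[jj]
    m = grid.pid(jj, kk)
    diag = np.zeros(len(m))

    has_up = jj < nr - 1
    a_p = np.zeros(len(m))
    a_p[has_up] = grid.rf[jj[has_up] + 1] / (rc[has_up] * dr * dr)
    rows.extend(m[has_up]); cols.extend(grid.pid(jj[has_up] + 1, kk[has_up])); vals.extend(a_p[has_up])
    diag -= a_p
    has_dn = jj > 0
    a_m = np.zeros(len(m))
    a_m[has_dn] = grid.rf[jj[has_dn]] / (rc[has_dn] * dr * dr)
    rows.extend(m[has_dn]); cols.extend(grid.pid(jj[has_dn] - 1, kk[has_dn])); vals.extend(a_m[has_dn])
    diag -= a_m

    has_zu = kk < nz - 1
    b = 1.0 / (dz * dz)
    rows.extend(m[has_zu]); cols.extend(grid.pid(jj[has_zu], kk[has_zu] + 1)); vals.extend(np.full(has_zu.sum(), b))
    diag[has_zu] -= b
    at_outlet = ~has_zu
    diag[at_outlet] -= 2.0 * b  # half-cell to the Dirichlet outlet face
    has_zd = kk > 0
    rows.extend(m[has_zd]); cols.extend(grid.pid(jj[has_zd], kk[has_zd] - 1)); vals.extend(np.full(has_zd.sum(), b))
    diag[has_zd] -= b

    rows.extend(m); cols.extend(m); vals.extend(diag)
    A = coo_matrix((vals, (rows, cols)), shape=(nr * nz, nr * nz)).tocsc()
    outlet_rows = grid.pid(np.arange(nr), nz - 1)
    return A, outlet_rows, 2.0 * b


# --------------------------------------------------------------------------
# shear rate and convection
# --------------------------------------------------------------------------

def _shear_rate(grid: _TubeGrid, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Generalized shear rate sqrt(2 D:D) at cell centres (nr, nz)."""
    nr, nz, dr, dz = grid.nr, grid.nz, grid.dr, grid.dz
    uc = 0.5 * (u[:, :-1] + u[:, 1:])  # (nr, nz) at cell centres
    dudr = np.empty((nr, nz))
    dudr[1:-1] = (uc[2:] - uc[:-2]) / (2 * dr)
    dudr[0] = (uc[1] - uc[0]) / (2 * dr)
    dudr[-1] = (-uc[-1] - uc[-2]) / (2 * dr)  # no-slip ghost beyond the wall
    dudz = (u[:, 1:] - u[:, :-1]) / dz
    dvdr = (v[1:, :] - v[:-1, :]) / dr
    vc = 0.5 * (v[:-1, :] + v[1:, :])
    dtheta = vc / grid.rc[:, None]
    dvdz = np.zeros((nr, nz))
    dvdz[:, 1:-1] = (vc[:, 2:] - vc[:, :-2]) / (2 * dz)
    drz = 0.5 * (dudr + dvdz)
    return np.sqrt(2.0 * (dudz**2 + dvdr**2 + dtheta**2) + 4.0 * drz**2)


def _convection_u(grid: _TubeGrid, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Explicit convection u·∂u/∂z + v·∂u/∂r at u points (rows k>=1)."""
    nr, nz, dr, dz = grid.nr, grid.nz, grid.dr, grid.dz
    conv = np.zeros_like(u)
    uu = u[:, 1:]  # k = 1..nz
    back = (u[:, 1:] - u[:, :-1]) / dz
    fwd = np.zeros_like(uu)
    fwd[:, :-1] = (u[:, 2:] - u[:, 1:-1]) / dz
    dudz = np.where(uu >= 0, back, fwd)

    # v averaged to u points (j, k): faces j, j+1 at cells k-1, min(k, nz-1)
    klo = np.arange(1, nz + 1) - 1
    khi = np.minimum(np.arange(1, nz + 1), nz - 1)
    vbar = 0.25 * (v[:-1, klo] + v[:-1, khi] + v[1:, klo] + v[1:, khi])

    dudr = np.empty((nr, nz))
    ui = u[:, 1:]
    dudr[1:-1] = (ui[2:] - ui[:-2]) / (2 * dr)
    dudr[0] = (ui[1] - ui[0]) / (2 * dr)
    dudr[-1] = (-ui[-1] - ui[-2]) / (2 * dr)
    conv[:, 1:] = uu * dudz + vbar * dudr
    return conv


def _convection_v(grid: _TubeGrid, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Explicit convection u·∂v/∂z + v·∂v/∂r at v points (rows j=1..nr-1)."""
    nr, nz, dr, dz = grid.nr, grid.nz, grid.dr, grid.dz
    conv = np.zeros_like(v)
    vi = v[1:-1, :]
    ubar = 0.25 * (u[:-1, :-1] + u[:-1, 1:] + u[1:, :-1] + u[1:, 1:])  # (nr-1, nz)
    back = np.empty_like(vi)
    back[:, 0] = vi[:, 0] / (dz / 2.0)  # inlet face value 0 at half-cell distance
    back[:, 1:] = (vi[:, 1:] - vi[:, :-1]) / dz
    fwd = np.zeros_like(vi)
    fwd[:, :-1] = (vi[:, 1:] - vi[:, :-1]) / dz
    dvdz = np.where(ubar >= 0, back, fwd)
    dvdr = (v[2:, :] - v[:-2, :]) / (2 * dr)
    conv[1:-1, :] = ubar * dvdz + vi * dvdr
    return conv


# --------------------------------------------------------------------------
# main driver
# --------------------------------------------------------------------------

def simulate_pulsatile_tube(
    radius: float,
    length: float,
    inlet,
    rheology: RheologyParams | float,
    outlet: WindkesselParams | None,
    config: SolverConfig = SolverConfig(),
    pc0: float | None = None,
) -> TubeRunResult:
    """Simulate pulsatile generalized-Newtonian flow in a rigid tube.

    Parameters
    ----------
    radius, length : float
        Tube dimensions in metres.
    inlet : FlowWaveform or callable(r, t) -> u
        Inlet axial-velocity boundary condition.  A FlowWaveform is
        expanded into the corresponding fully developed profile
        (Womersley by default, parabolic via config).
    rheology : RheologyParams or float
        Quemada parameters, or a constant Newtonian viscosity (Pa·s).
    outlet : WindkesselParams or None
        Coupled 3EWK outlet supplying the outlet pressure each step;
        ``None`` holds the outlet at zero pressure.
    pc0 : float, optional
        Initial compliance pressure; defaults to R2 times the inlet
        cycle-mean flow (a pre-charged bed shortens the transient).

    Returns
    -------
    TubeRunResult
        Final two cycles of fields plus periodicity history.

    Raises
    ------
    RuntimeError
        On CFL violation or non-finite fields, naming the step.
    """
    cfg = config
    grid = _TubeGrid(radius, length, cfg.nr, cfg.nz)
    rho, dt = cfg.rho, cfg.dt

    newtonian = not isinstance(rheology, RheologyParams)
    if newtonian:
        mu_const = float(rheology)
        mu_ref = mu_const
    else:
        mu_ref, _ = viscosity_bounds(rheology)
    nu_ref = mu_ref / rho

    profile, period = _make_inlet(inlet, radius, nu_ref, cfg)
    steps_per_cycle = int(round(period / dt))
    if steps_per_cycle < 50:
        raise ValueError("dt too coarse: fewer than 50 steps per cycle")

    # regime assessment (warn-only by default)
    u_in0 = np.array([profile(grid.rc, t) for t in np.linspace(0, period, 40, endpoint=False)])
    regime = assess_flow_regime(float(np.abs(u_in0).max()), 2 * radius, rho, mu_ref, period)
    if cfg.raise_on_turbulent and not regime.laminar:
        raise RuntimeError("flow regime exceeds the 150·alpha laminar threshold")

    # state
    u = np.tile(profile(grid.rc, 0.0)[:, None], (1, grid.nz + 1)).astype(float)
    v = np.zeros((grid.nr + 1, grid.nz))
    p = np.zeros((grid.nr, grid.nz))

    q0 = grid.flux(u[:, 0])
    qbar = float(np.mean([grid.flux(np.asarray(profile(grid.rc, t))) for t in np.linspace(0, period, 50, endpoint=False)]))
    if outlet is not None:
        pc = outlet.r2 * qbar + outlet.distal_pressure if pc0 is None else pc0
        p_wk = outlet.r1 * q0 + pc
    else:
        pc, p_wk = 0.0, 0.0
    p[:] = p_wk  # uniform initial pressure consistent with the outlet

    wgw = _wall_gradient_weights(grid.dr)
    A_pois, outlet_rows, outlet_coeff = _build_poisson(grid)
    lu_pois = splu(A_pois)

    mu_field = np.full((grid.nr, grid.nz), mu_ref)
    mu_wall = np.full(grid.nz + 1, mu_ref)
    mu_built = None
    lu_u = lu_v = None
    Lu = Lv = None
    Iu = identity(grid.nu_dof, format="csc")
    Iv = identity(grid.nv_dof, format="csc")
    dirich_u = grid.uid(np.arange(grid.nr), 0)
    dirich_v = np.r_[grid.vid(0, np.arange(grid.nz)), grid.vid(grid.nr, np.arange(grid.nz))]

    def refresh_matrices():
        nonlocal lu_u, lu_v, Lu, Lv, mu_built
        Lu = _build_Lu(grid, mu_field, mu_wall)
        Lv = _build_Lv(grid, mu_field)
        A_u = Iu / dt - (cfg.theta / rho) * Lu
        A_v = Iv / dt - (cfg.theta / rho) * Lv
        lu_u = splu(A_u)
        lu_v = splu(A_v)
        mu_built = mu_field.copy()

    refresh_matrices()

    hist_len = 2 * steps_per_cycle
    Hu = np.zeros((hist_len, grid.nr, grid.nz + 1))
    Hv = np.zeros((hist_len, grid.nr + 1, grid.nz))
    Hp = np.zeros((hist_len, grid.nr, grid.nz))
    Hg = np.zeros((hist_len, grid.nz + 1))
    Hqi = np.zeros(hist_len)
    Hqo = np.zeros(hist_len)
    Hpo = np.zeros(hist_len)
    Ht = np.zeros(hist_len)

    def wk_rhs(pcc, q):
        return (q - (pcc - outlet.distal_pressure) / outlet.r2) / outlet.c

    cycle_metrics: list = []
    step = 0
    n_cycles_run = 0
    dr, dz = grid.dr, grid.dz
    done = False
    while not done:
        for _ in range(steps_per_cycle):
            t_new = (step + 1) * dt
            # CFL
            cfl = np.abs(u).max() * dt / dz + np.abs(v).max() * dt / dr
            if cfl > 1.0:
                raise RuntimeError(f"CFL violation ({cfl:.2f}) at step {step}")

            if not newtonian:
                g = _shear_rate(grid, u, v)
                mu_field = quemada_viscosity(g, rheology)
                gw = np.abs(wgw[0] * u[-1, :] + wgw[1] * u[-2, :] + wgw[2] * u[-3, :])
                mu_wall = quemada_viscosity(gw, rheology)
                if np.max(np.abs(mu_field - mu_built) / mu_built) > cfg.mu_refresh_rtol:
                    refresh_matrices()

            # windkessel: advance with the current outlet flow
            q_out = grid.flux(u[:, -1])
            if outlet is not None:
                k1 = wk_rhs(pc, q_out)
                k2 = wk_rhs(pc + dt * k1 / 2, q_out)
                k3 = wk_rhs(pc + dt * k2 / 2, q_out)
                k4 = wk_rhs(pc + dt * k3, q_out)
                pc_new = pc + dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6
                p_wk_new = outlet.r1 * q_out + pc_new
            else:
                pc_new, p_wk_new = 0.0, 0.0

            # predictor
            conv_u = _convection_u(grid, u, v)
            conv_v = _convection_v(grid, u, v)
            gradp_u = np.zeros_like(u)
            gradp_u[:, 1:-1] = (p[:, 1:] - p[:, :-1]) / dz
            gradp_u[:, -1] = (p_wk - p[:, -1]) / (dz / 2.0)
            gradp_v = np.zeros_like(v)
            gradp_v[1:-1, :] = (p[1:, :] - p[:-1, :]) / dr

            rhs_u = u / dt - conv_u - gradp_u / rho
            if cfg.theta < 1.0:
                rhs_u += ((1.0 - cfg.theta) / rho) * (Lu @ u.ravel()).reshape(u.shape)
            rhs_u = rhs_u.ravel()
            rhs_u[dirich_u] = profile(grid.rc, t_new) / dt
            u_star = lu_u.solve(rhs_u).reshape(u.shape)

            rhs_v = v / dt - conv_v - gradp_v / rho
            if cfg.theta < 1.0:
                rhs_v += ((1.0 - cfg.theta) / rho) * (Lv @ v.ravel()).reshape(v.shape)
            rhs_v = rhs_v.ravel()
            rhs_v[dirich_v] = 0.0
            v_star = lu_v.solve(rhs_v).reshape(v.shape)

            # projection: pressure increment with outlet face value
            phi_face = p_wk_new - p_wk
            div = (
                grid.rf[1:, None] * v_star[1:, :] - grid.rf[:-1, None] * v_star[:-1, :]
            ) / (grid.rc[:, None] * dr) + (u_star[:, 1:] - u_star[:, :-1]) / dz
            rhs_p = (rho / dt) * div.ravel()
            rhs_p[outlet_rows] -= outlet_coeff * phi_face
            phi = lu_pois.solve(rhs_p).reshape(grid.nr, grid.nz)

            u = u_star.copy()
            u[:, 1:-1] -= (dt / rho) * (phi[:, 1:] - phi[:, :-1]) / dz
            u[:, -1] -= (dt / rho) * (phi_face - phi[:, -1]) / (dz / 2.0)
            v = v_star.copy()
            v[1:-1, :] -= (dt / rho) * (phi[1:, :] - phi[:-1, :]) / dr
            p = p + phi
            pc, p_wk = pc_new, p_wk_new

            if not (np.isfinite(u).all() and np.isfinite(p).all()):
                raise RuntimeError(f"non-finite fields at step {step} (projection)")

            s = step % hist_len
            Hu[s], Hv[s], Hp[s] = u, v, p
            Hg[s] = wgw[0] * u[-1, :] + wgw[1] * u[-2, :] + wgw[2] * u[-3, :]
            Hqi[s] = grid.flux(u[:, 0])
            Hqo[s] = grid.flux(u[:, -1])
            Hpo[s] = p_wk
            Ht[s] = t_new
            step += 1

        n_cycles_run += 1
        if n_cycles_run >= 2:
            idx_last = [(step - steps_per_cycle + i) % hist_len for i in range(steps_per_cycle)]
            idx_prev = [(step - 2 * steps_per_cycle + i) % hist_len for i in range(steps_per_cycle)]
            ref = Hpo[idx_last] if outlet is not None else Hqo[idx_last]
            prev = Hpo[idx_prev] if outlet is not None else Hqo[idx_prev]
            metric = periodicity_metric(ref, prev)
            cycle_metrics.append(metric)
            if n_cycles_run >= cfg.n_cycles_min and metric < cfg.periodicity_tolerance:
                done = True
        if n_cycles_run >= cfg.n_cycles_max:
            done = True

    def extract(indices) -> HemoField:
        idx = np.asarray(indices)
        return HemoField(
            r=grid.rc.copy(),
            z_faces=grid.zf.copy(),
            times=Ht[idx].copy(),
            u=Hu[idx].copy(),
            v=Hv[idx].copy(),
            p=Hp[idx].copy(),
            wall_shear_rate=Hg[idx].copy(),
            inlet_flow=Hqi[idx].copy(),
            outlet_flow=Hqo[idx].copy(),
            outlet_pressure=Hpo[idx].copy(),
            radius=radius,
            length=length,
            period=period,
            meta={"rheology": rheology, "mu_ref": mu_ref, "regime": regime, "config": cfg},
        )

    idx_last = [(step - steps_per_cycle + i) % hist_len for i in range(steps_per_cycle)]
    idx_prev = [(step - 2 * steps_per_cycle + i) % hist_len for i in range(steps_per_cycle)]
    achieved = cycle_metrics[-1] if cycle_metrics else float("inf")
    return TubeRunResult(
        final_cycle=extract(idx_last),
        previous_cycle=extract(idx_prev),
        cycle_metrics=cycle_metrics,
        achieved_periodicity=achieved,
        n_cycles_run=n_cycles_run,
        config=cfg,
    )


def converged_final_cycle(result: TubeRunResult) -> tuple[HemoField, float]:
    """Final cycle and its periodicity metric; fails if not converged.

    Raises
    ------
    RuntimeError
        If the last-two-cycle variation still exceeds the configured
        tolerance (reports the achieved metric).
    """
    if result.n_cycles_run < 2:
        raise RuntimeError("need at least two complete cycles")
    tol = result.config.periodicity_tolerance
    if result.achieved_periodicity >= tol:
        raise RuntimeError(
            f"simulation not periodic: metric {result.achieved_periodicity:.3f}% "
            f"after {result.n_cycles_run} cycles (tolerance {tol}%)"
        )
    return result.final_cycle, result.achieved_periodicity
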