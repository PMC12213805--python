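"""Synthetic 4D-flow MRI phantoms with analytically known velocity fields.

The phantom is a Y-shaped rigid vessel — a main pulmonary artery (MPA)
that bifurcates into left and right branches (LPA/RPA) — carrying
pulsatile laminar flow.  Inside each cylindrical segment the velocity
field is the exact axisymmetric Womersley solution for the prescribed
flow waveform (split between the branches by a configurable fraction),
so every downstream estimator can be checked against closed-form ground
truth.  The generator voxelizes that field the way a phase-contrast
acquisition does: voxel-centre sampling, partial-volume averaging at
the wall, optional additive Gaussian velocity noise, and clipping at
the velocity-encoding limit (venc).

The module also ships the printed seven-patient cohort (cardiac
periods, stroke volumes, branch flow splits, catheter pressures,
Windkessel parameters, validation velocities and regional TAWSS) as a
CSV fixture so cohort-level analyses run without any download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import ndimage, special

from pulmoflow.segmentation import LPA, MPA, OUTSIDE, RPA, Plane, VesselGeometry

__all__ = [
    "PhantomSpec",
    "FlowMRIStudy",
    "half_sine_harmonics",
    "waveform_from_harmonics",
    "womersley_velocity",
    "womersley_wall_shear_rate",
    "generate_bifurcation_geometry",
    "generate_flow_study",
    "analytic_peak_velocity",
    "load_printed_cohort",
    "load_plane_tawss_summary",
]


# --------------------------------------------------------------------------
# specifications and study container
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic bifurcation study.

    Lengths are in metres (SI); the cardiac conditions default to a
    mid-cohort PAH patient: dilated MPA (35 mm diameter), period 0.8 s,
    stroke volume 80 mL, 55% of flow to the RPA.  ``waveform_harmonics``
    are one-sided complex Fourier coefficients of the volumetric flow
    waveform Q(t) = Re Σ c_n·exp(i n ω t) in m³/s; when ``None`` a
    half-sine systolic ejection over T/3 (zero diastolic flow) scaled
    to the stroke volume is used, truncated to ``n_harmonics``.
    """

    mpa_radius: float = 0.0175
    branch_radii: tuple[float, float] = (0.0115, 0.012)  # (LPA, RPA)
    branch_angles: tuple[float, float] = (55.0, 55.0)  # degrees off the MPA axis
    mpa_length: float = 0.030
    branch_length: float = 0.040
    period: float = 0.8
    stroke_volume_ml: float = 80.0
    rpa_fraction: float = 0.55
    waveform_harmonics: tuple | None = None
    n_harmonics: int = 10
    nu: float = 3.3e-6  # kinematic viscosity of the analytic field, m²/s
    venc: float = 1.5  # m/s
    noise_sd: float = 0.0  # m/s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stroke_volume_ml <= 0:
            raise ValueError("stroke volume must be positive")
        if not 0.0 < self.rpa_fraction < 1.0:
            raise ValueError("rpa_fraction must lie in (0, 1)")
        if self.mpa_radius <= 0 or min(self.branch_radii) < 0:
            raise ValueError("radii must be non-negative (MPA strictly positive)")
        if self.period <= 0:
            raise ValueError("period must be positive")

    @property
    def harmonics(self) -> np.ndarray:
        """One-sided flow Fourier coefficients, m³/s."""
        if self.waveform_harmonics is not None:
            return np.asarray(self.waveform_harmonics, dtype=complex)
        return half_sine_harmonics(self.stroke_volume_ml, self.period, self.n_harmonics)


@dataclass
class FlowMRIStudy:
    """A voxelized phase-contrast study.

    Attributes
    ----------
    voxel_spacing : (3,) mm
    frame_times : (F,) seconds, strictly increasing, all < period
    magnitude : (F, n0, n1, n2) array
        Anatomical signal; proportional to lumen partial volume.
    phase_velocity : (F, 3, n0, n1, n2) array, m/s
        Signed velocity components.
    venc : float, m/s
    period : float, s
    """

    voxel_spacing: tuple[float, float, float]
    frame_times: np.ndarray
    magnitude: np.ndarray
    phase_velocity: np.ndarray
    venc: float
    period: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frame_times.size < 2:
            raise ValueError("at least two frames required")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.frame_times[-1] >= self.period:
            raise ValueError("frame times must all be below the period")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("spacing must be positive")
        if np.max(np.abs(self.phase_velocity)) > self.venc * (1 + 1e-9):
            raise ValueError("phase velocities exceed venc")

    @property
    def n_frames(self) -> int:
        return len(self.frame_times)


# --------------------------------------------------------------------------
# waveform and Womersley analytics
# --------------------------------------------------------------------------

def half_sine_harmonics(stroke_volume_ml: float, period: float, n_harmonics: int = 10) -> np.ndarray:
    """Fourier coefficients of a half-sine systolic ejection waveform.

    Q(t) = A·sin(3πt/T) for 0 ≤ t < T/3 and zero in diastole, with
    A = 3π·SV/(2T) so the cycle integral equals the stroke volume.
    Returns one-sided complex coefficients ``c[0..n_harmonics]`` (c_0
    real, the mean flow) in m³/s.
    """
    sv = stroke_volume_ml * 1e-6
    amp = 3.0 * np.pi * sv / (2.0 * period)
    m = 4096
    t = np.arange(m) / m * period
    q = np.where(t < period / 3.0, amp * np.sin(3.0 * np.pi * t / period), 0.0)
    spec = np.fft.rfft(q) / m
    c = np.zeros(n_harmonics + 1, dtype=complex)
    c[0] = spec[0].real
    c[1:] = 2.0 * spec[1 : n_harmonics + 1]
    return c


def waveform_from_harmonics(t, harmonics, period: float):
    """Evaluate Q(t) = Re Σ c_n exp(i n ω t) (m³/s)."""
    t = np.asarray(t, dtype=float)
    c = np.asarray(harmonics, dtype=complex)
    omega = 2.0 * np.pi / period
    n = np.arange(len(c))
    phase = np.exp(1j * np.outer(t, n) * omega)
    return (phase @ c).real.reshape(t.shape)


def _womersley_lambda(n: int, radius: float, nu: float, period: float) -> complex:
    omega = 2.0 * np.pi / period
    alpha = radius * np.sqrt(n * omega / nu)
    if alpha > 600.0:
        raise ValueError("Womersley number too large for stable Bessel evaluation")
    return alpha * 1j**1.5


def womersley_velocity(r, t, harmonics, radius: float, nu: float, period: float):
    """Axial velocity of pulsatile laminar flow in a rigid tube, m/s.

    Exact axisymmetric solution for the flow waveform given by the
    one-sided Fourier coefficients ``harmonics`` (m³/s): the n = 0 term
    is the Poiseuille parabola carrying the mean flow, higher harmonics
    are Womersley modes.  Integrating the returned profile over the
    cross-section recovers the prescribed Q(t) exactly.

    Parameters broadcast: ``r`` (m, 0 ≤ r ≤ R) against ``t`` (s).
    """
    r = np.asarray(r, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(r < -1e-12) or np.any(r > radius * (1 + 1e-9)):
        raise ValueError("radial positions must lie in [0, R]")
    c = np.asarray(harmonics, dtype=complex)
    omega = 2.0 * np.pi / period
    area = np.pi * radius**2
    rr = np.minimum(r / radius, 1.0)
    out = np.zeros(np.broadcast(r, t).shape, dtype=float)
    out += (2.0 * c[0].real / area) * (1.0 - rr**2) * np.ones_like(t)
    for n in range(1, len(c)):
        if c[n] == 0:
            continue
        lam = _womersley_lambda(n, radius, nu, period)
        j0l = special.jv(0, lam)
        denom = 1.0 - 2.0 * special.jv(1, lam) / (lam * j0l)
        shape = (1.0 - special.jv(0, lam * rr) / j0l) / denom
        out += np.real((c[n] / area) * shape * np.exp(1j * n * omega * t))
    return out


def womersley_wall_shear_rate(t, harmonics, radius: float, nu: float, period: float):
    """Wall shear rate −∂u/∂r|_{r=R} of the Womersley solution, 1/s."""
    t = np.asarray(t, dtype=float)
    c = np.asarray(harmonics, dtype=complex)
    omega = 2.0 * np.pi / period
    area = np.pi * radius**2
    out = np.full(t.shape, 4.0 * c[0].real / (area * radius))
    for n in range(1, len(c)):
        if c[n] == 0:
            continue
        lam = _womersley_lambda(n, radius, nu, period)
        j0l = special.jv(0, lam)
        denom = 1.0 - 2.0 * special.jv(1, lam) / (lam * j0l)
        # −d/dr of the mode shape at r = R: −(Λ/R)·J1(Λ)/(J0(Λ)·D)
        dshape = -(lam / radius) * special.jv(1, lam) / j0l / denom
        out += np.real((c[n] / area) * dshape * np.exp(1j * n * omega * t))
    return out


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

def _branch_layout(spec: PhantomSpec) -> dict:
    """Axes (world mm) of the MPA and surviving branches.

    Branches with zero radius are dropped; if no branch survives, or a
    single straight branch simply continues the MPA at equal radius,
    the vessel degenerates to one MPA cylinder.
    """
    mm = 1000.0
    z0 = 4.0  # mm of empty margin below the inlet
    r_mpa = spec.mpa_radius * mm
    l_mpa = spec.mpa_length * mm
    l_br = spec.branch_length * mm
    bif = np.array([z0 + l_mpa, 0.0, 0.0])

    branches = []
    for rid, radius, angle, sign in (
        (LPA, spec.branch_radii[0], spec.branch_angles[0], -1.0),
        (RPA, spec.branch_radii[1], spec.branch_angles[1], +1.0),
    ):
        if radius <= 0:
            continue
        th = np.deg2rad(angle)
        branches.append(
            {
                "region": rid,
                "radius_mm": radius * mm,
                "dir": np.array([np.cos(th), sign * np.sin(th), 0.0]),
                "origin": bif.copy(),
                "length_mm": l_br,
            }
        )

    degenerate = not branches or (
        len(branches) == 1
        and branches[0]["dir"][0] > 1.0 - 1e-12
        and abs(branches[0]["radius_mm"] - r_mpa) < 1e-9
    )
    if degenerate:
        mpa_len = l_mpa + (l_br if branches else 0.0)
        branches = []
    else:
        mpa_len = l_mpa

    layout = {
        "z0": z0,
        "mpa_radius_mm": r_mpa,
        "mpa_length_mm": mpa_len,
        "bif_point": np.array([z0 + mpa_len, 0.0, 0.0]),
        "branches": branches,
        "degenerate": degenerate,
    }
    layout["carina_mm"] = _find_carina(layout)
    return layout


def _find_carina(layout: dict, step: float = 0.5) -> float:
    """Axial position (mm) where the lumen first splits in two.

    The two branch cylinders emanating from the bifurcation point
    overlap for some distance; anatomically the MPA extends to the
    carina — the most distal cross-section whose lumen is still singly
    connected.  Found by scanning analytic cross-sections on a fine
    grid.  Degenerate (single-tube / single-branch) layouts return the
    bifurcation point.
    """
    from scipy import ndimage as _ndi

    zb = layout["bif_point"][0]
    if len(layout["branches"]) < 2:
        return zb
    ext = max(
        abs(b["origin"][1]) + b["length_mm"] + b["radius_mm"] for b in layout["branches"]
    ) + layout["mpa_radius_mm"]
    yy, zz = np.meshgrid(
        np.arange(-ext, ext, step), np.arange(-ext, ext, step), indexing="ij"
    )
    span = min(b["length_mm"] * abs(b["dir"][0]) for b in layout["branches"])
    for d in np.arange(step, span, step):
        pts = np.column_stack(
            [np.full(yy.size, zb + d), yy.ravel(), zz.ravel()]
        )
        region, _, _, _ = _classify_points(pts, layout)
        inside = (region != OUTSIDE).reshape(yy.shape)
        _, nc = _ndi.label(inside, structure=np.ones((3, 3), bool))
        if nc >= 2:
            return float(zb + d - step / 2)
    return float(zb + span)


def _classify_points(points: np.ndarray, layout: dict):
    """Region id, radial distance (mm), local radius (mm) and axial unit
    direction for world-mm points, vectorised.  Region 0 = outside."""
    n = len(points)
    region = np.zeros(n, dtype=np.int8)
    rho = np.zeros(n)
    radius = np.full(n, np.inf)
    axis_dir = np.zeros((n, 3))

    z0 = layout["z0"]
    zb = layout["z0"] + layout["mpa_length_mm"]
    r_mpa = layout["mpa_radius_mm"]
    s = points[:, 0] - z0
    rr = np.hypot(points[:, 1], points[:, 2])
    in_mpa = (s >= 0) & (points[:, 0] <= zb) & (rr <= r_mpa)
    region[in_mpa] = MPA
    rho[in_mpa] = rr[in_mpa]
    radius[in_mpa] = r_mpa
    axis_dir[in_mpa] = (1.0, 0.0, 0.0)

    # branches claim unassigned points; overlap resolved by relative radius
    rel_best = np.full(n, np.inf)
    for br in layout["branches"]:
        rel = points - br["origin"]
        sb = rel @ br["dir"]
        perp = rel - np.outer(sb, br["dir"])
        rb = np.linalg.norm(perp, axis=1)
        inside = (sb >= 0) & (sb <= br["length_mm"]) & (rb <= br["radius_mm"])
        cand = inside & (region != MPA) & (rb / br["radius_mm"] < rel_best)
        region[cand] = br["region"]
        rho[cand] = rb[cand]
        radius[cand] = br["radius_mm"]
        axis_dir[cand] = br["dir"]
        rel_best[cand] = rb[cand] / br["radius_mm"]

    return region, rho, radius, axis_dir


def generate_bifurcation_geometry(
    spec: PhantomSpec, spacing: tuple[float, float, float] = (2.0, 2.5, 2.5)
) -> VesselGeometry:
    """Voxelize the Y-shaped phantom vessel at the given spacing (mm).

    Returns a :class:`VesselGeometry` whose labels are the generator's
    ground truth and whose ``meta`` carries the analytic layout (axes,
    radii, bifurcation point) for oracle computations.

    Raises
    ------
    ValueError
        If any vessel diameter spans fewer than 4 voxels at this
        spacing (under-resolved).
    """
    layout = _branch_layout(spec)
    radii_mm = [layout["mpa_radius_mm"]] + [b["radius_mm"] for b in layout["branches"]]
    if min(2.0 * r for r in radii_mm) < 4.0 * max(spacing):
        raise ValueError(
            f"radius under-resolved: smallest diameter {min(radii_mm)*2:.1f} mm "
            f"spans fewer than 4 voxels at spacing {max(spacing):.1f} mm"
        )

    margin = 6.0  # mm
    zb = layout["z0"] + layout["mpa_length_mm"]
    ext0 = zb + margin
    ext1 = layout["mpa_radius_mm"] + margin
    ext2 = layout["mpa_radius_mm"] + margin
    for br in layout["branches"]:
        end = br["origin"] + br["length_mm"] * br["dir"]
        ext0 = max(ext0, end[0] + br["radius_mm"] + margin)
        ext1 = max(ext1, abs(end[1]) + br["radius_mm"] + margin)
        ext2 = max(ext2, abs(end[2]) + br["radius_mm"] + margin)

    sp = np.asarray(spacing, dtype=float)
    shape = tuple(int(np.ceil(e / s)) for e, s in zip((ext0, 2 * ext1, 2 * ext2), sp))
    center_off = np.array([0.0, shape[1] * sp[1] / 2.0, shape[2] * sp[2] / 2.0])

    grids = np.meshgrid(*[(np.arange(n) + 0.5) * s for n, s in zip(shape, sp)], indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1) - center_off
    region, _, _, _ = _classify_points(pts, layout)
    # anatomical ground truth: the MPA extends to the carina, where the
    # lumen first splits (the branch cylinders overlap proximal to it)
    region = region.copy()
    region[(region != OUTSIDE) & (pts[:, 0] <= layout["carina_mm"])] = MPA
    labels = region.reshape(shape)
    mask = labels != OUTSIDE

    inlet_z = layout["z0"] + 2.0 * sp[0]
    inlet_plane = Plane(
        (inlet_z, center_off[1], center_off[2]), (1.0, 0.0, 0.0)
    )
    outlet_planes = {}
    for br in layout["branches"]:
        # branch-axis-normal cut, distal to the carina so the disc lies
        # in one branch only and clear of the truncated branch end
        dirx = max(br["dir"][0], 1e-6)
        s_car = max((layout["carina_mm"] - br["origin"][0]) / dirx, 0.0)
        s_plane = s_car + 0.3 * (br["length_mm"] - s_car)
        origin = br["origin"] + s_plane * br["dir"] + center_off
        outlet_planes[{LPA: "LPA", RPA: "RPA"}[br["region"]]] = Plane(
            tuple(origin), tuple(br["dir"])
        )

    meta = {
        "layout": layout,
        "center_offset": center_off,
        "spec": spec,
        "inlet_axial_mm": inlet_z,
    }
    return VesselGeometry(
        mask=mask,
        labels=labels,
        spacing=tuple(sp),
        inlet_plane=inlet_plane,
        outlet_planes=outlet_planes,
        meta=meta,
    )


# --------------------------------------------------------------------------
# velocity-field evaluation and study generation
# --------------------------------------------------------------------------

def _region_harmonics(spec: PhantomSpec) -> dict:
    c = spec.harmonics
    return {
        MPA: (c, spec.mpa_radius),
        LPA: (c * (1.0 - spec.rpa_fraction), spec.branch_radii[0]),
        RPA: (c * spec.rpa_fraction, spec.branch_radii[1]),
    }


def _field_at_points(points_mm: np.ndarray, t: float, spec: PhantomSpec, layout: dict) -> np.ndarray:
    """Velocity vectors (m/s) at world-mm points at time t (vectorised)."""
    region, rho_mm, radius_mm, axis_dir = _classify_points(points_mm, layout)
    out = np.zeros((len(points_mm), 3))
    per_region = _region_harmonics(spec)
    n_table = 512
    for rid in (MPA, LPA, RPA):
        sel = region == rid
        if not sel.any():
            continue
        c, radius = per_region[rid]
        if layout["degenerate"] and rid == MPA:
            c = per_region[MPA][0]
        rgrid = np.linspace(0.0, radius, n_table)
        prof = womersley_velocity(rgrid, t, c, radius, spec.nu, spec.period)
        u = np.interp(rho_mm[sel] * 1e-3, rgrid, prof)
        out[sel] = u[:, None] * axis_dir[sel]
    return out


def analytic_peak_velocity(spec: PhantomSpec, n_t: int = 200) -> float:
    """Maximum |velocity| of the analytic field over radius and time."""
    peak = 0.0
    tgrid = np.linspace(0.0, spec.period, n_t, endpoint=False)
    for c, radius in _region_harmonics(spec).values():
        rgrid = np.linspace(0.0, radius, 256)
        prof = womersley_velocity(rgrid[None, :], tgrid[:, None], c, radius, spec.nu, spec.period)
        peak = max(peak, float(np.max(np.abs(prof))))
    return peak


def generate_flow_study(
    spec: PhantomSpec,
    geometry: VesselGeometry | None = None,
    n_frames: int = 25,
    spacing: tuple[float, float, float] = (2.0, 2.5, 2.5),
    n_subsamples: int = 3,
) -> FlowMRIStudy:
    """Sample the analytic phantom field into a phase-contrast study.

    Interior voxels are sampled at their centres; voxels straddling the
    wall average ``n_subsamples**3`` (≥ 8) sub-samples with velocity
    zero outside the lumen, reproducing the near-wall partial-volume
    signal dilution of real acquisitions.  Zero-mean Gaussian noise of
    sd ``spec.noise_sd`` is added to every phase component (seeded),
    and velocities are clipped at the venc.

    Raises
    ------
    ValueError
        If the requested stroke volume / period imply analytic peak
        velocities above the venc (aliasing is not modelled), or
        ``n_frames`` < 10.
    """
    if n_frames < 10:
        raise ValueError("n_frames must be at least 10")
    if n_subsamples < 2:
        raise ValueError("need at least 2 subsamples per axis (>= 8 per voxel)")
    if geometry is None or tuple(geometry.spacing) != tuple(spacing):
        geometry = generate_bifurcation_geometry(spec, spacing)
    layout = geometry.meta["layout"]
    center_off = geometry.meta["center_offset"]
    sp = np.asarray(geometry.spacing)
    shape = geometry.mask.shape

    peak = analytic_peak_velocity(spec)
    if peak > spec.venc:
        raise ValueError(
            f"analytic peak velocity {peak:.2f} m/s exceeds venc {spec.venc:.2f} m/s; "
            "aliasing is not modelled — raise venc or lower stroke volume"
        )

    # wall band: voxels whose 26-neighbourhood crosses the lumen boundary
    struct = np.ones((3, 3, 3), dtype=bool)
    wall_band = ndimage.binary_dilation(geometry.mask, struct) & ~ndimage.binary_erosion(
        geometry.mask, struct
    )
    interior = geometry.mask & ~wall_band

    grids = np.meshgrid(*[(np.arange(n) + 0.5) * s for n, s in zip(shape, sp)], indexing="ij")
    centers = np.stack([g.ravel() for g in grids], axis=1) - center_off

    int_idx = np.flatnonzero(interior.ravel())
    wall_idx = np.flatnonzero(wall_band.ravel())

    # sub-voxel offsets (mm), midpoint rule per axis
    offs1d = [((np.arange(n_subsamples) + 0.5) / n_subsamples - 0.5) * s for s in sp]
    og = np.meshgrid(*offs1d, indexing="ij")
    offsets = np.stack([o.ravel() for o in og], axis=1)  # (S, 3)
    n_sub = len(offsets)

    wall_pts = (centers[wall_idx][:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    wall_region, _, _, _ = _classify_points(wall_pts, layout)
    lumen_frac_wall = (wall_region != OUTSIDE).reshape(-1, n_sub).mean(axis=1)

    frame_times = np.arange(n_frames) / n_frames * spec.period
    rng = np.random.default_rng(spec.seed)

    nvox = int(np.prod(shape))
    phase = np.zeros((n_frames, 3, nvox))
    for f, t in enumerate(frame_times):
        v_int = _field_at_points(centers[int_idx], t, spec, layout)
        v_wall = _field_at_points(wall_pts, t, spec, layout).reshape(-1, n_sub, 3).mean(axis=1)
        for c in range(3):
            phase[f, c, int_idx] = v_int[:, c]
            phase[f, c, wall_idx] = v_wall[:, c]
    phase = phase.reshape(n_frames, 3, *shape)

    lumen_frac = interior.astype(float)
    lumen_frac.ravel()[wall_idx] = lumen_frac_wall
    magnitude = np.broadcast_to(lumen_frac, (n_frames, *shape)).copy()

    if spec.noise_sd > 0:
        phase = phase + rng.normal(0.0, spec.noise_sd, size=phase.shape)
    phase = np.clip(phase, -spec.venc, spec.venc)

    return FlowMRIStudy(
        voxel_spacing=tuple(sp),
        frame_times=frame_times,
        magnitude=magnitude,
        phase_velocity=phase,
        venc=spec.venc,
        period=spec.period,
        meta={"spec": spec, "geometry": geometry},
    )


# --------------------------------------------------------------------------
# printed cohort fixture
# --------------------------------------------------------------------------

def _read_fixture(name: str) -> pd.DataFrame:
    with resources.files("pulmoflow.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_printed_cohort() -> pd.DataFrame:
    """The seven-patient printed cohort, indexed by patient id.

    Columns cover the cardiac cycle, stroke volume, RPA flow fraction
    and catheter mean PAP; per-branch Windkessel parameters (SI units:
    resistances in Pa·s·m⁻³, compliances in m³·Pa⁻¹); the paired
    4D-flow / CFD validation quantities; and the regional TAWSS
    averages (whole geometry and MPA-only), in Pa.
    """
    df = _read_fixture("printed_cohort.csv").set_index("patient")
    if len(df) != 7:
        raise ValueError("cohort fixture must contain exactly seven patients")
    if (df.select_dtypes("number") <= 0).any().any():
        raise ValueError("cohort fixture values must all be positive")
    for a, b in (
        ("rpa_fraction_4dflow", "lpa_fraction_4dflow"),
        ("rpa_fraction_cfd", "lpa_fraction_cfd"),
    ):
        if np.any(np.abs(df[a] + df[b] - 1.0) > 0.01):
            raise ValueError("branch flow fractions must sum to 1.00 ± 0.01")
    return df


def load_plane_tawss_summary() -> pd.DataFrame:
    """Cohort-average plane TAWSS (Pa): fine CFD vs voxel-grade 4D-flow."""
    return _read_fixture("plane_tawss_summary.csv").set_index("region")
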