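"""Three-element Windkessel (3EWK) tuning and 0D simulation.

Each pulmonary branch outlet is represented by a proximal resistance
R1 in series with a parallel distal resistance R2 / compliance C pair
(the downstream vascular bed).  The state equation for the compliance
pressure P_c driven by a prescribed flow Q(t) is

    C·dP_c/dt = Q − (P_c − P_d)/R2,       P(t) = R1·Q(t) + P_c(t),

with P_d the distal (venous) reference pressure, zero by default.

Tuning is non-invasive: the total branch resistance comes from a
target mean pressure over the branch's mean flow, split into proximal
and distal parts by a fraction f, and the compliance follows from a
prescribed decay time constant τ = R2·C.  Back-derivation from the
printed cohort gives f in 0.04–0.21 and τ in 0.60–0.72 s, so the
defaults f = 0.1, τ = 0.7 s sit mid-range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from pulmoflow.flowquant import FlowWaveform
from pulmoflow.units import pa_to_mmhg

__all__ = [
    "WindkesselParams",
    "PressureWaveform",
    "tune_3ewk",
    "simulate_3ewk",
    "periodicity_metric",
    "mean_pressure",
]

DEFAULT_PROXIMAL_FRACTION = 0.1
DEFAULT_TIME_CONSTANT = 0.7  # s


@dataclass(frozen=True)
class WindkesselParams:
    """3EWK parameters in SI units.

    R1, R2 in Pa·s·m⁻³; C in m³·Pa⁻¹; ``distal_pressure`` in Pa.
    """

    r1: float
    r2: float
    c: float
    distal_pressure: float = 0.0

    def __post_init__(self) -> None:
        if self.r1 < 0 or self.r2 <= 0 or self.c <= 0:
            raise ValueError("require R1 >= 0, R2 > 0, C > 0")

    @property
    def total_resistance(self) -> float:
        return self.r1 + self.r2

    @property
    def time_constant(self) -> float:
        """Diastolic decay time constant τ = R2·C, seconds."""
        return self.r2 * self.c


@dataclass
class PressureWaveform:
    """Pressure trace (Pa) on a uniform time grid with cycle indices."""

    times: np.ndarray
    pressure: np.ndarray
    cycle: np.ndarray
    period: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.cycle = np.asarray(self.cycle, dtype=int)

    @property
    def n_cycles(self) -> int:
        return int(self.cycle.max()) + 1

    def cycle_slice(self, c: int) -> np.ndarray:
        return self.pressure[self.cycle == c]


def tune_3ewk(
    mean_pap_target: float,
    branch_mean_flow: float,
    proximal_fraction: float = DEFAULT_PROXIMAL_FRACTION,
    time_constant: float = DEFAULT_TIME_CONSTANT,
    distal_pressure: float = 0.0,
) -> WindkesselParams:
    """Tune branch 3EWK parameters from mean pressure and mean flow.

    R_total = (mean_pap_target − distal_pressure) / branch_mean_flow,
    R1 = f·R_total, R2 = (1 − f)·R_total, C = τ/R2.

    Parameters are SI: pressure in Pa, flow in m³/s.
    """
    if branch_mean_flow <= 0:
        raise ValueError("branch mean flow must be positive")
    if not 0.0 <= proximal_fraction < 1.0:
        raise ValueError("proximal fraction must lie in [0, 1)")
    if time_constant <= 0:
        raise ValueError("time constant must be positive")
    r_total = (mean_pap_target - distal_pressure) / branch_mean_flow
    if r_total <= 0:
        raise ValueError("target pressure must exceed the distal pressure")
    r1 = proximal_fraction * r_total
    r2 = (1.0 - proximal_fraction) * r_total
    return WindkesselParams(r1=r1, r2=r2, c=time_constant / r2, distal_pressure=distal_pressure)


def simulate_3ewk(
    params: WindkesselParams,
    waveform: FlowWaveform,
    n_cycles: int = 3,
    dt: float = 0.005,
    pc0: float | None = None,
) -> PressureWaveform:
    """Integrate the 3EWK pressure response to a periodic flow waveform.

    Classical 4th-order Runge–Kutta at fixed step ``dt`` over
    ``n_cycles`` cardiac cycles; the compliance pressure starts at
    ``pc0`` (default: the distal pressure, i.e. a discharged bed).

    Raises
    ------
    ValueError
        If ``dt`` is coarser than T/50 or fewer than 3 cycles are
        requested, or the integration produces non-finite values.
    """
    T = waveform.period
    if dt > T / 50.0:
        raise ValueError("dt must be at most period/50")
    if n_cycles < 3:
        raise ValueError("at least three cardiac cycles are required")
    n_steps = int(round(n_cycles * T / dt))
    times = np.arange(n_steps + 1) * dt
    q = waveform(times)

    pc = np.empty(n_steps + 1)
    pc[0] = params.distal_pressure if pc0 is None else pc0

    def rhs(t, p):
        return (waveform(t) - (p - params.distal_pressure) / params.r2) / params.c

    for i in range(n_steps):
        t, p = times[i], pc[i]
        k1 = rhs(t, p)
        k2 = rhs(t + dt / 2, p + dt * k1 / 2)
        k3 = rhs(t + dt / 2, p + dt * k2 / 2)
        k4 = rhs(t + dt, p + dt * k3)
        pc[i + 1] = p + dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6

    if not np.all(np.isfinite(pc)):
        raise ValueError("3EWK integration produced non-finite pressures")
    pressure = params.r1 * q + pc
    # half-step guard keeps boundary samples in the cycle they close
    # despite floating-point drift of i*dt against multiples of T
    cycle = np.minimum(((times + 0.5 * dt) / T).astype(int), n_cycles - 1)
    return PressureWaveform(times=times, pressure=pressure, cycle=cycle, period=T)


def periodicity_metric(cycle_a: np.ndarray, cycle_b: np.ndarray) -> float:
    """Cycle-to-cycle variation in percent: 100·max|a − b| / max|b|.

    Below 1% the simulation is considered periodic.
    """
    a = np.asarray(cycle_a, dtype=float)
    b = np.asarray(cycle_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("cycles must have equal length")
    ref = np.max(np.abs(b))
    if ref == 0:
        raise ValueError("reference cycle is identically zero")
    return float(100.0 * np.max(np.abs(a - b)) / ref)


def mean_pressure(waveform: PressureWaveform, cycle: int = -1) -> tuple[float, float]:
    """Trapezoidal cycle-average pressure, returned as (Pa, mmHg)."""
    if cycle < 0:
        cycle = waveform.n_cycles + cycle
    sel = np.flatnonzero(waveform.cycle == cycle)
    if sel.size < 2:
        raise ValueError(f"cycle {cycle} not present")
    # include the first sample of the next cycle to close the interval
    end = sel[-1] + 1 if sel[-1] + 1 < len(waveform.times) else sel[-1]
    idx = np.r_[sel, end] if end != sel[-1] else sel
    t, p = waveform.times[idx], waveform.pressure[idx]
    span = t[-1] - t[0]
    if span < waveform.period * (1 - 1e-6):
        raise ValueError("incomplete cycle")
    pa = float(np.trapezoid(p, t) / span)
    return pa, float(pa_to_mmhg(pa))
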