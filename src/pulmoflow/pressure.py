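"""Echocardiogram-based pulmonary arterial pressure estimation.

Peak pulmonary arterial pressure (PAP) follows from the simplified
Bernoulli equation applied to the tricuspid regurgitant jet,

    peak PAP [mmHg] = 4·v² + RAP,

with v the peak tricuspid valve velocity (m/s) and RAP the clinician's
estimate of right atrial pressure (mmHg).  Mean PAP then follows from
the empirical Chemla relation

    mean PAP = 0.61·peak PAP + 2.

Pulmonary hypertension is defined as mean PAP strictly above 20 mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "EchoMeasurement",
    "PressureEstimate",
    "peak_pap_bernoulli",
    "mean_pap_from_peak",
    "classify_ph",
    "estimate_pressures",
]

#: Diagnostic threshold for pulmonary hypertension, mmHg (strict).
PH_THRESHOLD_MMHG = 20.0

CHEMLA_SLOPE = 0.61
CHEMLA_INTERCEPT = 2.0


@dataclass(frozen=True)
class EchoMeasurement:
    """Echocardiographic inputs: tricuspid jet velocity and RAP estimate."""

    tricuspid_peak_velocity: float  # m/s
    right_atrial_pressure: float  # mmHg

    def __post_init__(self) -> None:
        if self.tricuspid_peak_velocity < 0:
            raise ValueError("tricuspid peak velocity must be >= 0")
        if self.right_atrial_pressure < 0:
            raise ValueError("right atrial pressure must be >= 0")


@dataclass(frozen=True)
class PressureEstimate:
    """Peak and mean PAP in mmHg, tagged by provenance (echo or RHC)."""

    peak_pap: float
    mean_pap: float
    source: str = "echo"


def peak_pap_bernoulli(echo: EchoMeasurement) -> float:
    """Peak PAP [mmHg] = 4·v² + RAP (simplified Bernoulli)."""
    v = echo.tricuspid_peak_velocity
    return 4.0 * v * v + echo.right_atrial_pressure


def mean_pap_from_peak(peak_pap: float) -> float:
    """Mean PAP [mmHg] from peak PAP via the Chemla relation."""
    if peak_pap < 0:
        raise ValueError("peak PAP must be >= 0")
    return CHEMLA_SLOPE * peak_pap + CHEMLA_INTERCEPT


def classify_ph(mean_pap: float) -> bool:
    """True iff mean PAP exceeds the 20 mmHg diagnostic threshold (strict)."""
    return mean_pap > PH_THRESHOLD_MMHG


def estimate_pressures(echo: EchoMeasurement) -> PressureEstimate:
    """Full echo pipeline: Bernoulli peak PAP, then Chemla mean PAP."""
    peak = peak_pap_bernoulli(echo)
    return PressureEstimate(peak_pap=peak, mean_pap=mean_pap_from_peak(peak), source="echo")
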