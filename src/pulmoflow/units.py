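"""Unit conversion constants shared across the package.

All internal computation is SI (m, s, Pa, m³/s).  Clinical quantities
are converted at the interfaces: pressures print in mmHg, stroke
volumes in mL.
"""

#: Pascals per millimetre of mercury; single source of truth for every
#: pressure conversion in the package.
MMHG_TO_PA: float = 133.322

#: Cubic metres per millilitre.
ML_TO_M3: float = 1.0e-6


def mmhg_to_pa(p_mmhg):
    """Convert pressure from mmHg to Pa."""
    return p_mmhg * MMHG_TO_PA


def pa_to_mmhg(p_pa):
    """Convert pressure from Pa to mmHg."""
    return p_pa / MMHG_TO_PA
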