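"""Quemada shear-thinning blood rheology.

The Quemada model treats blood as a concentrated suspension of red
cells in plasma.  The apparent viscosity is

    mu(γ̇) = mu_p · (1 − k(γ̇)·φ/2)⁻²

where ``mu_p`` is the plasma viscosity, ``φ`` the hematocrit and the
shear-dependent intrinsic viscosity interpolates between a low-shear
limit ``k0`` (rouleaux aggregates) and a high-shear limit ``k_inf``
(dispersed, deformed cells):

    k(γ̇) = (k0 + k_inf·sqrt(γ̇/γ_c)) / (1 + sqrt(γ̇/γ_c))

with ``γ_c`` a critical shear rate.  Default constants are the widely
used literature values for normal blood at φ = 0.45.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RheologyParams", "quemada_viscosity", "viscosity_bounds"]


@dataclass(frozen=True)
class RheologyParams:
    """Parameters of the Quemada viscosity law.

    Attributes
    ----------
    plasma_viscosity : float
        Plasma (suspending fluid) viscosity mu_p, Pa·s.
    hematocrit : float
        Red-cell volume fraction φ, dimensionless in [0, 1).
    k0 : float
        Zero-shear intrinsic viscosity limit.
    k_inf : float
        Infinite-shear intrinsic viscosity limit.
    gamma_c : float
        Critical shear rate γ_c, 1/s.
    shear_floor : float
        Shear rates below this value are floored before evaluating the
        law, avoiding the zero-shear singularity when k0·φ/2 ≥ 1.
    """

    plasma_viscosity: float = 1.32e-3
    hematocrit: float = 0.45
    k0: float = 4.33
    k_inf: float = 2.07
    gamma_c: float = 1.88
    shear_floor: float = 1.0e-3

    def __post_init__(self) -> None:
        if self.plasma_viscosity <= 0:
            raise ValueError("plasma viscosity must be positive")
        if not 0.0 <= self.hematocrit < 1.0:
            raise ValueError("hematocrit must lie in [0, 1)")
        if self.gamma_c <= 0:
            raise ValueError("critical shear rate must be positive")
        if 0.5 * self.k_inf * self.hematocrit >= 1.0:
            raise ValueError(
                "0.5*k_inf*hematocrit must be < 1 for a finite "
                "high-shear viscosity"
            )


def quemada_viscosity(shear_rate, params: RheologyParams = RheologyParams()):
    """Apparent viscosity mu(γ̇) of the Quemada model, Pa·s.

    Parameters
    ----------
    shear_rate : array_like
        Shear rate γ̇ ≥ 0, 1/s.  Values below ``params.shear_floor``
        are floored.
    params : RheologyParams
        Model constants.

    Returns
    -------
    ndarray or float
        Viscosity, same shape as ``shear_rate``.
    """
    g = np.asarray(shear_rate, dtype=float)
    if np.any(g < 0):
        raise ValueError("shear rate must be non-negative")
    g = np.maximum(g, params.shear_floor)
    s = np.sqrt(g / params.gamma_c)
    k = (params.k0 + params.k_inf * s) / (1.0 + s)
    denom = 1.0 - 0.5 * k * params.hematocrit
    if np.any(denom <= 0):
        raise ValueError(
            "Quemada viscosity diverges: 0.5*k*hematocrit >= 1 at the "
            "(floored) shear rate; raise shear_floor or lower k0/hematocrit"
        )
    mu = params.plasma_viscosity / denom**2
    return mu if mu.ndim else float(mu)


def viscosity_bounds(params: RheologyParams = RheologyParams()):
    """High- and low-shear viscosity limits ``(mu_inf, mu_0)``.

    ``mu_inf`` is the γ̇ → ∞ limit; ``mu_0`` the γ̇ → 0 limit, which is
    ``inf`` when 0.5·k0·φ ≥ 1 (yield-like behaviour at rest).  ``mu_inf``
    is the reference viscosity used for Reynolds/Womersley numbers and
    for voxel-grade wall shear stress.
    """
    mu_inf = params.plasma_viscosity / (1.0 - 0.5 * params.k_inf * params.hematocrit) ** 2
    d0 = 1.0 - 0.5 * params.k0 * params.hematocrit
    mu_0 = params.plasma_viscosity / d0**2 if d0 > 0 else float("inf")
    return mu_inf, mu_0
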