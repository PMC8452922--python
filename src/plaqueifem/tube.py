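"""Semi-analytic inflation of a concentric incompressible thick-walled tube.

Independent validation oracle for the plane-strain FE solver.  Under
plane-strain, incompressible kinematics the deformation of an annulus
``Ri <= R <= Ro`` is the area-preserving radial map

    r(R)^2 = R^2 + (ri^2 - Ri^2),

with principal stretches ``lambda_theta = r/R``, ``lambda_r = R/r``,
``lambda_z = 1``.  Radial equilibrium integrates to the classical relation

    P = int_{ri}^{ro} (sigma_theta - sigma_r) / r dr
      = int_{Ri}^{Ro} 2 W'(I1) (lt^2 - lt^-2) R / r^2 dR,

with ``lt = r/R`` and ``I1 = lt^2 + lt^-2 + 1``.  The integral is evaluated
over the fixed reference domain (change of variables to R).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .errors import ConfigurationError, OutOfRangeError
from .materials import MaterialModel

__all__ = ["TubeSpec", "tube_pressure", "tube_inflate", "inner_displacement"]


@dataclass(frozen=True)
class TubeSpec:
    inner_radius: float  # mm
    outer_radius: float  # mm
    material: MaterialModel

    def __post_init__(self):
        if not 0.0 < self.inner_radius < self.outer_radius:
            raise ConfigurationError("require 0 < Ri < Ro")


def _integrand(R, spec: TubeSpec, delta: float):
    r2 = R * R + delta
    lt2 = r2 / (R * R)
    i1 = lt2 + 1.0 / lt2 + 1.0
    return 2.0 * spec.material.dW_dI1(i1) * (lt2 - 1.0 / lt2) * R / r2


def tube_pressure(spec: TubeSpec, inner_stretch: float) -> float:
    """Intraluminal pressure (kPa) producing inner stretch ``lambda_i >= 1``."""
    if inner_stretch < 1.0 - 1e-12:
        raise OutOfRangeError("inner stretch < 1 not supported")
    if inner_stretch == 1.0:
        return 0.0
    delta = spec.inner_radius**2 * (inner_stretch**2 - 1.0)
    val, _ = quad(
        _integrand,
        spec.inner_radius,
        spec.outer_radius,
        args=(spec, delta),
        epsabs=1e-13,
        epsrel=1e-11,
        limit=200,
    )
    return val


def tube_inflate(spec: TubeSpec, pressure: float, lam_max: float = 64.0) -> float:
    """Inner stretch ``lambda_i`` at a given pressure (kPa); inverse of
    :func:`tube_pressure` by bracketed root finding.

    The bracket expands geometrically until the pressure is straddled; if the
    material admits a limit point below ``pressure`` a no-solution error is
    raised.
    """
    if pressure < 0.0:
        raise OutOfRangeError("pressure must be >= 0")
    if pressure == 0.0:
        return 1.0
    hi = 1.05
    while tube_pressure(spec, hi) < pressure:
        hi *= 1.3
        if hi > lam_max:
            raise OutOfRangeError(
                f"pressure {pressure} kPa not reached by lambda_i <= {lam_max} "
                "(at or beyond a limit point)"
            )
    return brentq(
        lambda lam: tube_pressure(spec, lam) - pressure, 1.0, hi, xtol=1e-12, rtol=1e-12
    )


def inner_displacement(spec: TubeSpec, pressure: float) -> float:
    """Radial displacement of the lumen boundary (mm) at ``pressure`` kPa."""
    return (tube_inflate(spec, pressure) - 1.0) * spec.inner_radius
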