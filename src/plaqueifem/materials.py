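"""Isotropic incompressible hyperelastic constitutive models.

Two strain-energy densities are supported, both functions of the first
invariant ``I1`` of the left/right Cauchy-Green tensor only:

* Neo-Hookean:  ``W = c1 (I1 - 3)``
* Yeoh:         ``W = sum_{i=1..3} c_i (I1 - 3)^i``

Constants are in kPa.  The Yeoh model captures the strain-stiffening of
fibrous arterial tissue; the Neo-Hookean model is used for the nearly
featureless lipid (soft, 1 kPa) and calcium (quasi-rigid, 1 GPa) inclusions.

The module also provides the Yeoh stability screen

    c1 > 0,   -3 c1 c3 < c2 < inf,   c3 > 0   (strict inequalities)

and the uniaxial post-processing used to compare fitted constants across
studies: for an incompressible uniaxial stretch ``lambda`` the transverse
stretches are ``lambda^(-1/2)``, ``I1 = lambda^2 + 2/lambda`` and the Cauchy
stress is ``sigma = 2 (lambda^2 - 1/lambda) dW/dI1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import ConfigurationError, OutOfRangeError

__all__ = [
    "MaterialKind",
    "MaterialModel",
    "StabilityVerdict",
    "StressStretchCurve",
    "neo_hookean",
    "yeoh",
    "strain_energy",
    "uniaxial_cauchy_stress",
    "plane_strain_cauchy_stress",
    "check_yeoh_stability",
    "default_component_materials",
    "stress_stretch_curve",
    "material_to_dict",
    "material_from_dict",
]


class MaterialKind(str, Enum):
    NEO_HOOKEAN = "neo_hookean"
    YEOH = "yeoh"


_N_CONSTANTS = {MaterialKind.NEO_HOOKEAN: 1, MaterialKind.YEOH: 3}


@dataclass(frozen=True)
class MaterialModel:
    """A constitutive law: kind plus ordered constants in kPa."""

    kind: MaterialKind
    constants: tuple
    name: str = ""
    #: placeholder models awaiting optimization (intima/wall before fitting)
    to_fit: bool = False

    def __post_init__(self):
        kind = MaterialKind(self.kind)
        object.__setattr__(self, "kind", kind)
        consts = tuple(float(c) for c in self.constants)
        if len(consts) != _N_CONSTANTS[kind]:
            raise ConfigurationError(
                f"{kind.value} takes {_N_CONSTANTS[kind]} constant(s), "
                f"got {len(consts)}"
            )
        if not all(math.isfinite(c) for c in consts):
            raise ConfigurationError(f"non-finite material constants: {consts}")
        object.__setattr__(self, "constants", consts)

    # -- polynomial coefficients (c1, c2, c3); neo-hookean is yeoh(c1, 0, 0)
    @property
    def _c123(self):
        if self.kind is MaterialKind.NEO_HOOKEAN:
            return (self.constants[0], 0.0, 0.0)
        return self.constants

    def strain_energy(self, i1):
        """Strain energy density W(I1) in kPa (I1 >= 3)."""
        i1 = np.asarray(i1, dtype=float)
        if np.any(i1 < 3.0 - 1e-12):
            raise OutOfRangeError("I1 < 3 is not attainable for isochoric deformation")
        c1, c2, c3 = self._c123
        x = i1 - 3.0
        return (c1 + (c2 + c3 * x) * x) * x

    def dW_dI1(self, i1):
        """First derivative dW/dI1 (kPa)."""
        c1, c2, c3 = self._c123
        x = np.asarray(i1, dtype=float) - 3.0
        return c1 + 2.0 * c2 * x + 3.0 * c3 * x * x

    def d2W_dI12(self, i1):
        """Second derivative d2W/dI1^2 (kPa)."""
        _, c2, c3 = self._c123
        x = np.asarray(i1, dtype=float) - 3.0
        return 2.0 * c2 + 6.0 * c3 * x


def material_to_dict(model: MaterialModel) -> dict:
    """Config-block form of a material (name, kind, constants in kPa)."""
    return {"name": model.name, "kind": model.kind.value,
            "constants_kPa": list(model.constants), "to_fit": model.to_fit}


def material_from_dict(block: dict) -> MaterialModel:
    return MaterialModel(MaterialKind(block["kind"]),
                         tuple(block["constants_kPa"]),
                         name=block.get("name", ""),
                         to_fit=bool(block.get("to_fit", False)))


def neo_hookean(c1: float, name: str = "", to_fit: bool = False) -> MaterialModel:
    return MaterialModel(MaterialKind.NEO_HOOKEAN, (c1,), name=name, to_fit=to_fit)


def yeoh(c1: float, c2: float, c3: float, name: str = "", to_fit: bool = False) -> MaterialModel:
    return MaterialModel(MaterialKind.YEOH, (c1, c2, c3), name=name, to_fit=to_fit)


@dataclass(frozen=True)
class StabilityVerdict:
    stable: bool
    violated_conditions: tuple = ()

    def __post_init__(self):
        assert self.stable == (len(self.violated_conditions) == 0)


@dataclass(frozen=True)
class StressStretchCurve:
    """Uniaxial Cauchy stress (kPa) vs stretch ratio (lambda >= 1)."""

    stretch_ratios: np.ndarray
    cauchy_stress: np.ndarray

    def __post_init__(self):
        lam = np.asarray(self.stretch_ratios, dtype=float)
        sig = np.asarray(self.cauchy_stress, dtype=float)
        if lam.shape != sig.shape:
            raise ConfigurationError("stretch and stress arrays must be congruent")
        object.__setattr__(self, "stretch_ratios", lam)
        object.__setattr__(self, "cauchy_stress", sig)


def strain_energy(model: MaterialModel, i1):
    """Strain energy density W(I1) in kPa."""
    return model.strain_energy(i1)


def uniaxial_cauchy_stress(model: MaterialModel, stretch):
    """Cauchy stress (kPa) under incompressible uniaxial tension.

    Kinematics: principal stretches (lambda, lambda^-1/2, lambda^-1/2), so
    I1 = lambda^2 + 2/lambda and sigma = 2 (lambda^2 - 1/lambda) dW/dI1.
    Accepts scalars or arrays; lambda < 1 (compression) is out of scope.
    """
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam < 1.0 - 1e-12):
        raise OutOfRangeError("uniaxial stretch < 1 (compression) not supported")
    i1 = lam**2 + 2.0 / lam
    sigma = 2.0 * (lam**2 - 1.0 / lam) * model.dW_dI1(i1)
    return sigma if sigma.ndim else float(sigma)


def stress_stretch_curve(model: MaterialModel, stretches) -> StressStretchCurve:
    lam = np.asarray(stretches, dtype=float)
    return StressStretchCurve(lam, uniaxial_cauchy_stress(model, lam))


def plane_strain_cauchy_stress(model: MaterialModel, deformation_gradient_2d, hydrostatic_pressure):
    """Cauchy stress tensor (2x2, kPa) for plane-strain incompressible response.

    The out-of-plane stretch is 1 and is included in I1, so
    ``I1 = tr(F F^T) + 1`` and the in-plane stress is

        sigma = 2 dW/dI1 * B - p * I,    B = F F^T.

    The hydrostatic pressure ``p`` is the solver's mixed unknown; a
    stress-free identity state corresponds to ``p = 2 dW/dI1(3)``.
    """
    f = np.asarray(deformation_gradient_2d, dtype=float)
    if f.shape != (2, 2):
        raise ConfigurationError("deformation gradient must be 2x2")
    det = f[0, 0] * f[1, 1] - f[0, 1] * f[1, 0]
    if abs(det) < 1e-12:
        raise FloatingPointError("singular in-plane deformation gradient")
    b = f @ f.T
    i1 = b[0, 0] + b[1, 1] + 1.0
    return 2.0 * model.dW_dI1(i1) * b - hydrostatic_pressure * np.eye(2)


def check_yeoh_stability(c1: float, c2: float, c3: float) -> StabilityVerdict:
    """Screen a Yeoh constant triplet against the stability criteria.

    Stable iff c1 > 0, c3 > 0 and c2 > -3 c1 c3 (strict; equality fails).
    """
    violated = []
    if not c1 > 0.0:
        violated.append("c1_nonpositive")
    if not c3 > 0.0:
        violated.append("c3_nonpositive")
    if not c2 > -3.0 * c1 * c3:
        violated.append("c2_below_lower_bound")
    return StabilityVerdict(stable=not violated, violated_conditions=tuple(violated))


#: Typical Yeoh constants for initializing to-be-fitted components (kPa).
#: These are representative soft-tissue magnitudes, not fit results.
_INTIMA_PLACEHOLDER = (1.0, 0.2, 0.4)
_WALL_PLACEHOLDER = (6.0, -0.3, 190.0)


def default_component_materials() -> dict:
    """Default material assignment per cross-section component.

    Lipid and calcium are fixed Neo-Hookean solids (1 kPa and 1 GPa = 1e6 kPa
    respectively); fibrous intima and wall are Yeoh placeholders flagged
    ``to_fit`` — their constants are the quantities the inverse pipeline
    estimates.
    """
    return {
        "lipid": neo_hookean(1.0, name="lipid"),
        "calcium": neo_hookean(1.0e6, name="calcium"),
        "intima": yeoh(*_INTIMA_PLACEHOLDER, name="intima", to_fit=True),
        "wall": yeoh(*_WALL_PLACEHOLDER, name="wall", to_fit=True),
    }
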