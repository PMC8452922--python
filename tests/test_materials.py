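import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plaqueifem.errors import ConfigurationError, OutOfRangeError
from plaqueifem.materials import (MaterialKind, MaterialModel,
                                  check_yeoh_stability,
                                  default_component_materials, neo_hookean,
                                  plane_strain_cauchy_stress, strain_energy,
                                  stress_stretch_curve, uniaxial_cauchy_stress,
                                  yeoh)


def finite_difference_uniaxial(model, lam, h=1e-6):
    """Independent oracle: sigma = lambda * dW/dlambda along the
    incompressible uniaxial path I1(lambda) = lambda^2 + 2/lambda."""
    def w(s):
        return model.strain_energy(s**2 + 2.0 / s)
    return lam * (w(lam + h) - w(lam - h)) / (2 * h)


@pytest.mark.parametrize("model, i1, expected", [
    (yeoh(1, 1, 1), 4.0, 3.0),
    (yeoh(2.5, -0.3, 7.0), 3.0, 0.0),
    (neo_hookean(1.0), 3.5, 0.5),
    (neo_hookean(3.0), 3.0, 0.0),
])
def test_strain_energy_reference_points(model, i1, expected):
    assert strain_energy(model, i1) == pytest.approx(expected, abs=1e-12)


def test_constant_count_is_enforced():
    with pytest.raises(ConfigurationError):
        MaterialModel(MaterialKind.YEOH, (1.0, 2.0))
    with pytest.raises(ConfigurationError):
        MaterialModel(MaterialKind.NEO_HOOKEAN, (1.0, 2.0))
    with pytest.raises(ConfigurationError):
        MaterialModel(MaterialKind.YEOH, (1.0, np.nan, 2.0))


@pytest.mark.parametrize("model", [
    neo_hookean(7.0), yeoh(0.10, 0.04, 0.15), yeoh(18.99, -96.68, 289.37),
])
def test_uniaxial_stress_matches_energy_derivative_oracle(model):
    """sigma(lambda) must equal lambda * dW/dlambda (finite differences) to
    high relative accuracy across the tensile range."""
    lams = np.linspace(1.01, 1.5, 25)
    sig = uniaxial_cauchy_stress(model, lams)
    oracle = np.array([finite_difference_uniaxial(model, l) for l in lams])
    assert np.allclose(sig, oracle, rtol=1e-6)


def test_uniaxial_stress_vanishes_at_identity_and_rejects_compression():
    assert uniaxial_cauchy_stress(yeoh(3, 2, 1), 1.0) == 0.0
    with pytest.raises(OutOfRangeError):
        uniaxial_cauchy_stress(neo_hookean(1.0), 0.9)


def test_uniaxial_stress_known_value_for_soft_intima():
    # frozen from the finite-difference oracle for (0.10, 0.04, 0.15) kPa
    sig = uniaxial_cauchy_stress(yeoh(0.10, 0.04, 0.15), 1.1)
    assert sig == pytest.approx(0.0617537, abs=1e-6)


@given(st.floats(0.2, 5.0), st.floats(1.0, 1.4))
@settings(max_examples=30, deadline=None)
def test_stress_is_linear_in_the_constants(k, lam):
    base = yeoh(1.2, -0.4, 3.0)
    scaled = yeoh(*(k * c for c in base.constants))
    assert uniaxial_cauchy_stress(scaled, lam) == pytest.approx(
        k * uniaxial_cauchy_stress(base, lam), rel=1e-12, abs=1e-12)


@given(st.floats(3.0, 6.0))
@settings(max_examples=25, deadline=None)
def test_yeoh_with_single_constant_reduces_to_neo_hookean(i1):
    nh, yh = neo_hookean(2.7), yeoh(2.7, 0.0, 0.0)
    assert strain_energy(yh, i1) == strain_energy(nh, i1)
    assert yh.dW_dI1(i1) == nh.dW_dI1(i1)


def test_plane_strain_stress_free_identity_and_neo_hookean_limit():
    model = neo_hookean(4.0)
    sigma = plane_strain_cauchy_stress(model, np.eye(2), 2 * 4.0)
    assert np.allclose(sigma, 0.0, atol=1e-12)
    sigma0 = plane_strain_cauchy_stress(model, np.eye(2), 0.0)
    assert np.allclose(sigma0, 2 * 4.0 * np.eye(2))


@pytest.mark.parametrize("lam", [1.05, 1.3])
def test_plane_strain_equibiaxial_principal_difference(lam):
    model = yeoh(1.5, 0.3, 2.0)
    f = np.diag([lam, 1 / lam])
    i1 = lam**2 + lam**-2 + 1
    sigma = plane_strain_cauchy_stress(model, f, 0.77)
    expected = 2 * model.dW_dI1(i1) * (lam**2 - lam**-2)
    assert sigma[0, 0] - sigma[1, 1] == pytest.approx(expected, rel=1e-12)


def test_plane_strain_matches_yeoh_neo_hookean_equivalence():
    rng = np.random.default_rng(4)
    f = np.eye(2) + 0.2 * rng.standard_normal((2, 2))
    a = plane_strain_cauchy_stress(neo_hookean(1.0), f, 0.3)
    b = plane_strain_cauchy_stress(yeoh(1.0, 0.0, 0.0), f, 0.3)
    assert np.allclose(a, b)


@pytest.mark.parametrize("c, stable, violations", [
    ((0.10, 0.04, 0.15), True, ()),
    ((18.99, -96.68, 289.37), True, ()),           # -3 c1 c3 ~ -16487 < c2
    ((-1.0, 0.0, 1.0), False, ("c1_nonpositive", "c2_below_lower_bound")),
    ((1.0, -4.0, 1.0), False, ("c2_below_lower_bound",)),
    # with c3 = 0 the lower bound for c2 degenerates to c2 > 0, so both fail
    ((1.0, 0.0, 0.0), False, ("c3_nonpositive", "c2_below_lower_bound")),
    ((0.0, 1.0, 1.0), False, ("c1_nonpositive",)),  # equality counts as unstable
    ((1.0, -3.0, 1.0), False, ("c2_below_lower_bound",)),  # c2 == -3 c1 c3
])
def test_yeoh_stability_screen(c, stable, violations):
    verdict = check_yeoh_stability(*c)
    assert verdict.stable is stable
    assert set(verdict.violated_conditions) == set(violations)


def test_default_component_materials():
    mats = default_component_materials()
    assert mats["lipid"].constants == (1.0,)
    assert mats["calcium"].constants == (1.0e6,)
    assert mats["intima"].to_fit and mats["wall"].to_fit
    assert mats["intima"].kind is MaterialKind.YEOH


def test_stress_stretch_curve_container():
    curve = stress_stretch_curve(yeoh(1, 0.2, 3), np.linspace(1, 1.3, 7))
    assert curve.cauchy_stress[0] == 0.0
    assert curve.stretch_ratios.shape == curve.cauchy_stress.shape


def test_material_config_round_trip():
    import yaml

    from plaqueifem.materials import material_from_dict, material_to_dict
    m = yeoh(1.2, -0.3, 4.0, name="intima", to_fit=True)
    block = yaml.safe_load(yaml.safe_dump(material_to_dict(m)))
    assert material_from_dict(block) == m
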