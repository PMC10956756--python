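"""Constitutive oracles: Yeoh energy, plane-stress membrane stress, trusses."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pelvifem.constitutive import (
    membrane_stress,
    plane_stress_I1,
    truss_force,
    uniaxial_membrane_stress,
    yeoh_energy_density,
)
from pelvifem.errors import ParameterError, StateError
from pelvifem.materials import MaterialModel, default_materials

VAGINA = MaterialModel.yeoh(0.111, 0.27)
BLADDER = MaterialModel.yeoh(0.0375, 0.07)
RECTUM = MaterialModel.yeoh(0.085, 0.056)
ORGANS = [VAGINA, BLADDER, RECTUM]


class TestYeohEnergy:
    def test_zero_at_reference(self):
        for mat in ORGANS:
            assert yeoh_energy_density(3.0, mat) == 0.0

    def test_hand_evaluated_value(self):
        # W(3.5) = 0.111*0.5 + 0.27*0.25 for the vaginal coefficients
        assert yeoh_energy_density(3.5, VAGINA) == pytest.approx(0.123, rel=1e-12)

    def test_neo_hookean_limit_is_linear(self):
        mat = MaterialModel.yeoh(0.2, 0.0)
        x = np.array([3.1, 3.5, 4.0])
        np.testing.assert_allclose(
            yeoh_energy_density(x, mat), 0.2 * (x - 3.0), rtol=1e-14
        )

    def test_rejects_non_yeoh_material(self):
        with pytest.raises(ParameterError):
            yeoh_energy_density(3.2, MaterialModel.linear_elastic(1.0, 0.3))

    def test_rejects_unattainable_invariant(self):
        with pytest.raises(StateError):
            yeoh_energy_density(2.5, VAGINA)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.floats(3.0, 9.0), st.floats(3.0, 9.0),
    )
    def test_monotone_increasing_in_invariant(self, i1, i2):
        lo, hi = sorted((i1, i2))
        for mat in ORGANS:
            assert yeoh_energy_density(hi, mat) >= yeoh_energy_density(lo, mat)


class TestMembraneStress:
    def test_reference_state_is_stress_free(self):
        for mat in ORGANS + [MaterialModel.linear_elastic(0.1, 0.45)]:
            s1, s2 = membrane_stress(1.0, 1.0, mat)
            assert s1 == pytest.approx(0.0, abs=1e-14)
            assert s2 == pytest.approx(0.0, abs=1e-14)

    @pytest.mark.parametrize("mat", ORGANS)
    def test_equibiaxial_matches_energy_differentiation(self, mat):
        """sigma_i = lam_i dW/dlam_i with lam3 eliminated; the oracle is
        central-difference differentiation of the reduced energy."""
        lam = 1.2
        h = 1e-6

        def W(l1, l2):
            return yeoh_energy_density(plane_stress_I1(l1, l2), mat)

        s1_fd = lam * (W(lam + h, lam) - W(lam - h, lam)) / (2 * h)
        s1, s2 = membrane_stress(lam, lam, mat)
        assert s1 == pytest.approx(s1_fd, rel=1e-6)
        assert s2 == pytest.approx(s1_fd, rel=1e-6)

    @pytest.mark.parametrize("mat", ORGANS)
    def test_uniaxial_closed_form(self, mat):
        """sigma = 2*(lam^2 - 1/lam)*(C0 + 2*C1*(I1-3)), I1 = lam^2 + 2/lam."""
        lam = 1.3
        lam2 = lam**-0.5  # lateral contraction of the uniaxial stress state
        s1, s2 = membrane_stress(lam, lam2, mat)
        I1 = lam**2 + 2.0 / lam
        expected = 2.0 * (lam**2 - 1.0 / lam) * (mat.C0 + 2.0 * mat.C1 * (I1 - 3.0))
        assert s1 == pytest.approx(expected, rel=1e-8)
        assert s2 == pytest.approx(0.0, abs=1e-10 * abs(expected))
        assert uniaxial_membrane_stress(lam, mat) == pytest.approx(expected, rel=1e-12)

    def test_linear_elastic_small_strain_matches_hooke(self):
        E, nu = 0.18, 0.45
        mat = MaterialModel.linear_elastic(E, nu)
        eps = 1e-5
        s1, s2 = membrane_stress(1.0 + eps, 1.0 - nu * eps, mat)
        assert s1 == pytest.approx(E * eps, rel=1e-3)
        assert s2 == pytest.approx(0.0, abs=E * eps * 1e-2)

    def test_rejects_nonpositive_stretch(self):
        with pytest.raises(StateError):
            membrane_stress(-1.0, 1.0, VAGINA)


class TestTrussForce:
    def test_reference_and_slack_states(self):
        assert truss_force(1.0, 1000.0, 0.2) == 0.0
        assert truss_force(0.9, 1000.0, 0.2) == 0.0  # slack filament

    def test_hand_value_at_five_percent_stretch(self):
        # E = 1000 MPa, A = 0.2 mm^2, lam = 1.05 -> N = 10 N
        assert truss_force(1.05, 1000.0, 0.2) == pytest.approx(10.0, rel=1e-12)

    def test_compression_carried_when_not_tension_only(self):
        assert truss_force(0.95, 100.0, 2.0, tension_only=False) == pytest.approx(
            -10.0
        )


def test_default_material_table_assignments():
    """The soft-tissue assignment: Yeoh organs, elastic support structures."""
    table = default_materials()
    assert table["vagina"] == VAGINA
    assert table["bladder"] == BLADDER
    assert table["rectum"] == RECTUM
    assert table["pelvic_floor"].E == pytest.approx(0.1)
    assert table["fascia_pubocervical"].E == pytest.approx(0.18)
    assert table["pelvic_floor"].nu == pytest.approx(0.45)
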