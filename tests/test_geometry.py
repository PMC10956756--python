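"""Synthetic pelvic geometry: symmetry, determinism, support conditions."""
import numpy as np
import pytest

from pelvifem.errors import GeometryError, ParameterError
from pelvifem.geometry import (
    PATHOLOGICAL_DISABLED,
    GeometryParams,
    apply_support_condition,
    build_pelvic_geometry,
    geometry_from_json,
    geometry_to_json,
    patient_like_params,
)

MIRROR = np.array([-1.0, 1.0, 1.0])


@pytest.fixture(scope="module")
def generic():
    return build_pelvic_geometry(GeometryParams(seed=1))


@pytest.fixture(scope="module")
def patient():
    return build_pelvic_geometry(patient_like_params(seed=1))


class TestSymmetry:
    def test_landmark_mirror_residual_is_zero(self, generic):
        lm = generic.landmarks
        assert np.allclose(
            lm["ischial_spine_left"], lm["ischial_spine_right"] * MIRROR, atol=1e-9
        )
        assert np.allclose(
            lm["sacrospinous_insertion_left"],
            lm["sacrospinous_insertion_right"] * MIRROR,
            atol=1e-9,
        )

    def test_surfaces_are_mirror_symmetric_point_sets(self, generic):
        from scipy.spatial import cKDTree

        for name, surf in generic.organ_surfaces.items():
            tree = cKDTree(surf.vertices)
            d, _ = tree.query(surf.vertices * MIRROR)
            assert d.max() < 1e-9, name

    def test_patient_variant_is_asymmetric(self, patient):
        assert not patient.symmetric
        bl = patient.organ_surfaces["bladder"].vertices
        assert abs(bl[:, 0].mean()) > 1.0  # lateral bladder shift

    def test_mirror_param_reflects_and_swaps_sides(self):
        a = build_pelvic_geometry(GeometryParams(seed=3))
        b = build_pelvic_geometry(GeometryParams(seed=3, mirror=True))
        assert np.allclose(
            b.landmarks["ischial_spine_left"],
            a.landmarks["ischial_spine_right"] * MIRROR,
        )
        assert np.allclose(
            b.ligaments["sacrospinous_left"].points,
            a.ligaments["sacrospinous_right"].points * MIRROR,
        )


class TestParameters:
    def test_pcl_length_pass_through(self):
        for L in (90.0, 100.0):
            g = build_pelvic_geometry(GeometryParams(pcl_length=L))
            d = np.linalg.norm(
                g.landmarks["pubic_symphysis_inferior"]
                - g.landmarks["coccyx_last_joint"]
            )
            assert d == pytest.approx(L, abs=1e-9)

    def test_inter_spine_width_pass_through(self, generic):
        d = np.linalg.norm(
            generic.landmarks["ischial_spine_left"]
            - generic.landmarks["ischial_spine_right"]
        )
        assert d == pytest.approx(100.0, abs=1e-9)

    def test_determinism_byte_identical(self):
        p = patient_like_params(seed=7)
        a = geometry_to_json(build_pelvic_geometry(p))
        b = geometry_to_json(build_pelvic_geometry(p))
        assert a == b

    def test_zero_asymmetry_reproduces_symmetric_variant(self):
        a = build_pelvic_geometry(GeometryParams(seed=5, asymmetry_amplitude=0.0))
        assert a.symmetric

    def test_invalid_scale_rejected(self):
        with pytest.raises(ParameterError):
            GeometryParams(organ_scales=(("bladder", -1.0),))

    def test_excessive_asymmetry_breaks_ligament_invariant(self):
        with pytest.raises(GeometryError):
            build_pelvic_geometry(patient_like_params(asymmetry_amplitude=200.0))


class TestSacrospinousLigaments:
    def test_polyline_runs_spine_to_insertion_with_placeable_arc(self, generic):
        for side in ("left", "right"):
            poly = generic.ligaments[f"sacrospinous_{side}"]
            assert np.allclose(
                poly.points[0], generic.landmarks[f"ischial_spine_{side}"]
            )
            assert np.allclose(
                poly.points[-1],
                generic.landmarks[f"sacrospinous_insertion_{side}"],
            )
            assert poly.arc_length() > 30.0

    def test_arc_length_matches_parameter(self, generic):
        assert generic.ligaments["sacrospinous_left"].arc_length() == pytest.approx(
            45.0, abs=1e-9
        )


class TestReferencePoints:
    def test_points_live_on_the_right_surfaces(self, generic):
        assert generic.reference_points["C"][0] == "vagina"
        assert generic.reference_points["Ba"][0] == "bladder"
        assert generic.reference_points["Bp"][0] == "rectum"

    def test_points_near_midsagittal_plane(self, generic):
        for name in ("Ba", "C", "Bp"):
            assert abs(generic.reference_position(name)[0]) < 3.0, name

    def test_c_point_is_the_vaginal_apex(self, generic):
        surf, vid = generic.reference_points["C"]
        assert vid == generic.organ_surfaces["vagina"].meta["apex"]


class TestSupportCondition:
    def test_physiological_keeps_everything_active(self, generic):
        g = apply_support_condition(generic, "physiological")
        assert all(g.ligament_active.values())

    def test_pathological_disables_exactly_broad_and_round(self, generic):
        g = apply_support_condition(generic, "pathological")
        inactive = {k for k, v in g.ligament_active.items() if not v}
        assert inactive == set(PATHOLOGICAL_DISABLED)

    def test_idempotent(self, generic):
        g1 = apply_support_condition(generic, "pathological")
        g2 = apply_support_condition(g1, "pathological")
        assert g1.ligament_active == g2.ligament_active

    def test_unknown_condition_rejected(self, generic):
        with pytest.raises(ParameterError):
            apply_support_condition(generic, "florid")


class TestShells:
    def test_consistent_outward_orientation_of_closed_shells(self, generic):
        """Closed shells (bladder, uterus) have positive enclosed volume
        under the divergence theorem with outward-facing triangles."""
        for name in ("bladder", "uterus"):
            s = generic.organ_surfaces[name]
            p = s.vertices[s.faces]
            vol = np.einsum(
                "ij,ij->i", p[:, 0], np.cross(p[:, 1], p[:, 2])
            ).sum() / 6.0
            assert vol > 0, name
            assert len(s.boundary_vertices()) == 0, name

    def test_open_shells_have_boundaries(self, generic):
        for name in ("pelvic_floor", "fascia_pubocervical", "vagina"):
            assert len(generic.organ_surfaces[name].boundary_vertices()) > 0

    def test_uterus_only_in_generic_variant(self, generic, patient):
        assert "uterus" in generic.organ_surfaces
        assert "uterus" not in patient.organ_surfaces


def test_json_roundtrip(patient):
    doc = geometry_to_json(patient)
    back = geometry_from_json(doc)
    assert geometry_to_json(back) == doc
    assert np.allclose(
        back.organ_surfaces["vagina"].vertices,
        patient.organ_surfaces["vagina"].vertices,
    )
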