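"""Pubococcygeal-line metric: line construction, distances, descent rows."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pelvifem.errors import GeometryError, ReportError
from pelvifem.model import SimulationResult
from pelvifem.pcl import (
    DescentReport,
    descent,
    pcl_line,
    perpendicular_distance,
)

from conftest import make_mesh


def line_from(pubis, coccyx):
    return pcl_line(
        {
            "pubic_symphysis_inferior": np.asarray(pubis, float),
            "coccyx_last_joint": np.asarray(coccyx, float),
        }
    )


class TestPCLLine:
    def test_line_through_the_two_landmarks(self):
        line = line_from([0, 60, 0], [0, -40, -10])
        assert perpendicular_distance([0, 60, 0], line) == pytest.approx(0.0)
        assert perpendicular_distance([0, -40, -10], line) == pytest.approx(0.0)

    def test_off_plane_landmarks_projected_first(self):
        a = line_from([5, 60, 0], [-3, -40, -10])
        b = line_from([0, 60, 0], [0, -40, -10])
        assert np.allclose(a.origin, b.origin)
        assert np.allclose(a.direction, b.direction)

    def test_swapped_landmarks_reverse_direction_same_line(self):
        a = line_from([0, 0, 0], [0, 100, 0])
        b = line_from([0, 100, 0], [0, 0, 0])
        assert np.allclose(a.direction, -b.direction)
        assert np.allclose(a.normal, b.normal)  # caudal side is unchanged
        p = [0, 30, -12]
        assert perpendicular_distance(p, a) == pytest.approx(
            perpendicular_distance(p, b)
        )

    def test_coincident_landmarks_rejected(self):
        with pytest.raises(GeometryError):
            line_from([1, 2, 3], [1, 2, 3])


class TestPerpendicularDistance:
    def test_planar_right_triangle(self):
        line = line_from([0, 0, 0], [0, 100, 0])
        assert perpendicular_distance([0, 50, -30], line) == pytest.approx(30.0)

    def test_lateral_offset_is_discarded(self):
        line = line_from([0, 0, 0], [0, 100, 0])
        assert perpendicular_distance([12, 50, -30], line) == pytest.approx(30.0)

    def test_caudal_side_is_positive(self):
        line = line_from([0, 60, 0], [0, -40, -10])
        below = perpendicular_distance([0, 10, -40], line)
        above = perpendicular_distance([0, 10, 40], line)
        assert below > 0 > above

    @settings(derandomize=True, max_examples=40)
    @given(st.tuples(*[st.floats(-50, 50) for _ in range(3)]))
    def test_rigid_translation_invariance(self, shift):
        """Translating landmarks and point together changes nothing."""
        s = np.asarray(shift)
        line0 = line_from([0, 60, 0], [0, -40, -10])
        line1 = line_from(np.array([0, 60, 0.0]) + s, np.array([0, -40, -10.0]) + s)
        p = np.array([3.0, 12.0, -25.0])
        assert perpendicular_distance(p + s, line1) == pytest.approx(
            perpendicular_distance(p, line0), abs=1e-9
        )


class _GeomStub:
    """Minimal geometry carrying only landmarks (what descent() reads)."""

    def __init__(self):
        self.landmarks = {
            "pubic_symphysis_inferior": np.array([0.0, 60.0, 0.0]),
            "coccyx_last_joint": np.array([0.0, -40.0, -10.0]),
        }


# make the stub quack like PelvicGeometry for pcl_line's isinstance check
from pelvifem.geometry import PelvicGeometry  # noqa: E402


def make_point_mesh():
    nodes = [[0, 10, -20], [0, -5, -25], [0, 0, -30], [0, 60, 0], [0, -40, -10]]
    return make_mesh(
        nodes,
        node_sets={
            "point_Ba": [0],
            "point_C": [1],
            "point_Bp": [2],
            "pcl_pubis": [3],
            "pcl_coccyx": [4],
        },
    )


def result(u, n=5):
    disp = np.zeros((n, 3))
    disp[:] = u
    return SimulationResult(
        displacement=disp, converged=True, residual_history=[], reactions={}
    )


class TestDescent:
    def test_identical_states_give_zero_descent(self):
        mesh = make_point_mesh()
        r = result([0.0, 0.0, 0.0])
        row = descent(r, r, _GeomStub(), mesh)
        for p in ("Ba", "C", "Bp"):
            assert row[f"{p}_mm"] == pytest.approx(0.0)

    def test_pure_lateral_motion_gives_zero_descent_and_flags_ba(self):
        mesh = make_point_mesh()
        rest = result([0.0, 0.0, 0.0])
        strain = result([4.0, 0.0, 0.0])
        row = descent(rest, strain, _GeomStub(), mesh)
        assert row["Ba_mm"] == pytest.approx(0.0, abs=1e-12)
        assert row["Ba_not_evaluable"] is True
        assert row["Ba_total_mm"] == pytest.approx(4.0)

    def test_rigid_inferior_translation_descends_everywhere(self):
        """5 mm caudal rigid motion with fixed PCL landmarks -> 5 mm descent
        at every reference point (hand-computed projected distances)."""
        mesh = make_point_mesh()
        rest = result([0.0, 0.0, 0.0])
        strain = result([0.0, 0.0, 0.0])
        line = pcl_line(_GeomStub().landmarks)
        shift = 5.0 * line.normal  # exactly caudal
        strain.displacement[:3] = shift
        row = descent(rest, strain, _GeomStub(), mesh)
        for p in ("Ba", "C", "Bp"):
            assert row[f"{p}_mm"] == pytest.approx(5.0, abs=1e-9)
        assert row["Ba_not_evaluable"] is False

    def test_unconverged_states_rejected(self):
        mesh = make_point_mesh()
        ok = result([0, 0, 0])
        bad = result([0, 0, 0])
        bad.converged = False
        with pytest.raises(ReportError):
            descent(ok, bad, _GeomStub(), mesh)

    def test_missing_reference_set_rejected(self):
        mesh = make_point_mesh()
        del mesh.node_sets["point_C"]
        r = result([0, 0, 0])
        with pytest.raises(ReportError):
            descent(r, r, _GeomStub(), mesh)


class TestDescentReport:
    def test_rows_keyed_without_duplicates(self):
        rep = DescentReport()
        row = {"Ba_mm": 1.0, "C_mm": 2.0, "Bp_mm": 3.0}
        rep.add(["left"], 20.0, "pathological", row)
        rep.add(["left", "right"], 20.0, "pathological", row)
        with pytest.raises(ReportError):
            rep.add(["left"], 20.0, "pathological", row)
        df = rep.to_frame()
        assert len(df) == 2
        assert set(df["sides"]) == {"left", "left+right"}

    def test_csv_roundtrip_is_stable(self, tmp_path):
        rep = DescentReport()
        rep.add([], 20.0, "pathological", {"Ba_mm": 0.1, "C_mm": 0.2, "Bp_mm": 0.3})
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        rep.to_csv(p1)
        rep.to_csv(p2)
        assert p1.read_bytes() == p2.read_bytes()
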