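"""Load calibration: scalar root-find, linear oracle, failure contracts."""
import numpy as np
import pytest

from pelvifem.calibration import CalibrationSpec, calibrate_loads, scalar_secant
from pelvifem.errors import CalibrationError, ParameterError
from pelvifem.materials import MaterialModel
from pelvifem.model import FEModel, FixedSet, LoadCase, Traction

from conftest import make_mesh


def strip_model(E=0.5):
    """Membrane strip clamped at one edge, pulled by a named traction on the
    free edge; at small load the tip response is essentially linear."""
    nodes = [[0, 0, 0], [10, 0, 0], [20, 0, 0],
             [0, 10, 0], [10, 10, 0], [20, 10, 0]]
    tris = [(0, 1, 4), (0, 4, 3), (1, 2, 5), (1, 5, 4)]
    mesh = make_mesh(
        nodes, tris, tri_thickness=1.0,
        node_sets={
            "clamp": [0, 3],
            "tip": [2, 5],
            "all": list(range(6)),
            "point_tip": [2],
        },
    )
    lc = LoadCase(
        tractions=[Traction("pull", "tip", (0.0, 0.0, -1.0), 1e-4)],
        fixed=[FixedSet("clamp")],
        n_load_steps=2,
        newton_tolerance=1e-9,
    )
    # slight sag so the transverse response is first-order
    mesh.nodes[:, 2] = -0.02 * mesh.nodes[:, 0]
    return FEModel(
        mesh=mesh,
        materials={"membrane": MaterialModel.linear_elastic(E, 0.3)},
        load_case=lc,
    )


def tip_deflection(result, point):
    return float(-result.displacement[2, 2])


class TestScalarSecant:
    def test_converges_on_a_linear_map(self):
        x, y, _ = scalar_secant(lambda m: 3.0 * m, 6.0, 1.0, 1e-8, 30)
        assert x == pytest.approx(2.0, rel=1e-6)

    def test_single_iteration_when_already_at_target(self):
        calls = []

        def f(m):
            calls.append(m)
            return 5.0

        x, y, _ = scalar_secant(f, 5.0, 0.7, 0.1, 30)
        assert x == 0.7 and len(calls) == 1

    def test_nonlinear_monotone_map(self):
        x, _, _ = scalar_secant(lambda m: m**3, 8.0, 0.5, 1e-10, 50)
        assert x == pytest.approx(2.0, rel=1e-6)

    def test_non_monotone_response_raises_with_trace(self):
        trace = []
        with pytest.raises(CalibrationError) as err:
            scalar_secant(
                lambda m: np.sin(4.0 * m), 1.5, 0.3, 1e-10, 50, trace=trace
            )
        assert err.value.trace  # diagnostics preserved

    def test_unreachable_target_fails_structured(self):
        with pytest.raises(CalibrationError):
            scalar_secant(lambda m: m / (1.0 + m), 2.0, 0.1, 1e-8, 20)


class TestCalibrateLoads:
    def test_linear_oracle_recovers_known_magnitude(self):
        """Solve at a known magnitude, feed the measured displacement back
        as the setpoint from a perturbed initial guess: the calibrated
        magnitude must recover the truth (linear spring law P = k u)."""
        from pelvifem.solver import solve_quasi_static

        model = strip_model()
        truth = 2e-4
        probe = model.copy()
        probe.load_case = probe.load_case.with_magnitudes({"pull": truth})
        target = tip_deflection(solve_quasi_static(probe), "tip")
        spec = CalibrationSpec(
            setpoints=(("tip", target),),
            drivers=(("tip", "pull"),),
            tolerance=target * 5e-4,
            initial_magnitudes=(("pull", 0.6 * truth),),
        )
        cal = calibrate_loads(model, spec, measure=tip_deflection)
        assert cal.converged
        assert cal.magnitudes["pull"] == pytest.approx(truth, rel=0.01)

    def test_already_converged_initial_magnitude_returns_immediately(self):
        from pelvifem.solver import solve_quasi_static

        model = strip_model()
        res = solve_quasi_static(model)
        target = tip_deflection(res, "tip")
        spec = CalibrationSpec(
            setpoints=(("tip", target),),
            drivers=(("tip", "pull"),),
            tolerance=0.5,
        )
        cal = calibrate_loads(model, spec, measure=tip_deflection)
        assert cal.converged
        assert cal.magnitudes["pull"] == pytest.approx(1e-4)

    def test_infeasible_setpoint_fails_not_crashes(self):
        model = strip_model()
        spec = CalibrationSpec(
            setpoints=(("tip", 1e5),),
            drivers=(("tip", "pull"),),
            tolerance=0.01,
            max_iterations=8,
        )
        with pytest.raises(CalibrationError) as err:
            calibrate_loads(model, spec, measure=tip_deflection)
        assert err.value.trace

    def test_spec_validation(self):
        with pytest.raises(ParameterError):
            CalibrationSpec(setpoints=(("C", -1.0),))
        with pytest.raises(ParameterError):
            CalibrationSpec(setpoints=(("X", 1.0),), drivers=())
        with pytest.raises(ParameterError):
            CalibrationSpec(
                setpoints=(("C", 1.0), ("Bp", 1.0)),
                drivers=(("C", "pull"), ("Bp", "pull")),
            )
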