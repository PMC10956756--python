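"""Empirical load calibration.

The straining tractions are unknown: the study prescribes reference-point
displacements (pre-operative PCL descents read off imaging) and the load
magnitudes are increased until the simulation reproduces them.  Each driven
setpoint is paired with one traction; the scalar map magnitude -> achieved
descent is solved by a damped secant iteration with bracketing/bisection
fallback, and the (weak) coupling between the loads is handled by outer
fixed-point sweeps over the drivers.  The monotonicity of every scalar
response is checked from the sampled points, not assumed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import CalibrationError, ParameterError
from .model import FEModel, SimulationResult
from .pcl import pcl_line, perpendicular_distance
from .solver import solve_quasi_static

__all__ = ["CalibrationSpec", "CalibrationResult", "calibrate_loads", "scalar_secant"]

_MAX_SWEEPS = 5


@dataclass(frozen=True)
class CalibrationSpec:
    """Setpoints (mm) per reference point, each driven by one named traction.

    Default mapping: the vaginal traction drives the apical point C and the
    rectal traction drives the posterior point Bp; the bladder traction is
    not driven (the anterior compartment is reported passively)."""

    setpoints: tuple[tuple[str, float], ...] = (("C", 7.0), ("Bp", 6.0))
    drivers: tuple[tuple[str, str], ...] = (
        ("C", "vagina_traction"),
        ("Bp", "rectum_traction"),
    )
    tolerance: float = 0.1   # mm
    max_iterations: int = 30
    initial_magnitudes: tuple[tuple[str, float], ...] = ()

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ParameterError("tolerance must be > 0")
        drv = dict(self.drivers)
        for point, target in self.setpoints:
            if target <= 0:
                raise ParameterError(f"setpoint for {point} must be positive")
            if point not in drv:
                raise ParameterError(f"setpoint {point!r} has no driving load")
        loads = [drv[p] for p, _ in self.setpoints]
        if len(set(loads)) != len(loads):
            raise ParameterError("each driven setpoint needs its own load")


@dataclass
class CalibrationResult:
    magnitudes: dict[str, float]          # MPa per traction name
    result: SimulationResult              # solve at the calibrated magnitudes
    trace: list[dict] = field(default_factory=list)
    converged: bool = False
    achieved: dict[str, float] = field(default_factory=dict)


def scalar_secant(fn, target, x0, tol, max_iter, trace=None, label=""):
    """Damped secant root-find for monotone fn(x) = target, x > 0.

    Secant steps are clamped to a factor of [1/4, 4] per update; once a
    bracket exists, steps falling outside it bisect instead.  Samples are
    collected and checked for strict monotone increase; a violation raises
    ``CalibrationError`` with the trace."""
    samples = []

    def record(x, y, note=""):
        samples.append((x, y))
        if trace is not None:
            trace.append({"load": label, "magnitude": x, "achieved": y,
                          "target": target, "note": note})

    # decreases smaller than a fraction of the matching tolerance are
    # solver noise (the equilibrium is only resolved to the Newton
    # tolerance), not a genuine non-monotone response
    noise_floor = max(1e-9, 0.2 * tol)

    def check_monotone():
        pts = sorted(samples)
        xs = [p[0] for p in pts]
        ys = [p[1] for p in pts]
        for i in range(len(pts) - 1):
            if xs[i + 1] - xs[i] > 1e-15 and ys[i + 1] <= ys[i] - noise_floor:
                raise CalibrationError(
                    f"response of {label or 'load'} is not monotone increasing "
                    f"over the searched bracket ({xs[i]:.4g}->{xs[i+1]:.4g} MPa "
                    f"gave {ys[i]:.4g}->{ys[i+1]:.4g} mm)",
                    trace=trace if trace is not None else samples,
                )

    x, y = x0, fn(x0)
    record(x, y, "initial")
    lo = hi = None  # bracket magnitudes with f below/above target
    for _ in range(max_iter):
        if abs(y - target) <= tol:
            check_monotone()
            return x, y, samples
        if y < target:
            lo = x if lo is None else max(lo, x)
        else:
            hi = x if hi is None else min(hi, x)
        if len(samples) >= 2:
            (xa, ya), (xb, yb) = samples[-2], samples[-1]
            if abs(yb - ya) > 1e-14:
                x_new = xb + (target - yb) * (xb - xa) / (yb - ya)
            else:
                x_new = 2.0 * xb if yb < target else 0.5 * xb
        else:
            x_new = x * float(np.clip(target / max(y, 1e-9), 0.25, 4.0)) \
                if y > 0 else 2.0 * x
        x_new = float(np.clip(x_new, 0.25 * x, 4.0 * x))
        if lo is not None and hi is not None and not (lo < x_new < hi):
            x_new = 0.5 * (lo + hi)
        if x_new <= 0:
            x_new = 0.5 * x
        x, y = x_new, fn(x_new)
        record(x, y)
    check_monotone()
    raise CalibrationError(
        f"no convergence for {label or 'load'} after {max_iter} iterations "
        f"(last achieved {y:.4g} mm vs target {target} mm)",
        trace=trace if trace is not None else samples,
    )


def calibrate_loads(
    model: FEModel,
    spec: CalibrationSpec,
    measure=None,
) -> CalibrationResult:
    """Scale the driven tractions until the measured displacements match the
    setpoints within tolerance.

    ``measure(result, point_name) -> mm`` defaults to the PCL descent of
    the reference node against the mesh's bone-node PCL.  Deterministic for
    a given model and spec.  Raises ``CalibrationError`` (with the full
    iteration trace) on non-convergence or a non-monotone response."""
    mesh = model.mesh
    if measure is None:
        lm = {
            "pubic_symphysis_inferior": mesh.nodes[int(mesh.node_sets["pcl_pubis"][0])],
            "coccyx_last_joint": mesh.nodes[int(mesh.node_sets["pcl_coccyx"][0])],
        }
        line = pcl_line(lm)

        def measure(result, point):
            nid = int(mesh.node_sets[f"point_{point}"][0])
            x0 = mesh.nodes[nid]
            return perpendicular_distance(
                x0 + result.displacement[nid], line
            ) - perpendicular_distance(x0, line)

    mags = {t.name: t.magnitude for t in model.load_case.tractions}
    mags.update(dict(spec.initial_magnitudes))
    drivers = dict(spec.drivers)
    trace: list[dict] = []
    # every evaluation warm-starts from the solved state with the nearest
    # magnitudes (branch continuation): re-equilibrating from a distant
    # state can hop between nearby wrinkling equilibria and make the
    # magnitude -> displacement map look non-monotone
    state = {"result": None}
    cache: dict[tuple, SimulationResult] = {}

    def _key(magnitudes):
        return tuple(sorted((k, float(v)) for k, v in magnitudes.items()))

    def solve_at(magnitudes) -> SimulationResult:
        key = _key(magnitudes)
        if key in cache:
            state["result"] = cache[key]
            return cache[key]
        m = model.copy()
        m.load_case = m.load_case.with_magnitudes(magnitudes)
        warm = None
        if cache:
            target = np.array([v for _, v in key])

            def dist(other):
                o = np.array([v for _, v in other])
                return float(np.sum(np.abs(np.log(
                    np.maximum(o, 1e-300) / np.maximum(target, 1e-300)
                ))))

            nearest = min(cache, key=dist)
            warm = cache[nearest].displacement
        if warm is not None:
            m.load_case = replace(m.load_case, n_load_steps=1)
            res = solve_quasi_static(m, initial_displacement=warm)
            if not res.converged:
                m.load_case = replace(m.load_case,
                                      n_load_steps=model.load_case.n_load_steps)
                res = solve_quasi_static(m)
        else:
            res = solve_quasi_static(m)
        if not res.converged:
            raise CalibrationError(
                f"solver failed at magnitudes {magnitudes}: {res.message}",
                trace=trace,
            )
        state["result"] = res
        cache[key] = res
        return res

    converged = False
    achieved: dict[str, float] = {}
    for sweep in range(_MAX_SWEEPS):
        all_ok = True
        for point, target in spec.setpoints:
            load = drivers[point]

            def fn(mag, _load=load, _point=point):
                res = solve_at({**mags, _load: mag})
                return measure(res, _point)

            current = measure(solve_at(mags), point)
            if abs(current - target) <= spec.tolerance:
                achieved[point] = current
                trace.append({"load": load, "magnitude": mags[load],
                              "achieved": current, "target": target,
                              "note": f"sweep {sweep}: within tolerance"})
                continue
            all_ok = False
            x, y, _ = scalar_secant(
                fn, target, mags[load], spec.tolerance,
                spec.max_iterations, trace=trace, label=load,
            )
            mags[load] = x
            achieved[point] = y
        if all_ok:
            converged = True
            break
        # verify jointly after the sweep
        res = solve_at(mags)
        if all(
            abs(measure(res, p) - t) <= spec.tolerance
            for p, t in spec.setpoints
        ):
            converged = True
            break
    final = solve_at(mags)
    achieved = {p: measure(final, p) for p, _ in spec.setpoints}
    if not converged or not all(
        abs(achieved[p] - t) <= spec.tolerance for p, t in spec.setpoints
    ):
        raise CalibrationError(
            f"calibration did not reach the setpoints: achieved {achieved}",
            trace=trace,
        )
    return CalibrationResult(
        magnitudes=mags, result=final, trace=trace, converged=True,
        achieved=achieved,
    )
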