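"""Study orchestration: geometry -> mesh -> calibration -> surgery matrix.

``run_study`` builds the configured pre-operative model, calibrates the
straining loads once on the no-surgery model, freezes them, runs every
surgical configuration of the matrix under the identical load, and writes
the descent report (CSV + JSON), per-configuration VTK snapshots and a
machine-readable manifest.  Reruns with the same config and seed reproduce
the report bit-identically.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .calibration import CalibrationSpec, calibrate_loads
from .errors import ConfigError, PelvifemError
from .geometry import GeometryParams, build_pelvic_geometry
from .io import export_surfaces_stl, write_vtk
from .materials import MaterialModel, default_materials
from .meshing import default_load_case, mesh_geometry
from .model import FEModel
from .pcl import DescentReport, descent
from .solver import solve_quasi_static
from .surgery import SSFConfig, apply_ssf

log = logging.getLogger("pelvifem")

__all__ = ["StudyConfig", "validate_config", "run_study", "default_surgery_matrix"]


class GeometryBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    inter_spine_width: float = Field(100.0, gt=0)
    pcl_length: float = Field(100.0, gt=0)
    sacrospinous_length: float = Field(45.0, gt=30.0)
    support_condition: Literal["physiological", "pathological"] = "pathological"
    asymmetry_amplitude: float = Field(5.0, ge=0)
    target_edge_length: float = Field(6.0, gt=0)
    include_uterus: Optional[bool] = None
    mirror: bool = False
    organ_scales: dict[str, float] = Field(default_factory=dict)


class MaterialBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: Literal["yeoh", "linear_elastic"]
    C0: float = Field(0.0, ge=0)
    C1: float = Field(0.0, ge=0)
    E: float = Field(0.0, ge=0)
    nu: float = Field(0.0, ge=0, lt=0.5)


class LoadsBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    vagina_traction: float = Field(8e-5, ge=0)
    bladder_traction: float = Field(5e-5, ge=0)
    rectum_traction: float = Field(7e-4, ge=0)
    n_load_steps: int = Field(2, ge=1)
    newton_tolerance: float = Field(1e-7, gt=0)
    stabilization: float = Field(1e-6, ge=0)


class CalibrationBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    setpoints: dict[str, float] = Field(
        default_factory=lambda: {"C": 7.0, "Bp": 6.0}
    )
    drivers: dict[str, str] = Field(
        default_factory=lambda: {"C": "vagina_traction", "Bp": "rectum_traction"}
    )
    tolerance: float = Field(0.1, gt=0)
    max_iterations: int = Field(30, ge=1)


class SurgeryBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    sides: list[Literal["left", "right"]] = Field(default_factory=list)
    anchor_distance_mm: float = Field(20.0, ge=0)
    sutures_per_side: int = Field(2, ge=1)
    suture_area_mm2: float = Field(0.2, gt=0)
    apex_spread_mm: float = Field(5.0, gt=0)
    pretension: float = Field(0.0, ge=0, lt=1)


class StudyConfig(BaseModel):
    """Validated study configuration with the full default matrix."""

    model_config = ConfigDict(extra="forbid")
    geometry: GeometryBlock = Field(default_factory=GeometryBlock)
    materials: dict[str, MaterialBlock] = Field(default_factory=dict)
    loads: LoadsBlock = Field(default_factory=LoadsBlock)
    calibration: CalibrationBlock = Field(default_factory=CalibrationBlock)
    surgery_matrix: Optional[list[SurgeryBlock]] = None
    seed: int = 0
    log_level: str = "INFO"
    write_vtk: bool = True
    write_stl: bool = False

    def resolved_matrix(self) -> list[SurgeryBlock]:
        if self.surgery_matrix is not None:
            return self.surgery_matrix
        return default_surgery_matrix()


def default_surgery_matrix() -> list[SurgeryBlock]:
    """The study grid: no surgery, left, right and bilateral fixation at
    2 cm, plus the 1/2/3 cm anchor sweep for the bilateral and the
    left-sided variants (the two ways the anchor distance was varied)."""
    rows = [
        SurgeryBlock(sides=[]),
        SurgeryBlock(sides=["left"]),
        SurgeryBlock(sides=["right"]),
        SurgeryBlock(sides=["left", "right"]),
    ]
    for dist in (10.0, 30.0):
        rows.append(SurgeryBlock(sides=["left", "right"], anchor_distance_mm=dist))
        rows.append(SurgeryBlock(sides=["left"], anchor_distance_mm=dist))
    return rows


def validate_config(raw) -> StudyConfig:
    """Validate a raw mapping / YAML / JSON text into a StudyConfig.

    All defaults are injected; every offending field is reported with its
    path in a single ``ConfigError``; unknown keys are rejected."""
    if raw is None:
        raw = {}
    if isinstance(raw, (str, bytes)):
        raw = yaml.safe_load(raw) or {}
    if isinstance(raw, StudyConfig):
        return raw
    try:
        return StudyConfig.model_validate(raw)
    except ValidationError as e:
        problems = [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in e.errors()
        ]
        raise ConfigError(problems) from None


def _geometry_params(cfg: StudyConfig) -> GeometryParams:
    g = cfg.geometry
    return GeometryParams(
        inter_spine_width=g.inter_spine_width,
        pcl_length=g.pcl_length,
        sacrospinous_length=g.sacrospinous_length,
        organ_scales=tuple(sorted(g.organ_scales.items())),
        support_condition=g.support_condition,
        asymmetry_amplitude=g.asymmetry_amplitude,
        seed=cfg.seed,
        target_edge_length=g.target_edge_length,
        include_uterus=g.include_uterus,
        mirror=g.mirror,
    )


def _materials(cfg: StudyConfig) -> dict[str, MaterialModel]:
    overrides = {}
    for name, m in cfg.materials.items():
        if m.kind == "yeoh":
            overrides[name] = MaterialModel.yeoh(m.C0, m.C1)
        else:
            overrides[name] = MaterialModel.linear_elastic(m.E, m.nu)
    return default_materials(overrides)


def build_study_model(cfg: StudyConfig):
    """Geometry + mesh + load case for the configured pre-operative state."""
    params = _geometry_params(cfg)
    geometry = build_pelvic_geometry(params)
    mesh = mesh_geometry(geometry)
    lc = default_load_case(
        mesh,
        vagina_traction=cfg.loads.vagina_traction,
        bladder_traction=cfg.loads.bladder_traction,
        rectum_traction=cfg.loads.rectum_traction,
        n_load_steps=cfg.loads.n_load_steps,
        newton_tolerance=cfg.loads.newton_tolerance,
        stabilization=cfg.loads.stabilization,
    )
    model = FEModel(mesh=mesh, materials=_materials(cfg), load_case=lc)
    return geometry, model


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_study(config, out_dir, seed: int | None = None) -> DescentReport:
    """Execute the full study and write artifacts under ``out_dir``.

    Calibration runs once on the no-surgery model; the calibrated loads are
    then reused unchanged for every surgical configuration so that descent
    differences are attributable to the repair alone.  On any stage failure
    the partial results are preserved, the manifest records the cause, and
    ``PelvifemError`` is re-raised."""
    cfg = validate_config(config)
    if seed is not None:
        cfg = cfg.model_copy(update={"seed": int(seed)})
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": cfg.seed,
        "config": json.loads(cfg.model_dump_json()),
        "config_sha256": hashlib.sha256(
            cfg.model_dump_json().encode()
        ).hexdigest(),
        "version": __version__,
        "artifacts": {},
        "status": "running",
    }
    report = DescentReport()
    try:
        log.info("building geometry and mesh (seed=%d)", cfg.seed)
        geometry, model = build_study_model(cfg)
        log.info("mesh: %d nodes, %d elements", model.mesh.n_nodes,
                 model.mesh.n_elements)
        if cfg.write_stl:
            for p in export_surfaces_stl(geometry, out / "stl"):
                manifest["artifacts"][str(p.relative_to(out))] = _sha256(p)
        rest = solve_quasi_static(
            replace(model.copy(), load_case=model.load_case.with_magnitudes(
                {t.name: 0.0 for t in model.load_case.tractions}))
        )
        calibration_info = {"enabled": cfg.calibration.enabled}
        if cfg.calibration.enabled:
            spec = CalibrationSpec(
                setpoints=tuple(sorted(cfg.calibration.setpoints.items())),
                drivers=tuple(sorted(cfg.calibration.drivers.items())),
                tolerance=cfg.calibration.tolerance,
                max_iterations=cfg.calibration.max_iterations,
            )
            log.info("calibrating straining loads on the no-surgery model")
            cal = calibrate_loads(model, spec)
            model.load_case = model.load_case.with_magnitudes(cal.magnitudes)
            calibration_info.update(
                magnitudes=cal.magnitudes, achieved=cal.achieved,
                iterations=len(cal.trace),
            )
            log.info("calibrated magnitudes: %s", cal.magnitudes)
            base_result = cal.result
        else:
            base_result = solve_quasi_static(model)
            if not base_result.converged:
                raise PelvifemError(f"baseline solve failed: {base_result.message}")
        manifest["calibration"] = calibration_info
        condition = cfg.geometry.support_condition
        warm = base_result.displacement
        for block in cfg.resolved_matrix():
            ssf = SSFConfig(
                sides=frozenset(block.sides),
                anchor_distance_mm=block.anchor_distance_mm,
                sutures_per_side=block.sutures_per_side,
                suture_area_mm2=block.suture_area_mm2,
                apex_spread_mm=block.apex_spread_mm,
                pretension=block.pretension,
            )
            if ssf.sides:
                m = apply_ssf(model, geometry, ssf)
                res = solve_quasi_static(m, initial_displacement=warm)
                if not res.converged:
                    res = solve_quasi_static(m)
            else:
                m, res = model, base_result
            if not res.converged:
                raise PelvifemError(
                    f"solve failed for configuration {ssf.label}"
                    f"@{ssf.anchor_distance_mm}: {res.message}"
                )
            row = descent(rest, res, geometry, m.mesh)
            report.add(
                sorted(ssf.sides), ssf.anchor_distance_mm, condition, row,
                newton_iterations=res.n_newton_iterations,
            )
            log.info(
                "config %s@%g mm: C %.2f mm, Ba %.2f mm, Bp %.2f mm",
                ssf.label, ssf.anchor_distance_mm, row["C_mm"], row["Ba_mm"],
                row["Bp_mm"],
            )
            if cfg.write_vtk:
                tag = f"{ssf.label}_{ssf.anchor_distance_mm:g}mm"
                p = write_vtk(out / f"result_{tag}.vtk", m.mesh,
                              {"displacement": res.displacement})
                manifest["artifacts"][p.name] = _sha256(p)
        csv_path = out / "descent_report.csv"
        report.to_csv(csv_path)
        json_path = out / "descent_report.json"
        json_path.write_text(
            report.to_frame().to_json(orient="records", double_precision=6)
        )
        for p in (csv_path, json_path):
            manifest["artifacts"][p.name] = _sha256(p)
        manifest["status"] = "ok"
    except Exception as e:
        manifest["status"] = "failed"
        manifest["failure"] = f"{type(e).__name__}: {e}"
        raise
    finally:
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str)
        )
    return report
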