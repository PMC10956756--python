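"""Finite-element model containers: mesh, loads, boundary conditions, results.

Coordinates are in mm, x lateral (patient-right positive), y anterior,
z superior; the midsagittal plane is x = 0.  Tractions are in MPa, nodal
forces and residuals in N.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import MeshError, ModelError, ParameterError
from .materials import MaterialModel

__all__ = [
    "FEMesh",
    "Traction",
    "FixedSet",
    "LoadCase",
    "FEModel",
    "SimulationResult",
]

_MIN_TRI_AREA = 1e-6  # mm^2


@dataclass
class FEMesh:
    """Membrane-triangle + truss-segment mesh with named node/element sets.

    ``tri_structure`` / ``truss_structure`` carry one structure label per
    element; thicknesses (mm) per triangle and cross-section areas (mm^2)
    per truss.  ``truss_ref_length`` stores the stress-free length of each
    filament (by default the as-meshed length).  ``ligament_chains`` maps a
    ligament name to ``(node_ids, arc_lengths)`` along the discretised
    polyline, used by the surgery module to locate anchor nodes.
    """

    nodes: np.ndarray                      # (n, 3) float
    tri_nodes: np.ndarray                  # (m, 3) int
    tri_structure: np.ndarray              # (m,) object/str
    tri_thickness: np.ndarray              # (m,) float
    truss_nodes: np.ndarray                # (k, 2) int
    truss_structure: np.ndarray            # (k,) object/str
    truss_area: np.ndarray                 # (k,) float
    truss_tension_only: np.ndarray         # (k,) bool
    truss_ref_length: np.ndarray           # (k,) float
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    element_sets: dict[str, tuple[str, np.ndarray]] = field(default_factory=dict)
    ligament_chains: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    #: isotropic resting-tone membrane pretension (N/mm) per triangle: a small
    #: surface tension representing tissue tone, which also provides the
    #: membranes' physical transverse stiffness.  None -> zero.
    tri_pretension: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return int(self.nodes.shape[0])

    @property
    def n_elements(self) -> int:
        return int(self.tri_nodes.shape[0] + self.truss_nodes.shape[0])

    def tri_areas(self) -> np.ndarray:
        if self.tri_nodes.shape[0] == 0:
            return np.zeros(0)
        p = self.nodes[self.tri_nodes]
        return 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
        )

    def truss_lengths(self) -> np.ndarray:
        if self.truss_nodes.shape[0] == 0:
            return np.zeros(0)
        d = self.nodes[self.truss_nodes[:, 1]] - self.nodes[self.truss_nodes[:, 0]]
        return np.linalg.norm(d, axis=1)

    def validate(self) -> None:
        n = self.n_nodes
        for arr, what in ((self.tri_nodes, "triangle"), (self.truss_nodes, "truss")):
            if arr.size and (arr.min() < 0 or arr.max() >= n):
                raise MeshError(f"{what} references a node outside [0, {n})")
        areas = self.tri_areas()
        if areas.size and areas.min() <= _MIN_TRI_AREA:
            raise MeshError(f"zero-area triangle (min area {areas.min():.3g} mm^2)")
        if self.tri_thickness.size and self.tri_thickness.min() <= 0.0:
            raise MeshError("non-positive membrane thickness")
        lengths = self.truss_lengths()
        if lengths.size and lengths.min() <= 0.0:
            raise MeshError("zero-length truss")
        if self.truss_ref_length.size and self.truss_ref_length.min() <= 0.0:
            raise MeshError("non-positive truss reference length")

    def nodal_membrane_area(self) -> np.ndarray:
        """Tributary reference area per node (one third of each incident
        triangle), used to convert surface tractions to nodal forces."""
        out = np.zeros(self.n_nodes)
        if self.tri_nodes.shape[0]:
            areas = self.tri_areas() / 3.0
            for c in range(3):
                np.add.at(out, self.tri_nodes[:, c], areas)
        return out

    def copy(self) -> "FEMesh":
        return FEMesh(
            nodes=self.nodes.copy(),
            tri_nodes=self.tri_nodes.copy(),
            tri_structure=self.tri_structure.copy(),
            tri_thickness=self.tri_thickness.copy(),
            truss_nodes=self.truss_nodes.copy(),
            truss_structure=self.truss_structure.copy(),
            truss_area=self.truss_area.copy(),
            truss_tension_only=self.truss_tension_only.copy(),
            truss_ref_length=self.truss_ref_length.copy(),
            node_sets={k: v.copy() for k, v in self.node_sets.items()},
            element_sets={k: (t, i.copy()) for k, (t, i) in self.element_sets.items()},
            ligament_chains={
                k: (a.copy(), b.copy()) for k, (a, b) in self.ligament_chains.items()
            },
            tri_pretension=None if self.tri_pretension is None
            else self.tri_pretension.copy(),
        )


@dataclass(frozen=True)
class Traction:
    """Uniform surface traction on a node set: magnitude (MPa) along a fixed
    unit direction, converted to dead nodal loads with tributary areas."""

    name: str
    node_set: str
    direction: tuple[float, float, float]
    magnitude: float  # MPa

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ParameterError(f"traction {self.name!r}: direction must be unit-norm")
        if self.magnitude < 0.0:
            raise ParameterError(f"traction {self.name!r}: magnitude must be >= 0")

    def dir_array(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float)


@dataclass(frozen=True)
class FixedSet:
    """Encastre-style support: the listed components of every node in the
    set are fixed to zero displacement."""

    node_set: str
    components: str = "xyz"

    def component_indices(self) -> list[int]:
        idx = [{"x": 0, "y": 1, "z": 2}[c] for c in self.components]
        if not idx:
            raise ParameterError("FixedSet needs at least one component")
        return idx


@dataclass
class LoadCase:
    tractions: list[Traction] = field(default_factory=list)
    fixed: list[FixedSet] = field(default_factory=list)
    tie_links: list[tuple[int, int]] = field(default_factory=list)
    nodal_forces: np.ndarray | None = None  # (n, 3) N, optional point loads
    n_load_steps: int = 10
    newton_tolerance: float = 1e-6  # N, residual 2-norm
    max_newton_iterations: int = 25
    # Numerical grounding spring per node (N/mm) regularising transverse
    # modes of slack tension-only filament chains; 0 disables it.
    stabilization: float = 0.0

    def __post_init__(self):
        if self.n_load_steps < 1:
            raise ParameterError("n_load_steps must be >= 1")
        if self.newton_tolerance <= 0.0:
            raise ParameterError("newton_tolerance must be > 0")
        if self.stabilization < 0.0:
            raise ParameterError("stabilization must be >= 0")

    def with_magnitudes(self, magnitudes: Mapping[str, float]) -> "LoadCase":
        """Copy of the load case with selected traction magnitudes replaced."""
        new = []
        for t in self.tractions:
            if t.name in magnitudes:
                t = replace(t, magnitude=float(magnitudes[t.name]))
            new.append(t)
        missing = set(magnitudes) - {t.name for t in self.tractions}
        if missing:
            raise ParameterError(f"unknown traction name(s): {sorted(missing)}")
        return replace(self, tractions=new)


@dataclass
class FEModel:
    """Mesh + material assignment + load case, the unit the solver consumes."""

    mesh: FEMesh
    materials: dict[str, MaterialModel]
    load_case: LoadCase

    def copy(self) -> "FEModel":
        return FEModel(
            mesh=self.mesh.copy(),
            materials=dict(self.materials),
            load_case=replace(
                self.load_case,
                tractions=list(self.load_case.tractions),
                fixed=list(self.load_case.fixed),
                tie_links=list(self.load_case.tie_links),
            ),
        )

    def node_set(self, name: str) -> np.ndarray:
        try:
            return self.mesh.node_sets[name]
        except KeyError:
            raise ModelError(f"model has no node set {name!r}") from None


@dataclass
class SimulationResult:
    """Converged displacement field plus solver diagnostics.

    ``residual_history`` holds one list of Newton residual norms (N) per
    completed load increment; ``reactions`` the summed constraint force (N)
    per fixed node set.
    """

    displacement: np.ndarray               # (n, 3) mm
    converged: bool
    residual_history: list[list[float]]
    reactions: dict[str, np.ndarray]
    n_steps_completed: int = 0
    n_newton_iterations: int = 0
    message: str = ""

    def displaced_nodes(self, mesh: FEMesh) -> np.ndarray:
        return mesh.nodes + self.displacement


def sum_applied_forces(mesh: FEMesh, load_case: LoadCase, scale: float = 1.0) -> np.ndarray:
    """Resultant of all applied loads (N), for global equilibrium checks."""
    total = np.zeros(3)
    area = mesh.nodal_membrane_area()
    for t in load_case.tractions:
        ids = mesh.node_sets[t.node_set]
        total += scale * t.magnitude * area[ids].sum() * t.dir_array()
    if load_case.nodal_forces is not None:
        total += scale * load_case.nodal_forces.sum(axis=0)
    return total
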