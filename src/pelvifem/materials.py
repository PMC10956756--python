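"""Constitutive parameter sets for pelvic tissue, ligaments and sutures.

Units: stresses and moduli in MPa, lengths in mm, forces in N (consistent
with MPa x mm^2 = N).

Two material kinds are supported:

* ``yeoh`` -- two-term Yeoh hyperelastic solid,
  ``W = C0*(I1 - 3) + C1*(I1 - 3)**2``, used for the hollow organs
  (vagina, bladder, rectum) which undergo large strains.
* ``linear_elastic`` -- St. Venant-Kirchhoff behaviour parameterised by a
  Young modulus ``E`` and Poisson ratio ``nu``, used for the pelvic floor,
  the fasciae, ligaments and suture filaments.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

from .errors import ParameterError

__all__ = [
    "MaterialModel",
    "TrussSection",
    "default_materials",
    "default_sections",
    "resolve_material",
    "resolve_section",
]


@dataclass(frozen=True)
class MaterialModel:
    """Constitutive parameters of one structure.

    For ``kind == "yeoh"`` only ``C0``/``C1`` are meaningful; for
    ``kind == "linear_elastic"`` only ``E``/``nu``.
    """

    kind: str
    C0: float = 0.0  # MPa
    C1: float = 0.0  # MPa
    E: float = 0.0   # MPa
    nu: float = 0.0  # dimensionless

    def __post_init__(self):
        if self.kind == "yeoh":
            if not self.C0 > 0.0:
                raise ParameterError(f"Yeoh C0 must be > 0, got {self.C0}")
            if self.C1 < 0.0:
                raise ParameterError(f"Yeoh C1 must be >= 0, got {self.C1}")
        elif self.kind == "linear_elastic":
            if not self.E > 0.0:
                raise ParameterError(f"Young modulus must be > 0, got {self.E}")
            if not 0.0 <= self.nu < 0.5:
                raise ParameterError(
                    f"Poisson ratio must lie in [0, 0.5), got {self.nu}"
                )
        else:
            raise ParameterError(f"unknown material kind {self.kind!r}")

    @classmethod
    def yeoh(cls, C0: float, C1: float) -> "MaterialModel":
        return cls(kind="yeoh", C0=C0, C1=C1)

    @classmethod
    def linear_elastic(cls, E: float, nu: float) -> "MaterialModel":
        return cls(kind="linear_elastic", E=E, nu=nu)


@dataclass(frozen=True)
class TrussSection:
    """Cross-section of a truss family: area in mm^2 and the tension-only flag.

    Suture filaments and ligaments cannot push (a thread buckles at zero
    force), so they default to tension-only; inter-organ links stand in for
    fascial connective tissue that also transmits compressive contact and
    therefore carry both signs.
    """

    area: float  # mm^2
    tension_only: bool = True

    def __post_init__(self):
        if not self.area > 0.0:
            raise ParameterError(f"truss area must be > 0, got {self.area}")


# Organ hyperelastic coefficients and linear-elastic table for the
# supporting structures.  Sutures are stiff elastic filaments.
_DEFAULT_MATERIALS: dict[str, MaterialModel] = {
    "vagina": MaterialModel.yeoh(0.111, 0.27),
    "uterus": MaterialModel.yeoh(0.111, 0.27),
    "bladder": MaterialModel.yeoh(0.0375, 0.07),
    "rectum": MaterialModel.yeoh(0.085, 0.056),
    "pelvic_floor": MaterialModel.linear_elastic(0.1, 0.45),
    "fascia_pubocervical": MaterialModel.linear_elastic(0.18, 0.45),
    "fascia_endopelvic": MaterialModel.linear_elastic(0.18, 0.45),
    "suture": MaterialModel.linear_elastic(3000.0, 0.3),
    "ligament": MaterialModel.linear_elastic(5.0, 0.45),
    "link": MaterialModel.linear_elastic(0.18, 0.45),
    # elastic bed coupling the sacrospinous ligament to the pelvic sidewall
    # (coccygeus muscle / sidewall embedding): gives the ligament its
    # transverse anchorage so a suture cannot drag it freely off its line
    "ligament_bed": MaterialModel.linear_elastic(3.0, 0.45),
}

_LIGAMENT_NAMES = {
    "sacrospinous_left",
    "sacrospinous_right",
    "uterosacral",
    "cardinal",
    "broad",
    "round",
    "ATFP",
}

_DEFAULT_SECTIONS: dict[str, TrussSection] = {
    "suture": TrussSection(area=0.2, tension_only=True),
    "ligament": TrussSection(area=10.0, tension_only=True),
    "link": TrussSection(area=4.0, tension_only=False),
    "ligament_bed": TrussSection(area=4.0, tension_only=False),
}


def _family(label: str) -> str:
    if label in _LIGAMENT_NAMES or label.startswith("ligament"):
        return "ligament"
    if label.startswith("suture"):
        return "suture"
    if label.startswith("link"):
        return "link"
    return label


def default_materials(overrides: Mapping[str, MaterialModel] | None = None
                      ) -> dict[str, MaterialModel]:
    """Return the default structure -> material table, with overrides applied."""
    table = dict(_DEFAULT_MATERIALS)
    if overrides:
        table.update(overrides)
    return table


def default_sections(overrides: Mapping[str, TrussSection] | None = None
                     ) -> dict[str, TrussSection]:
    table = dict(_DEFAULT_SECTIONS)
    if overrides:
        table.update(overrides)
    return table


def resolve_material(label: str, table: Mapping[str, MaterialModel]) -> MaterialModel:
    """Look up the material for a structure label, falling back to its family."""
    if label in table:
        return table[label]
    fam = _family(label)
    if fam in table:
        return table[fam]
    raise ParameterError(f"no material assigned to structure {label!r}")


def resolve_section(label: str, table: Mapping[str, TrussSection]) -> TrussSection:
    if label in table:
        return table[label]
    fam = _family(label)
    if fam in table:
        return table[fam]
    raise ParameterError(f"no truss section assigned to structure {label!r}")


def scaled_section(section: TrussSection, factor: float) -> TrussSection:
    return replace(section, area=section.area * factor)
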