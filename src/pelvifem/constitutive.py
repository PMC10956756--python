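"""Point-wise constitutive evaluations.

Membrane kinematics use the incompressible plane-stress reduction for the
Yeoh organs: with in-plane principal stretches ``lam1, lam2 > 0`` the
thickness stretch is ``lam3 = 1/(lam1*lam2)`` and

    I1 = lam1**2 + lam2**2 + 1/(lam1*lam2)**2.

The linear-elastic structures use a plane-stress St. Venant-Kirchhoff law in
the Green strain, which reduces to Hooke's law at small strain.
"""
from __future__ import annotations

import numpy as np

from .errors import ParameterError, StateError
from .materials import MaterialModel

__all__ = [
    "yeoh_energy_density",
    "yeoh_dW_dI1",
    "plane_stress_I1",
    "membrane_stress",
    "uniaxial_membrane_stress",
    "truss_force",
]

_I1_TOL = 1e-12


def yeoh_energy_density(I1, material: MaterialModel):
    """Two-term Yeoh strain-energy density W(I1) in MPa.

    ``W = C0*(I1-3) + C1*(I1-3)**2``; zero at the undeformed state
    ``I1 = 3`` and strictly increasing for ``I1 > 3``.
    """
    if material.kind != "yeoh":
        raise ParameterError(
            f"yeoh_energy_density needs a yeoh material, got {material.kind!r}"
        )
    I1 = np.asarray(I1, dtype=float)
    if np.any(I1 < 3.0 - _I1_TOL):
        raise StateError(f"first invariant below 3 is unattainable: {I1}")
    x = np.maximum(I1 - 3.0, 0.0)
    W = material.C0 * x + material.C1 * x * x
    return W if W.ndim else float(W)


def yeoh_dW_dI1(I1, material: MaterialModel):
    """dW/dI1 = C0 + 2*C1*(I1-3)."""
    x = np.maximum(np.asarray(I1, dtype=float) - 3.0, 0.0)
    out = material.C0 + 2.0 * material.C1 * x
    return out if out.ndim else float(out)


def plane_stress_I1(lam1, lam2):
    """First invariant under incompressible plane stress."""
    lam1 = np.asarray(lam1, dtype=float)
    lam2 = np.asarray(lam2, dtype=float)
    if np.any(lam1 <= 0.0) or np.any(lam2 <= 0.0):
        raise StateError("principal stretches must be positive")
    lam3sq = 1.0 / (lam1 * lam2) ** 2
    return lam1**2 + lam2**2 + lam3sq


def membrane_stress(lam1, lam2, material: MaterialModel):
    """Principal Cauchy stresses (MPa) of a membrane point under plane stress.

    For a Yeoh material (incompressible) the transverse normal stress is
    eliminated analytically:

        sigma_i = 2 * W'(I1) * (lam_i**2 - lam3**2),  lam3 = 1/(lam1*lam2).

    For a linear-elastic (St. Venant-Kirchhoff, plane stress) material the
    second Piola-Kirchhoff principal stresses are pushed forward with the
    area Jacobian ``lam1*lam2``.

    Returns a pair ``(sigma1, sigma2)``; both vanish at ``lam1 = lam2 = 1``.
    """
    lam1 = np.asarray(lam1, dtype=float)
    lam2 = np.asarray(lam2, dtype=float)
    if np.any(lam1 <= 0.0) or np.any(lam2 <= 0.0):
        raise StateError("principal stretches must be positive")
    if material.kind == "yeoh":
        lam3sq = 1.0 / (lam1 * lam2) ** 2
        I1 = lam1**2 + lam2**2 + lam3sq
        dW = yeoh_dW_dI1(I1, material)
        s1 = 2.0 * dW * (lam1**2 - lam3sq)
        s2 = 2.0 * dW * (lam2**2 - lam3sq)
    elif material.kind == "linear_elastic":
        E, nu = material.E, material.nu
        e1 = 0.5 * (lam1**2 - 1.0)
        e2 = 0.5 * (lam2**2 - 1.0)
        c = E / (1.0 - nu * nu)
        S1 = c * (e1 + nu * e2)
        S2 = c * (e2 + nu * e1)
        J = lam1 * lam2
        s1 = lam1**2 * S1 / J
        s2 = lam2**2 * S2 / J
    else:  # pragma: no cover - MaterialModel already validates the kind
        raise ParameterError(f"unknown material kind {material.kind!r}")
    if np.ndim(s1) == 0:
        return float(s1), float(s2)
    return s1, s2


def uniaxial_membrane_stress(lam, material: MaterialModel):
    """Closed-form uniaxial Cauchy stress of an incompressible Yeoh membrane.

    With lateral contraction free, ``lam2 = lam3 = lam**-0.5`` so
    ``I1 = lam**2 + 2/lam`` and

        sigma = 2 * (lam**2 - 1/lam) * (C0 + 2*C1*(I1 - 3)).
    """
    if material.kind != "yeoh":
        raise ParameterError("uniaxial closed form is for yeoh materials")
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0.0):
        raise StateError("stretch must be positive")
    I1 = lam**2 + 2.0 / lam
    out = 2.0 * (lam**2 - 1.0 / lam) * (material.C0 + 2.0 * material.C1 * (I1 - 3.0))
    return out if out.ndim else float(out)


def truss_force(lam, E: float, area: float, tension_only: bool = True):
    """Axial force (N) in a filament at stretch ``lam``.

    ``N = E*A*(lam - 1)`` in tension; a tension-only filament is slack
    (zero force) for ``lam < 1``.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0.0):
        raise StateError("stretch must be positive")
    strain = lam - 1.0
    if tension_only:
        strain = np.maximum(strain, 0.0)
    out = E * area * strain
    return out if out.ndim else float(out)
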