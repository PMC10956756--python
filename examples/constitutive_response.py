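"""Uniaxial response of the three hyperelastic organ tissues.

Evaluates the closed-form incompressible plane-stress Yeoh law for the
vaginal, bladder and rectal walls over a range of stretches and prints the
Cauchy stress.  The stiffening with stretch (the C1 term) is what makes
these tissues progressively resist large prolapse displacements.
"""
import numpy as np

from pelvifem import MaterialModel, uniaxial_membrane_stress

TISSUES = {
    "vagina": MaterialModel.yeoh(0.111, 0.27),
    "bladder": MaterialModel.yeoh(0.0375, 0.07),
    "rectum": MaterialModel.yeoh(0.085, 0.056),
}

stretches = np.array([1.05, 1.1, 1.2, 1.3, 1.5])
print("uniaxial Cauchy stress (MPa) vs stretch")
print("stretch  " + "  ".join(f"{n:>8s}" for n in TISSUES))
for lam in stretches:
    row = [uniaxial_membrane_stress(lam, mat) for mat in TISSUES.values()]
    print(f"{lam:7.2f}  " + "  ".join(f"{s:8.4f}" for s in row))
print(
    "\nEach column is one tissue; the vagina is the stiffest organ wall,\n"
    "the bladder the most compliant, consistent with their coefficients."
)
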