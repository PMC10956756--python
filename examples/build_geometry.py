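"""Build the synthetic pelvic geometry and inspect it.

Creates the generic (symmetric) and patient-like (asymmetric,
post-hysterectomy) variants, prints the bony landmarks, reference points
and mesh statistics, and exports the organ surfaces as STL into
./scratch_geometry/.
"""
import numpy as np

from pelvifem import GeometryParams, build_pelvic_geometry, mesh_geometry, patient_like_params
from pelvifem.io import export_surfaces_stl

for name, params in (
    ("generic", GeometryParams(support_condition="pathological")),
    ("patient-like", patient_like_params()),
):
    geom = build_pelvic_geometry(params)
    print(f"== {name} variant (symmetric={geom.symmetric})")
    for lm, p in geom.landmarks.items():
        print(f"  landmark {lm:32s} {np.round(p, 1)}")
    for rp in ("Ba", "C", "Bp"):
        print(f"  reference {rp}: {np.round(geom.reference_position(rp), 1)} "
              f"on {geom.reference_points[rp][0]}")
    mesh = mesh_geometry(geom)
    print(f"  mesh: {mesh.n_nodes} nodes, {len(mesh.tri_nodes)} membranes, "
          f"{len(mesh.truss_nodes)} trusses")
    print(f"  active ligaments: {', '.join(geom.active_ligaments())}")

paths = export_surfaces_stl(
    build_pelvic_geometry(patient_like_params()), "scratch_geometry"
)
print("\nSTL surfaces written:")
for p in paths:
    print(" ", p)
print("The pathological variant deactivates the broad and round ligaments,")
print("removing the apical suspension and letting the vault descend.")
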