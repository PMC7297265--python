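"""Static mechanics: point loads and an AFM indentation surrogate.

A solid responds to a downward push mostly along the push axis — the
qualitative contrast with spring networks, whose response spreads sideways.
The indentation surrogate prescribes displacements under a spherical tip
and reads off the force/depth slope per unit Young's modulus (κ_cal);
dividing a measured AFM stiffness by κ_cal yields the modulus in GPa.
"""

import numpy as np

import solidnma as s

# --- a slab pushed from above -------------------------------------------
slab = s.make_bar(9, 9, 4, spacing=1.5)
mesh = s.build_alpha_shape(slab, 3.0)
system = s.assemble(mesh, s.ElasticParams.for_mesh(mesh, slab.total_mass))
base = np.nonzero(slab.coords[:, 2] < 0.1)[0]
top = np.nonzero(slab.coords[:, 2] > 4.4)[0]
bc = s.BoundaryCondition(
    fixed_nodes=base, forces={int(n): np.array([0, 0, -0.01]) for n in top}
)
ext = s.deformation_extents(s.static_solve(system, bc), axis=2)
print(f"max |u_z| = {ext['max_axis']:.4f} Å,  max in-plane = "
      f"{ext['max_plane']:.4f} Å  (axial/planar ratio "
      f"{ext['max_axis'] / ext['max_plane']:.1f})")

# --- indentation of a hemispherical shell --------------------------------
shell = s.make_shell(14.0, 4.0, spacing=1.5, hemisphere=True)
smesh = s.build_alpha_shape(shell, 2.6)
params = s.ElasticParams.for_mesh(smesh, shell.total_mass)
kappa = s.indentation_stiffness(smesh, params, tip_radius=10.0,
                                contact_depth_step=0.5)
print(f"shell stiffness slope κ_cal = {kappa:.3f} nm per unit E (GPa)")

# with a computed slope and a measured AFM stiffness, the modulus follows:
k_exp = 0.15  # nN/nm, a typical capsid stiffness
print(f"AFM-calibrated modulus for k_exp = {k_exp} nN/nm: "
      f"{s.young_from_afm(kappa, k_exp):.2f} GPa")
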