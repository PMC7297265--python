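# Methods

## The solid model

A structure is represented by a set of N labelled nodes (Cα atoms, heavy
atoms, or thresholded density voxels) with per-node masses.  The solid is
the alpha shape of the nodes: the subset of Delaunay tetrahedra whose
circumsphere radius is ≤ α, with only 3-simplices kept (no dangling edges
or triangles).  Node coordinates are used verbatim — the mesh never
introduces vertices — so eigenvectors, fluctuations, and deformations are
defined directly on the input atoms.

Circumradii are computed from the 3×3 equidistance system
2(pᵢ−p₀)·c = |pᵢ|²−|p₀|²; degenerate cells get radius ∞.  Exactly
coplanar Delaunay cells (volume < 10⁻⁹ Å³), which regular lattices
produce, are dropped before filtering; they carry no volume but their
removal can expose coincident internal face pairs, so the boundary-surface
extraction verifies each candidate face by probing a point just outside it
against the incident tetrahedra.  Cospherical ties in the triangulation are
resolved by Qhull's symbolic perturbation; alternative backends may
triangulate zero-measure configurations differently, which can change
tetrahedron counts but not volumes or physics.

When no α is given, the critical alpha is used: the smallest value whose
shape has every node as a vertex.  Because a node is enclosed as soon as α
reaches the smallest circumradius among its incident tetrahedra, the
critical value is exactly the maximum over nodes of that per-node minimum —
no search is needed, though tests cross-check against a brute-force scan
over the sorted radius candidates.  `alpha_for_volume` inverts the
(stepwise, non-decreasing) volume-vs-α function over the same finite
candidate set, returning the smallest α of the plateau closest to the
target; this is how a coarser model's α is matched to a finer model's
volume.  A bracketing error is raised only for targets outside the
attainable range; a near-miss beyond 0.1% relative warns instead of
failing, since plateaus are quantized by whole tetrahedra.

## Elasticity, units, and matrices

The material is homogeneous isotropic linear elastic: Young's modulus E in
kcal mol⁻¹ Å⁻³ (≈ 6.95 GPa per unit), Poisson ratio ν = 0.3 by default
(protein elasticity is weakly sensitive to ν in the 0.2–0.4 range), and
uniform density ρ = total node mass / solid volume in amu Å⁻³.  Elements
are 4-node constant-strain tetrahedra: Kₑ = V·BᵀCB with the Voigt-form
isotropic C(λ, μ), assembled by scatter-add into a sparse 3N×3N stiffness
K with x, y, z interleaved per node.  K is linear in E, translation
invariant, and annihilates the six rigid-body vectors of a connected mesh.

The mass matrix is the consistent FEM mass — ρV/20·(1+δᵢⱼ) per element on
the scalar (per-node) level, expanded to 3N×3N by a Kronecker product with
I₃ — rather than the diagonal lumped mass of network models.  A lumped
option exists for sensitivity checks.  Total mass is conserved exactly:
1ᵀM1 per axis equals ρ × volume.

Working units are Å / kcal·mol⁻¹ / amu.  Eigenvalues of (K, M) then carry
kcal mol⁻¹ amu⁻¹ Å⁻² and convert to spectroscopic wavenumbers by
ω[cm⁻¹] = 108.59·√λ, with the factor derived at import time from CODATA
constants (c = 2.997925×10¹⁰ cm/s).  k_B = 0.0019872 kcal mol⁻¹ K⁻¹ and
T = 298 K by default.  Published absolute frequencies for specific
proteins depend on the (often unstated) mass/density convention of the
original computation; ours is declared above, and deviations should be
reported, not tuned away.

Node-mass conventions: Cα nodes carry their residue's average residue mass
(57–186 amu; 110 amu for unknown residues), heavy-atom nodes carry atomic
weights, density voxels carry mass proportional to density normalized to a
user-specified total (default 110 amu per kept voxel).  Hydrogens and
waters are always excluded; alternate locations keep the highest-occupancy
atom (ties: alphabetically first).  Disconnected-segment removal (e.g. an
unresolved N-terminal hairpin) is an explicit residue-range exclusion,
never auto-detected.

## Modes, fluctuations, calibration, overlaps

Modes solve Kv = λMv: dense generalized `eigh` up to 1200 DOFs, sparse
shift-invert Lanczos above (shift σ < 0, valid because K is PSD and M is
SPD).  Eigenvectors are M-orthonormalized with a deterministic sign
convention.  Rigid modes are flagged by λ < 10⁻⁸ × (largest computed λ);
a connected free solid must show exactly 6 (12 for two components) and a
mismatch warns.  Mode indexing in all reports starts at the first
non-rigid mode.

Equipartition sets thermal amplitudes Aₖ² = k_BT/(Eλₖ) for a system
assembled at unit modulus, giving per-node mean-square fluctuations
msf_i = (k_BT/E) Σₖ |v_{k,i}|²/λₖ over non-rigid modes and B-factors
B = 8π²/3·msf.  The identical quantity is also computed, as a cross-check,
from the 3×3 diagonal blocks of M^{-½}Kₘ⁺M^{-½} (Kₘ = M^{-½}KM^{-½},
rigid modes deflated); the algebraic identity between the two routes is
verified numerically in the tests, not assumed.  The modulus is calibrated
by a least-squares scale fit: with P the predicted B at E = 1, the optimal
1/E is (P·B_exp)/(P·P); whether experimental B-factors reflect thermal
motion alone is a caveat for the user, not the fit.  The same machinery
calibrates the network model's spring constant γ (its Hessian is taken at
unit γ, mirroring the unit-E convention).

Overlaps of a conformational change d with the modes use the
mass-weighted basis: Oₖ = d·qₖ/‖d‖, qₖ = M^½vₖ (Euclidean-orthonormal, so
Parseval's sum over the complete basis is exactly 1).  Structures are
rigid-superposed (Kabsch) before differencing — overlaps are meaningless
against a rigid offset.  Summary metrics follow the conformational-change
benchmark conventions: α₁..α₃ are the three best |O|; δ_m = √(Σ_{k≤m}Oₖ²)
over the first m non-rigid modes for m = 3, 5, 10; Nα₁ is the (non-rigid,
1-based) index of the best mode; Nσ₉₀ is the smallest m with cumulative
squared overlap ≥ 0.90 (we restate this definition explicitly since
published benchmarks sometimes inherit it by citation only).  The vibrational
spectrum's cumulative distribution G(ω) is fitted as G ∝ ω^b by ordinary
least squares in log–log space over modes below the median frequency; the
fit window is a package choice, as published fits rarely state theirs.

## Statics and indentation

Static response solves K_ff u_f = f_f − K_fc u_c on free DOFs after
eliminating clamped nodes and prescribed displacements (sparse LU; a
singular reduced system raises an under-constrained error naming the
remaining rigid motion).  Reactions are recovered at constrained DOFs;
global force balance and the work–energy identity ½uᵀKu = ½fᵀu hold to
solver precision and are asserted in tests.

The AFM indentation surrogate is a *linearized* contact model: a rigid
sphere of given radius, centred on the structure's axis, is lowered one
depth step from first touch; nodes inside the sphere receive prescribed
axial displacements equal to their penetration, base nodes are clamped,
and the total axial reaction divided by depth is the stiffness.
Normalized by E it is exactly E-independent (K ∝ E) and converts to the
nm-per-GPa-unit scale used with AFM data; E = k_exp/κ_cal then yields a
modulus in GPa.  A full nonlinear contact FEA would track the evolving
contact set and large deformations; the linear surrogate reproduces the
small-indentation slope only, so agreement with nonlinear published slopes
is order-of-magnitude.  For that use case the mesh exporters (VTK legacy,
Abaqus INP with C3D4 elements, GMSH MSH 2.2) hand the same solid to
external FEA programs.

## Coarse-graining

Layer-wise peeling: build the alpha shape of the current point set, take
the nodes of its boundary triangles as the surface layer, decimate that
triangle mesh to the target fraction, remove the whole layer, and recurse
on the interior until fewer than 4 points remain or the layer cap is hit;
leftover interior points are voxel-grid downsampled to the same fraction
(voxel size bisected to hit the count, representative per voxel chosen by
a seeded RNG).  The decimator is an in-house quadric edge collapse that
collapses each edge onto the endpoint with the smaller combined quadric
error — vertices never move, so retained nodes are exactly a subset of the
input coordinates, preserving the nodes-are-atoms property without a
snap-back step.  Collapses that would pinch the surface (edges whose
endpoints share more than two neighbours) are skipped, so very small
fractions may keep slightly more faces than requested rather than break
the surface.  Interior and surface are thinned to the same fraction so
that re-running the alpha shape on the coarse set still produces a proper
surface.  Determinism: identical inputs and seed give identical output.

## Synthetic fixtures and what they do (not) show

Generators: cubic lattices (known exact volumes), rectangular bars (known
continuum frequencies — the free-free fundamental axial wavenumber is
(1/2L)√(E/ρ), reproduced within 1% on a 21×3×3 bar and converging under
refinement), spherical/hemispherical shells (indentation), supercoiled
helical Cα-like traces (protein-like 3.8 Å spacing and 110 amu masses),
and binary sphere density maps (known volume, used for the density
pipeline and coarse-graining).  All are deterministic under a seed.

These fixtures validate the geometry, the FEM assembly, the unit system,
and every algebraic identity, but they are not proteins: they do not probe
heterogeneous packing, real B-factor noise (which mixes static disorder
with thermal motion), or experimental map artefacts.  Tests passing on
them certify the machinery, not agreement with any particular experiment.

Known limitations: linear elasticity only (no large deformation, buckling,
or nonlinear contact); a single uniform material per solid; only the
tetrahedral (3-simplex) alpha complex; no weighted alpha shapes or cavity
detection; assembly expansion uses the operators recorded in the file, no
space-group inference.

## Problem sizes

Default tests and the acceptance script run on 27–4,000-node models
(≤ ~12,000 DOFs, dense eigensolves only below 1,200 DOFs), chosen so the
full suite completes in well under a minute while still exercising the
sparse solver path, multi-thousand-node density pipelines, and three
refinement levels of the bar.
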