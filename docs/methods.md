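# Methods

This note documents the models, numerical choices and limitations behind
molcanvas, in the order the pipeline uses them.

## Structure model and parsing

Structures are stored hierarchically (chains → residues → atoms), with
1-based PDB residue numbering, Ångström coordinates and right-handed axes
as stored in the file. The PDB reader follows wwPDB v3.3 fixed columns.
Lenient-parsing rules: an atom record shorter than the mandatory 54
coordinate columns (or with unparseable coordinates) is skipped with a
logged warning; parsing fails only when no atom survives. Alternate
locations are restricted to `' '` and `'A'` — the simplest deterministic
rule. Multi-model PDB files (NMR ensembles) keep model 1 only, whereas
multi-MODEL PDBQT files keep every model, because there the models are
docking poses and the whole point of the file. Waters and ions are parsed
and retained; consumers that must ignore them (ligand detection) filter
them out themselves.

Element inference takes the PDB element columns (77–78) first, then the
AutoDock type map for PDBQT atoms (OA/OS → O, NA/NS → N, HD/HS → H,
A → aromatic carbon, …), then an atom-name heuristic in which standard
amino-acid residues use the organic one-letter set (so ` CA ` in alanine
is carbon while `CA` in a hetero ion site is calcium). A single Bondi
radii table is used everywhere: C 1.70, N 1.55, O 1.52, S 1.80, H 1.20,
P 1.80 Å, default 1.70 Å for unknown elements (with a warning).

The PDBQT energy parser accepts any REMARK containing an energy token
(`RESULT`, `ENERGY`, `AFFINITY`, `KCAL`) plus a decimal number, because
docking engines differ in the exact remark they write; the remark line
actually used is recorded on the ensemble (`energy_remarks`) so the
provenance of each energy is auditable.

## Surfaces

All four surfaces are level sets of scalar fields on an axis-aligned
isotropic voxel grid.

**Grid.** Default resolution 4 voxels/Å (spacing 0.25 Å). The grid box
covers every atom inflated by (vdW radius + probe radius) plus a 2-voxel
margin. No dimension may exceed the cap (default 180): when a molecule is
too large, the spacing is uniformly *coarsened* until it fits. Cropping
was rejected because it would truncate the molecule; coarsening merely
lowers resolution.

**Fields.** The signed distance to the union of (optionally inflated)
atom spheres is computed as min over atoms of ‖v − c_i‖ − (r_i + inflation),
with the argmin atom recorded per voxel (ties break to the lowest atom
index). VdW and SAS surfaces are the zero level sets with inflation 0 and
r_p. For SES/MS an exact Euclidean distance transform
(scipy.ndimage.distance_transform_edt, with index propagation for atom
attribution) measures the inward distance from the SAS exterior. The raw
center-to-center EDT carries a half-voxel outward bias, so the distance
to the nearest exterior voxel center is corrected by that voxel's own
positive signed distance to the SAS iso-boundary; for a sphere this
reconstruction is exact up to interpolation. The correction preserves the
voxelwise guarantee that VdW-interior voxels keep depth ≥ r_p (triangle
inequality against the atom containing the voxel), so the nesting
invariant VdW ⊆ SES/MS ⊆ SAS holds without fudges.

**Two derivations of the same surface.** `ses` uses the erosion route
(level set depth = r_p: the SAS solid eroded by the probe ball); `ms`
uses the closing route (VdW solid united with SAS-interior voxels no
probe center can reach). In the continuum they coincide; on the grid they
differ on at most a one-voxel shell where the VdW solid pokes out of the
eroded SAS. Which label maps to which derivation is swappable with
`compute_surface(..., swap_ses_ms=True)`.

**Meshing.** Marching cubes (scikit-image, Lewiner variant, linear edge
interpolation) extracts the level set; normals come from the field
gradient. If any grid value equals the isovalue exactly, the level is
nudged by a relative 1e-9 so that no cell corner lies on the surface —
exact hits create duplicate vertices and open the mesh. Remaining
coincident vertices are welded (coordinates rounded at 1e-7 Å) and
triangles with area < 1e-12 Å² dropped, after which meshes of solids
strictly inside the grid are watertight. Ambiguous saddle configurations
are resolved by the table, not an asymptotic decider, so tunnels at such
saddles may differ from other EDT implementations by one voxel. Each
vertex is attributed to the nearest-atom id of its edge endpoint with the
smaller |field| value, which drives per-vertex surface coloring.

Optional Laplacian smoothing (v ← v + 0.5·(mean of neighbors − v)) may be
applied to reduce voxel staircase artifacts; it never changes topology.
Accuracy at the defaults: a single-atom VdW sphere area is within ~0.5%
of 4πr², the SES of one atom within ~2.1% (measured by the acceptance
script), comfortably inside the 5% band the tests assert.

## Hydrogen bonds

A putative intermolecular hydrogen bond is a cross-molecule
donor/acceptor pair with heavy-atom (donor–acceptor) separation ≤ 3.5 Å.
The distance-only criterion with the conventional D–A cutoff is used
deliberately: without hydrogens (typical crystal-structure PDB input) an
angle term is not well defined. Chemistry rules, documented and
overridable:

* PDBQT route — acceptors: AutoDock types OA/NA/SA; donors: N or O with a
  covalently attached HD hydrogen (attachment = distance < 1.3 Å).
* PDB route — donors: backbone N, side-chain N of Lys/Arg/His/Trp/Asn/Gln,
  hydroxyl O of Ser/Thr/Tyr; acceptors: every O plus His side-chain N;
  hetero-group N/O take both roles.

Pairs are found with a KD-tree in both directions, deduplicated as
unordered pairs and sorted by length. Labels (`chain:resname
resseq:atomname` anchored at the atom position) are emitted once per
distinct participating atom.

## Docking box

The binding site comes from the largest co-crystallized ligand: the
hetero residue group with the most atoms, excluding waters (HOH/WAT/DOD)
and a documented list of monoatomic ions / crystallization additives
(NA, K, CL, MG, CA, ZN, MN, FE, CU, CO, NI, CD, HG, SO4, PO4); ties break
to first occurrence. The box is cubic — center at the midpoint of the
ligand coordinate extremes, edge = (1 + expand) × the largest per-axis
extent with expand = 0.5 — i.e. cube-first-then-expand; an axis-wise
rectangular variant is available behind `cubic=False` since the wording
"extend in all three dimensions" admits both readings. A 10 Å edge floor
guards degenerate (single-atom) ligands and a 20 Å default edge is used
when no ligand exists and the box falls back to the protein's unweighted
geometric center; both magnitudes are typical docking search-space sizes
and are exposed as parameters. Containment uses closed intervals, so an
atom exactly on a face counts as inside.

## Representations and colors

Bonds are derived by distance (d < 1.2 × sum of single-bond covalent
radii, KD-tree search), with explicit CONECT pairs honored additively.
Backbone curves are uniform Catmull–Rom splines through consecutive Cα
atoms with duplicated endpoints, 8 subdivisions per residue — a local,
interpolating scheme, so the curve passes exactly through every Cα.
Ribbons extrude the spline 1.6 Å wide along parallel-transported frames;
B-factor tubes scale a circular cross-section by B/mean(B); cylinder &
plate fits a least-squares axis through each helix run's Cα atoms.
Spheres are icospheres (20·4^s faces, subdivision default 2) for even
tessellation; sticks are 12-sided cylinders of radius 0.25 Å split at the
bond midpoint for bicolor shading; ball & stick scales spheres to
0.4 × vdW. Chains with fewer than two Cα atoms contribute an empty batch
with a warning.

Color schemes: spectrum (hue 240°→0° over residue rank per chain), chain
(8-color palette cycled), secondary structure (helix magenta, sheet
amber, coil gray), B factor (blue→red, monotone after min–max
normalization; constant B maps to the midpoint), residue name (fixed
palette), polarity (polar = Arg, Asn, Asp, Gln, Glu, His, Lys, Ser, Thr,
Tyr, Cys, Trp; two colors), and CPK element colors.

## Rendering

The software rasterizer is fixed-function and deterministic: z-buffered
barycentric triangle fill with Gouraud shading, 1-px DDA lines, 1-px
points, no antialiasing. Lighting is a single headlight at the eye
(two-sided Lambert, ambient 0.2) — the simplest model that shades
curvature without introducing configuration state. Opaque batches render
first; translucent batches (opacity 1.0–0.5) composite afterwards
back-to-front against the opaque depth buffer. Both camera models share
one code path: orthographic depth is linear in view z, perspective uses
the standard perspective divide, and a perspective point at or behind the
eye plane raises an error. Interpolation is screen-space linear (not
perspective-correct) — invisible at the image sizes and depth ranges
involved. The default camera sits on +z at twice the bounding-sphere
radius. Repeated renders of identical scenes are byte-identical PNGs,
which the tests rely on.

Anaglyph stereo displaces the two eyes ±s/2 along the camera right
vector with both converging on the target (so disparity is zero at the
target depth and grows with distance from it), then packs the left view's
luminance into the red channel and the right view's into green and blue.
The gray (luminance) encoding was chosen over color anaglyph to avoid
retinal rivalry on saturated molecular colors. Labels are drawn with a
fixed bitmap font at the projected anchor plus a constant offset;
off-screen or behind-camera anchors are skipped, and draw order is by
atom serial for determinism.

## Synthetic fixtures

All tests run on generated structures: diatomic probes, ideal α-helix Cα
traces (rise 1.5 Å/residue, 100°/residue, radius 2.3 Å — consecutive Cα
distances come out at the canonical 3.8 Å), hetero ligand blobs whose two
corner atoms pin exact per-axis extents, sphere clusters at stated
centers, and multi-MODEL PDBQT ensembles with REMARK energies and at
least one OA acceptor and HD-bearing donor. The only randomness is the
seeded interior jitter of the ligand blob; everything else is closed
form, so the same spec and seed produce byte-identical files.

What the fixtures do *not* emulate: full backbone/side-chain atoms
(helices are Cα-only), realistic packing density, alternate conformers,
disorder, or experimental noise in B factors. Passing tests therefore
demonstrate the geometric and algorithmic contracts — parsing fidelity,
field/mesh correctness against analytic oracles, cutoff and box
arithmetic, render determinism — not biochemical realism of any
particular protein family. The suite's one real-structure check (the
two-copy CCR5–maraviroc asymmetric unit) needs the public wwPDB archive
and fails with an explanatory message when the network is unreachable.

## Problem sizes

Property tests use grids of 10³–12³ voxels for brute-force distance
comparisons, single atoms and ≤ 30-atom fixtures for surface areas and
nesting at 3–4 voxels/Å, and images of 100×80 to 200×150 pixels; the
acceptance script uses the same sizes plus one 200 Å three-atom cluster
to exercise grid coarsening. These sizes were chosen so each analytic
oracle remains exactly computable while every code path — capped grids,
EDT correction, both SES/MS routes, stereo compositing — is exercised.

## Known limitations

* No mmCIF input, PDB writing, bond-order perception or hydrogen
  addition.
* Surface cavities are only those the erosion/closing construction
  produces; there is no dedicated cavity or pocket detector.
* Hydrogen-bond detection has no angular term and no salt-bridge,
  π-stacking or hydrophobic-contact detection.
* The rasterizer is not perspective-correct and unantialiased by design;
  it is an instrument for deterministic, verifiable output rather than a
  production renderer.
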