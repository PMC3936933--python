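# molcanvas

Headless visualization core for protein–ligand complexes: everything a
structure viewer computes *before* pixels hit a GPU, as a plain Python
library with a CLI. It targets structural bioinformaticians and docking
practitioners who need reproducible, scriptable versions of the usual
interactive steps — parsing receptors and docking poses, building
molecular surfaces, finding hydrogen bonds, defining a search box,
rendering publication images — on machines without a display.

## What it computes

* **Parsing** — PDB (wwPDB v3.3 columns) and the AutoDock/docking PDBQT
  dialect: multi-MODEL pose files, ROOT/BRANCH/TORSDOF torsion trees,
  per-atom types and partial charges, and predicted binding energies from
  REMARK lines. Structures are chains → residues → atoms with per-residue
  helix/sheet/coil flags and Bondi van der Waals radii.
* **Surfaces** — the four standard macromolecular surfaces on a voxel
  grid, via exact Euclidean distance transforms (EDT) and marching cubes:
  van der Waals (VdW, union of atom spheres), solvent-accessible (SAS,
  radii inflated by the probe radius r<sub>p</sub> = 1.4 Å),
  solvent-excluded (SES, the SAS solid eroded by the probe ball) and
  molecular surface (MS, the morphological closing of the VdW solid —
  mathematically the same surface as the SES, derived differently). The
  grid never exceeds 180×180×180 voxels; oversized molecules coarsen the
  spacing instead of being cropped. Nesting holds voxelwise:
  VdW ⊆ SES/MS ⊆ SAS.
* **Hydrogen bonds** — putative intermolecular donor–acceptor pairs with
  heavy-atom separation ≤ 3.5 Å (no angle term), with AutoDock-type
  chemistry (OA/NA/SA acceptors, N/O–HD donors) for PDBQT and
  residue-table chemistry for hydrogen-free PDB input, plus atom labels
  for annotation.
* **Docking box** — the binding site from the largest co-crystallized
  ligand: smallest cube covering the ligand, extended by 50% per axis
  (center c = midpoint of the coordinate extremes, edge
  e = 1.5 · max-extent), falling back to the protein's geometric center;
  plus pose-containment checks.
* **Representations** — line / stick / ball & stick / sphere / dot and
  ribbon / strand / Cα trace / B-factor tube / cylinder & plate geometry
  with seven color schemes (spectrum, chain, secondary structure,
  B factor, residue, polarity, CPK).
* **Rendering** — deterministic software rasterizer (z-buffer, Gouraud
  shading, orthographic/perspective cameras) to PNG, with translucent
  surface compositing, text labels, and gray anaglyph stereo (left eye in
  the red channel, right eye in green/blue).

## Worked example

All inputs below are generated by the built-in fixture generators — no
downloads required.

```sh
molcanvas fixtures make ligand_blob --param 'extents=[10,6,4]' -o blob.pdb
molcanvas fixtures make docked_ensemble --param k=2 \
    --param 'energies=[-9.1,-8.4]' -o poses.pdbqt

molcanvas info poses.pdbqt
# models: 2
# model 1: 5 atoms  energy -9.10 kcal/mol
# model 2: 5 atoms  energy -8.40 kcal/mol

molcanvas box blob.pdb --check poses.pdbqt
# {"center": [0.0, 0.0, 0.0], "edge": 15.0, "containment":
#  [{"model": 1, "all_inside": true, "atoms_outside": 0},
#   {"model": 2, "all_inside": true, "atoms_outside": 0}]}
```

The ligand blob spans 10 Å on its longest axis, so the tight covering
cube has edge 10 Å and the automatic search box is 1.5 × 10 = 15 Å; both
docked poses fall inside it. Hydrogen bonds between a receptor and a
pose are reported as TSV:

```sh
molcanvas hbonds rec.pdbqt poses.pdbqt
# donor	acceptor	length_A
# L:LIG 1:N1	A:RES 1:O1	2.51
```

The ligand amine (N1, a nitrogen with a polar hydrogen) donates to the
receptor's OA-typed oxygen at 2.51 Å, within the 3.5 Å cutoff. Surfaces
and images come from the same structures:

```sh
molcanvas surface blob.pdb --kind ses -o blob_ses.obj
# 7822 vertices, 15640 triangles -> blob_ses.obj
molcanvas render helix.pdb --rep ribbon --color spectrum -o helix.png
molcanvas render helix.pdb --rep sphere --anaglyph 3.0 --bg black \
    -o helix_anaglyph.png
```

The same operations are available as library functions
(`molcanvas.parse_pdbqt`, `compute_surface`, `detect_hbonds`,
`auto_box`, `rasterize`, `render_anaglyph`, …).

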