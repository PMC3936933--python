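"""EDT-based surface construction: grids, distance fields, meshes."""

import numpy as np
import pytest
import trimesh as trimesh_lib
from scipy.ndimage import binary_erosion
from scipy.spatial.distance import cdist

from molcanvas import (
    build_grid,
    compute_surface,
    exact_edt,
    extract_isosurface,
    mesh_area_volume,
    min_signed_distance_field,
    smooth_mesh,
)
from molcanvas.errors import NoAtomsError, NoFeaturesError
from molcanvas.fixtures import FixtureSpec, synth_pdb
from molcanvas.surface_engine import (
    GridSpec,
    ScalarField,
    TriangleMesh,
    surface_solids,
)
from tests.conftest import load_pdb


def sphere_area(r):
    return 4.0 * np.pi * r * r


class TestBuildGrid:
    def test_single_atom_dims_arithmetic(self, single_atom):
        grid = build_grid(single_atom(2.0), probe_radius=0.0,
                          target_resolution=4.0)
        # extent 4 A at 0.25 A spacing + 1 + 2*2 margin voxels = 21
        assert grid.dims == (21, 21, 21)
        assert grid.spacing == pytest.approx(0.25)

    def test_cap_honored_for_200A_structure(self):
        s = load_pdb(synth_pdb(FixtureSpec("sphere_cluster", {
            "centers": [(0, 0, 0), (200, 0, 0)]})))
        grid = build_grid(s, probe_radius=1.4, target_resolution=4.0)
        assert all(d <= 180 for d in grid.dims)
        assert grid.spacing > 0.25  # coarsened, not cropped

    def test_custom_cap(self):
        s = load_pdb(synth_pdb(FixtureSpec("sphere_cluster", {
            "centers": [(0, 0, 0), (200, 0, 0)]})))
        grid = build_grid(s, 1.4, 4.0, cap=10)
        assert all(d <= 10 for d in grid.dims)

    def test_no_atoms_raises(self):
        with pytest.raises(NoAtomsError):
            build_grid([], 0.0, 4.0)


class TestSignedDistanceField:
    def test_closed_form_values(self, single_atom):
        s = single_atom(1.5)
        grid = GridSpec(origin=np.array([-3.0, 0.0, 0.0]), spacing=3.0,
                        dims=(3, 1, 1))
        field = min_signed_distance_field(s, grid, inflation=0.0)
        # voxels at x = -3, 0 (atom center), +3
        assert field.values[1, 0, 0] == pytest.approx(-1.5)
        assert field.values[0, 0, 0] == pytest.approx(1.5)
        assert field.values[2, 0, 0] == pytest.approx(1.5)

    def test_inflation_shifts_field(self, single_atom):
        s = single_atom(1.5)
        grid = GridSpec(origin=np.zeros(3), spacing=1.0, dims=(2, 2, 2))
        f0 = min_signed_distance_field(s, grid, 0.0)
        f1 = min_signed_distance_field(s, grid, 1.4)
        assert np.allclose(f0.values - f1.values, 1.4)

    def test_midpoint_tie_breaks_to_lowest_index(self, diatomic):
        s = diatomic(4.0, elements=("C", "C"))
        grid = GridSpec(origin=np.array([2.0, 0.0, 0.0]), spacing=1.0,
                        dims=(1, 1, 1))  # single voxel at the midpoint
        field = min_signed_distance_field(s, grid, 0.0)
        assert field.nearest_atom[0, 0, 0] == 0


class TestExactEdt:
    def test_all_feature_mask_is_zero(self):
        field = exact_edt(np.ones((4, 4, 4), dtype=bool))
        assert np.all(field.values == 0)

    def test_single_feature_corner_distance(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        field = exact_edt(mask)
        assert field.values[0, 0, 0] == pytest.approx(np.sqrt(12), abs=1e-9)

    def test_no_features_raises(self):
        with pytest.raises(NoFeaturesError):
            exact_edt(np.zeros((3, 3, 3), dtype=bool))

    def test_matches_bruteforce_on_random_masks(self, rng):
        """Exact EDT equals an all-pairs nearest-feature scan."""
        shape = (10, 10, 10)
        coords = np.argwhere(np.ones(shape, dtype=bool)).astype(float)
        for _ in range(20):
            mask = rng.random(shape) < 0.05
            if not mask.any():
                mask[tuple(rng.integers(0, 10, size=3))] = True
            expected = cdist(coords, np.argwhere(mask).astype(float)) \
                .min(axis=1).reshape(shape)
            field = exact_edt(mask)
            assert np.allclose(field.values, expected, atol=1e-9)

    def test_nearest_atom_propagated_from_features(self):
        mask_values = np.zeros((5, 1, 1))
        mask_values[0] = 1.0
        mask_values[4] = 1.0
        ids = np.full((5, 1, 1), -1, dtype=np.int32)
        ids[0], ids[4] = 7, 9
        grid = GridSpec(origin=np.zeros(3), spacing=1.0, dims=(5, 1, 1))
        field = exact_edt(ScalarField(grid=grid, values=mask_values,
                                      nearest_atom=ids))
        assert field.nearest_atom[1, 0, 0] == 7
        assert field.nearest_atom[3, 0, 0] == 9


def _edge_counts(mesh):
    edges = np.concatenate([mesh.triangles[:, [0, 1]],
                            mesh.triangles[:, [1, 2]],
                            mesh.triangles[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return counts


class TestIsosurface:
    def test_uniform_field_empty_mesh(self):
        grid = GridSpec(origin=np.zeros(3), spacing=1.0, dims=(4, 4, 4))
        field = ScalarField(grid=grid, values=np.ones((4, 4, 4)))
        mesh = extract_isosurface(field, 0.0)
        assert mesh.n_triangles == 0

    def test_cube_volume_within_2_percent(self):
        # Chebyshev SDF of a cube with half-edge 3 (exact for a cube)
        n = 41
        ax = np.arange(n) * 0.25 - 5.0
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
        values = np.maximum.reduce([np.abs(x), np.abs(y), np.abs(z)]) - 3.0
        grid = GridSpec(origin=np.array([-5.0] * 3), spacing=0.25,
                        dims=(n, n, n))
        mesh = extract_isosurface(ScalarField(grid=grid, values=values), 0.0)
        _, volume = mesh_area_volume(mesh)
        assert volume == pytest.approx(6.0 ** 3, rel=0.02)

    def test_sphere_mesh_watertight(self, single_atom):
        mesh = compute_surface(single_atom(2.0), "vdw")
        counts = _edge_counts(mesh)
        assert np.all(counts == 2)


class TestComputeSurface:
    def test_vdw_area_single_atom(self, single_atom):
        mesh = compute_surface(single_atom(2.0), "vdw", target_resolution=4.0)
        area, _ = mesh_area_volume(mesh)
        assert area == pytest.approx(sphere_area(2.0), rel=0.05)

    def test_ses_closing_of_one_sphere_is_itself(self, single_atom):
        mesh = compute_surface(single_atom(1.7), "ses", probe_radius=1.4)
        area, _ = mesh_area_volume(mesh)
        assert area == pytest.approx(sphere_area(1.7), rel=0.05)

    def test_sas_disjoint_spheres(self, diatomic):
        s = diatomic(20.0, elements=("C", "C"))
        for atom in s.atoms:
            atom.vdw_radius = 1.7
        mesh = compute_surface(s, "sas", probe_radius=1.4)
        area, _ = mesh_area_volume(mesh)
        assert area == pytest.approx(2 * sphere_area(3.1), rel=0.05)

    def test_unknown_kind_rejected(self, single_atom):
        with pytest.raises(ValueError):
            compute_surface(single_atom(), "blobby")

    def test_area_volume_agree_with_trimesh(self, single_atom):
        mesh = compute_surface(single_atom(2.0), "vdw")
        area, volume = mesh_area_volume(mesh)
        ref = trimesh_lib.Trimesh(vertices=mesh.vertices,
                                  faces=mesh.triangles, process=False)
        assert area == pytest.approx(ref.area, rel=1e-6)
        assert volume == pytest.approx(abs(ref.volume), rel=1e-6)

    def test_swap_flag_exchanges_derivations(self, single_atom):
        s = single_atom(1.7)
        ses = compute_surface(s, "ses")
        ms_swapped = compute_surface(s, "ms", swap_ses_ms=True)
        assert np.array_equal(ses.vertices, ms_swapped.vertices)

    @pytest.mark.parametrize("fixture_kind,params", [
        ("mini_helix", {"n": 8}),
        ("ligand_blob", {"extents": (6, 4, 3), "n": 8}),
    ])
    def test_voxelwise_nesting(self, fixture_kind, params):
        """VdW solid within SES/MS solid within SAS solid, voxelwise."""
        s = load_pdb(synth_pdb(FixtureSpec(fixture_kind, params, seed=3)))
        _, solids = surface_solids(s, probe_radius=1.4, target_resolution=3.0)
        assert not (solids["vdw"] & ~solids["ses"]).any()
        assert not (solids["vdw"] & ~solids["ms"]).any()
        assert not (solids["ses"] & ~solids["sas"]).any()
        assert not (solids["ms"] & ~solids["sas"]).any()

    def test_ses_ms_differ_by_at_most_one_voxel_shell(self):
        s = load_pdb(synth_pdb(FixtureSpec(
            "ligand_blob", {"extents": (6, 4, 3), "n": 8}, seed=3)))
        _, solids = surface_solids(s, probe_radius=1.4, target_resolution=3.0)
        diff = solids["ms"] ^ solids["ses"]
        # every differing voxel sits on the outer shell of the MS solid
        interior = binary_erosion(solids["ms"],
                                  structure=np.ones((3, 3, 3), dtype=bool))
        assert not (diff & interior).any()

    def test_grid_cap_never_exceeded_by_default(self):
        s = load_pdb(synth_pdb(FixtureSpec("sphere_cluster", {
            "centers": [(0, 0, 0), (120, 80, 0), (0, 0, 150)]})))
        grid, _ = surface_solids(s)
        assert all(d <= 180 for d in grid.dims)


class TestSmoothing:
    def test_zero_iterations_identity(self, single_atom):
        mesh = compute_surface(single_atom(2.0), "vdw")
        out = smooth_mesh(mesh, 0)
        assert out is mesh

    def test_two_iterations_area_stable(self, single_atom):
        mesh = compute_surface(single_atom(2.0), "vdw")
        area0, _ = mesh_area_volume(mesh)
        smoothed = smooth_mesh(mesh, 2)
        area1, _ = mesh_area_volume(smoothed)
        assert abs(area1 - area0) / area0 < 0.05
        assert np.array_equal(smoothed.triangles, mesh.triangles)

    def test_planar_patch_is_fixed_point(self):
        # regular grid patch in the z=0 plane; interior vertex is harmonic
        xs, ys = np.meshgrid(np.arange(3.0), np.arange(3.0), indexing="ij")
        verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(9)])
        tris = []
        for i in range(2):
            for j in range(2):
                a = i * 3 + j
                tris += [(a, a + 1, a + 3), (a + 1, a + 4, a + 3)]
        mesh = TriangleMesh(vertices=verts,
                            triangles=np.array(tris, dtype=np.int64))
        out = smooth_mesh(mesh, 1)
        assert np.linalg.norm(out.vertices[4] - verts[4]) < 1e-6


class TestAreaVolume:
    def test_right_triangle(self):
        mesh = TriangleMesh(
            vertices=np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float),
            triangles=np.array([[0, 1, 2]]))
        area, _ = mesh_area_volume(mesh)
        assert area == pytest.approx(0.5)

    def test_unit_cube(self):
        corners = np.array([[x, y, z] for x in (0, 1) for y in (0, 1)
                            for z in (0, 1)], dtype=float)
        faces = np.array([
            [0, 1, 3], [0, 3, 2], [4, 6, 7], [4, 7, 5],
            [0, 4, 5], [0, 5, 1], [2, 3, 7], [2, 7, 6],
            [0, 2, 6], [0, 6, 4], [1, 5, 7], [1, 7, 3]])
        area, volume = mesh_area_volume(TriangleMesh(corners, faces))
        assert area == pytest.approx(6.0)
        assert volume == pytest.approx(1.0)

    def test_empty_mesh(self):
        mesh = TriangleMesh(vertices=np.zeros((0, 3)),
                            triangles=np.zeros((0, 3), dtype=np.int64))
        assert mesh_area_volume(mesh) == (0.0, 0.0)
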