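"""Layer-population selection, manifold extraction and density statistics."""

import numpy as np
import pytest

from purkinje3d.layer import (LayerParams, LayerSurface, extract_layer_surface,
                              local_density, select_layer_population, write_ply)


# --- select_layer_population -------------------------------------------------

def test_single_cube_keeps_everything(rng):
    pts = rng.uniform(10, 40, (20, 3))
    kept, mask = select_layer_population(pts, LayerParams(), (256, 256, 256))
    assert mask.all()
    np.testing.assert_array_equal(kept, pts)


def test_largest_cluster_survives_matching_exhaustive_oracle(rng):
    """30 cells spread over one block of cubes vs 3 cells in a far corner:
    the large component is kept, verified against a brute-force component
    search over filled cubes."""
    big = rng.uniform(0, 100, (30, 3))            # cubes (0..2)³ region
    small = rng.uniform(400, 450, (3, 3))         # far corner, gap > 1 cube
    pts = np.vstack([big, small])
    p = LayerParams()
    kept, mask = select_layer_population(pts, p, (500, 500, 500))
    assert mask[:30].all() and not mask[30:].any()

    # oracle: exhaustive BFS over filled 50-voxel cubes (26-neighbourhood)
    cubes = {tuple(c) for c in (pts // p.grid_spacing_vox).astype(int)}
    comps = []
    todo = set(cubes)
    while todo:
        start = todo.pop()
        comp, stack = {start}, [start]
        while stack:
            c = stack.pop()
            for dz in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        nb = (c[0] + dz, c[1] + dy, c[2] + dx)
                        if nb in todo:
                            todo.discard(nb)
                            comp.add(nb)
                            stack.append(nb)
        comps.append(comp)
    largest = max(comps, key=len)
    oracle_mask = np.array([tuple(c) in largest
                            for c in (pts // p.grid_spacing_vox).astype(int)])
    np.testing.assert_array_equal(mask, oracle_mask)


def test_equal_components_break_ties_deterministically():
    a = np.array([[10.0, 10.0, 10.0], [210.0, 210.0, 210.0]])
    p = LayerParams()
    kept1, m1 = select_layer_population(a, p, (256, 256, 256))
    kept2, m2 = select_layer_population(a.copy(), p, (256, 256, 256))
    np.testing.assert_array_equal(m1, m2)
    # smallest lexicographic cube index wins
    assert m1[0] and not m1[1]


def test_selection_is_idempotent_and_subset(rng):
    pts = np.vstack([rng.uniform(0, 100, (15, 3)), rng.uniform(400, 450, (2, 3))])
    p = LayerParams()
    kept, mask = select_layer_population(pts, p, (500, 500, 500))
    assert kept.shape[0] <= pts.shape[0]
    again, mask2 = select_layer_population(kept, p, (500, 500, 500))
    np.testing.assert_array_equal(again, kept)
    assert mask2.all()


def test_empty_input_returns_empty():
    kept, mask = select_layer_population(np.empty((0, 3)), LayerParams(), (64, 64, 64))
    assert kept.shape[0] == 0 and mask.size == 0


# --- extract_layer_surface ---------------------------------------------------

def _plane_lattice(z0, spacing, extent):
    ax = np.arange(spacing, extent - spacing, spacing, dtype=float)
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    return np.column_stack([np.full(yy.size, float(z0)), yy.ravel(), xx.ravel()])


def test_dense_plane_yields_two_offset_sheets():
    """A dense planar lattice of cells at z = z0 produces two parallel sheets
    at z0 ± zero_level; each within 10% of the 44-voxel offset."""
    shape = (220, 220, 220)
    p = LayerParams(smoothing_sigma_nodes=1.0)
    cells = _plane_lattice(110, 10, 220)
    voxel = 1.75
    surf = extract_layer_surface(cells, p, shape, voxel)
    dz = surf.vertices_um[:, 0] - 110 * voxel
    # ignore the rim where the two sheets connect at the grid boundary
    interior = (np.abs(surf.vertices_um[:, 1] - 110 * voxel) < 70 * voxel) \
        & (np.abs(surf.vertices_um[:, 2] - 110 * voxel) < 70 * voxel)
    up, down = dz[interior & (dz > 0)], dz[interior & (dz < 0)]
    assert up.size and down.size
    assert np.mean(up) == pytest.approx(44 * voxel, rel=0.10)
    assert np.mean(-down) == pytest.approx(44 * voxel, rel=0.10)


def test_single_centroid_yields_sphere_with_closed_form_area():
    shape = (256, 256, 256)
    p = LayerParams(smoothing_sigma_nodes=0.5)
    voxel = 1.75
    surf = extract_layer_surface(np.array([[128.0, 128.0, 128.0]]), p, shape, voxel)
    expected = 4 * np.pi * (44 * voxel) ** 2 / 1e6
    assert surf.area_mm2 == pytest.approx(expected, rel=0.15)
    radii = np.linalg.norm(surf.vertices_um - 128 * voxel, axis=1)
    assert np.median(radii) == pytest.approx(44 * voxel, rel=0.10)


def test_empty_input_raises():
    with pytest.raises(ValueError):
        extract_layer_surface(np.empty((0, 3)), LayerParams(), (64, 64, 64), 1.0)


def test_no_zero_crossing_raises():
    # every node is within the zero level of some cell -> no crossing
    cells = _plane_lattice(30, 5, 64)
    p = LayerParams(zero_level_vox=200.0)
    with pytest.raises(ValueError, match="zero crossing"):
        extract_layer_surface(cells, p, (64, 64, 64), 1.0)


def test_translation_equivariance_on_grid_multiples():
    from scipy.spatial import cKDTree
    p = LayerParams(smoothing_sigma_nodes=1.0)
    voxel = 1.0
    cells = _plane_lattice(100, 10, 200)
    base = extract_layer_surface(cells, p, (200, 220, 220), voxel)
    shift = p.dist_grid_spacing_vox  # one coarse-grid node
    shifted = extract_layer_surface(cells + [shift, 0, 0], p, (200 + shift, 220, 220), voxel)
    back = shifted.vertices_um - [shift * voxel, 0, 0]
    d, _ = cKDTree(base.vertices_um).query(back)
    # marching-cubes vertices are float32: ~1e-5 μm resolution at 100 μm
    assert d.max() < 1e-4


# --- local_density -----------------------------------------------------------

def _flat_surface(z_um, extent_um, step_um, voxel_len_um, zero_level_um):
    ax = np.arange(0.0, extent_um + step_um / 2, step_um)
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    n = ax.size
    verts = np.column_stack([np.full(yy.size, z_um), yy.ravel(), xx.ravel()])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces.append([a, a + 1, a + n])
            faces.append([a + 1, a + n + 1, a + n])
    tri = np.asarray(faces)
    area = extent_um ** 2 / 1e6
    return LayerSurface(verts, tri, area, voxel_len_um, zero_level_um)


def test_uniform_lattice_density_matches_brute_force_count():
    """Cells on an 80 μm lattice: true density 1/0.0064 ≈ 156 mm⁻²; the
    offset-corrected per-vertex estimate must match a brute-force count and
    recover the lattice density."""
    voxel = 1.75
    p = LayerParams(density_radius_um=100.0)
    offset_um = p.zero_level_vox * voxel  # 77 μm
    cells_um = _plane_lattice(0, 80, 2000)[:, [0, 1, 2]]
    cells_um[:, 0] = 0.0
    cells_vox = cells_um / voxel
    surf = _flat_surface(offset_um, 2000.0, 50.0, voxel, offset_um)
    surf = local_density(surf, cells_vox, p)
    # brute-force neighbour counting oracle at every vertex
    r_eff2 = p.density_radius_um ** 2 - offset_um ** 2
    for k in range(0, surf.n_vertices, 97):
        d = np.linalg.norm(cells_um - surf.vertices_um[k], axis=1)
        count = int((d <= p.density_radius_um).sum())
        assert surf.density_mm2[k] == pytest.approx(
            count / (np.pi * r_eff2 / 1e6), rel=1e-9)
    # away from the rim the estimate recovers the planted lattice density
    interior = np.all((surf.vertices_um[:, 1:] > 300)
                      & (surf.vertices_um[:, 1:] < 1700), axis=1)
    mean_interior = surf.density_mm2[interior].mean()
    assert mean_interior == pytest.approx(1.0 / 0.0064, rel=0.15)


def test_vertex_far_from_all_cells_has_zero_density():
    surf = _flat_surface(0.0, 200.0, 100.0, 1.0, 44.0)
    cells_vox = np.array([[0.0, 5000.0, 5000.0]])
    surf = local_density(surf, cells_vox, LayerParams())
    assert np.all(surf.density_mm2 == 0.0)


def test_density_scaling_law_quarter_on_doubled_coordinates(rng):
    """Doubling all coordinates and the radius leaves counts unchanged and
    divides densities by four."""
    voxel = 1.0
    cells = rng.uniform(100, 900, (50, 3)) / voxel
    p1 = LayerParams(density_radius_um=100.0)
    s1 = _flat_surface(500.0, 1000.0, 100.0, voxel, p1.zero_level_vox * voxel)
    s1 = local_density(s1, cells, p1)
    p2 = LayerParams(density_radius_um=200.0)
    s2 = _flat_surface(1000.0, 2000.0, 200.0, 2 * voxel,
                       p2.zero_level_vox * 2 * voxel)
    s2 = local_density(s2, cells, p2)  # voxel doubled -> same cells, μm doubled
    np.testing.assert_allclose(s2.density_mm2, s1.density_mm2 / 4.0, rtol=1e-9)


def test_summary_global_density_uses_half_area(rng):
    surf = _flat_surface(77.0, 1000.0, 100.0, 1.75, 77.0)
    cells = rng.uniform(0, 570, (40, 3))
    surf = local_density(surf, cells, LayerParams(), roi_volume_mm3=0.09)
    s = surf.summary
    assert s["n_cells"] == 40
    assert s["global_density_per_mm2"] == pytest.approx(40 / (surf.area_mm2 / 2))
    assert s["volumetric_density_per_mm3"] == pytest.approx(40 / 0.09)


# --- PLY output --------------------------------------------------------------

def test_ply_roundtrip_via_trimesh(tmp_path, rng):
    surf = _flat_surface(10.0, 100.0, 50.0, 1.0, 44.0)
    surf = local_density(surf, rng.uniform(0, 100, (5, 3)), LayerParams())
    path = write_ply(surf, tmp_path / "layer.ply")
    import trimesh
    mesh = trimesh.load(path, process=False)
    assert len(mesh.vertices) == surf.n_vertices
    assert len(mesh.faces) == len(surf.faces)
    # PLY stores (x, y, z); internal order is (z, y, x)
    np.testing.assert_allclose(np.asarray(mesh.vertices)[:, ::-1],
                               surf.vertices_um, rtol=1e-6)
    dens = mesh.metadata["_ply_raw"]["vertex"]["data"]["density_mm2"]
    np.testing.assert_allclose(np.asarray(dens).ravel(),
                               surf.density_mm2, rtol=1e-6)
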