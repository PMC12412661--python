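"""Volumes, meshes, coordinate maps, interpolation, gradients."""

import numpy as np
import pytest
import SimpleITK as sitk
import trimesh

from vesselforge import autodiff as ad
from vesselforge.mesh import TriangleMesh, read_mesh, write_mesh
from vesselforge.volume import (ScalarVolume, gradient_magnitude_volume,
                                read_volume, sample_trilinear,
                                trilinear_sample_tensor, write_volume)


@pytest.fixture
def rng():
    return np.random.default_rng(11)


# ----------------------------------------------------------------- volume I/O
@pytest.mark.parametrize("suffix", [".nii.gz", ".mha"])
def test_volume_round_trip(tmp_path, rng, suffix):
    vol = ScalarVolume(rng.random((16, 16, 16)), spacing=(1, 1, 2),
                       origin=(5, -3, 0.5))
    path = tmp_path / f"vol{suffix}"
    write_volume(vol, path)
    back = read_volume(path)
    np.testing.assert_array_equal(back.values, vol.values)
    np.testing.assert_allclose(back.spacing, (1, 1, 2))
    np.testing.assert_allclose(back.origin, (5, -3, 0.5))


def test_read_2d_image_raises(tmp_path):
    img = sitk.GetImageFromArray(np.zeros((8, 8), dtype=np.float32))
    path = tmp_path / "flat.mha"
    sitk.WriteImage(img, str(path))
    with pytest.raises(ValueError, match="3D"):
        read_volume(path)


def test_volume_invariants():
    with pytest.raises(ValueError):
        ScalarVolume(np.zeros((4, 4, 4)), spacing=(0, 1, 1))
    with pytest.raises(ValueError):
        ScalarVolume(np.full((4, 4, 4), np.nan))


# ----------------------------------------------------------- coordinate maps
def test_index_world_examples():
    vol = ScalarVolume(np.zeros((8, 8, 8)))
    np.testing.assert_allclose(vol.index_to_world((3, 4, 5)), (3, 4, 5))
    vol2 = ScalarVolume(np.zeros((8, 8, 8)), spacing=(2, 1, 1),
                        origin=(10, 0, 0))
    np.testing.assert_allclose(vol2.index_to_world((1, 0, 0)), (12, 0, 0))


def test_index_world_inverse_property(rng):
    vol = ScalarVolume(np.zeros((9, 7, 5)), spacing=rng.random(3) + 0.1,
                       origin=rng.standard_normal(3) * 10)
    pts = rng.random((100, 3)) * 6
    back = vol.world_to_index(vol.index_to_world(pts))
    assert np.max(np.abs(back - pts)) < 1e-9


# ------------------------------------------------------------------- sampling
def test_trilinear_constant_and_affine(rng):
    vol = ScalarVolume(np.full((6, 6, 6), 4.25))
    vals, frac = sample_trilinear(vol, rng.random((20, 3)) * 5)
    np.testing.assert_allclose(vals, 4.25)
    assert frac == 0.0

    ii, jj, kk = np.meshgrid(*[np.arange(6)] * 3, indexing="ij")
    affine = ScalarVolume(2 * ii + 3 * jj - kk)
    pts = rng.random((50, 3)) * 5
    vals, _ = sample_trilinear(affine, pts)
    np.testing.assert_allclose(vals, 2 * pts[:, 0] + 3 * pts[:, 1] - pts[:, 2],
                               atol=1e-10)


def test_trilinear_matches_corner_sum_oracle(rng):
    vol = ScalarVolume(rng.random((7, 6, 5)), spacing=(1.5, 1.0, 0.5),
                       origin=(-2, 1, 0))
    pts = np.column_stack([
        rng.random(100) * 6 * 1.5 - 2,
        rng.random(100) * 5 + 1,
        rng.random(100) * 4 * 0.5,
    ])
    vals, _ = sample_trilinear(vol, pts)
    # brute-force 8-corner convex combination
    idx = vol.world_to_index(pts)
    for n in range(100):
        i0 = np.minimum(np.floor(idx[n]).astype(int), np.array(vol.shape) - 2)
        t = idx[n] - i0
        acc = 0.0
        for di in (0, 1):
            for dj in (0, 1):
                for dk in (0, 1):
                    w = ((t[0] if di else 1 - t[0])
                         * (t[1] if dj else 1 - t[1])
                         * (t[2] if dk else 1 - t[2]))
                    acc += w * vol.values[i0[0] + di, i0[1] + dj, i0[2] + dk]
        assert vals[n] == pytest.approx(acc, abs=1e-12)


def test_trilinear_out_of_bounds_clamped():
    vol = ScalarVolume(np.arange(27, dtype=float).reshape(3, 3, 3))
    vals, frac = sample_trilinear(vol, [[-5, 0, 0], [1, 1, 1]])
    assert frac == pytest.approx(0.5)
    assert vals[0] == vol.values[0, 0, 0]


def test_trilinear_tensor_point_gradients(rng):
    vol = ScalarVolume(rng.random((8, 8, 8)), spacing=(1.0, 0.8, 1.2))
    pts0 = rng.random((5, 3)) * 5 + 0.5
    pts = ad.Tensor(pts0.copy(), requires_grad=True)
    out = trilinear_sample_tensor(vol, pts).sum()
    out.backward()
    ana = pts.grad.copy()
    eps = 1e-6
    for n in range(5):
        for c in range(3):
            for s, sign in ((eps, 1), (-eps, -1)):
                pass
            p_hi = pts0.copy(); p_hi[n, c] += eps
            p_lo = pts0.copy(); p_lo[n, c] -= eps
            hi, _ = sample_trilinear(vol, p_hi)
            lo, _ = sample_trilinear(vol, p_lo)
            num = (hi.sum() - lo.sum()) / (2 * eps)
            assert ana[n, c] == pytest.approx(num, abs=1e-6)


# ------------------------------------------------------------------ gradients
def test_gradient_magnitude_constant_and_ramp():
    const = ScalarVolume(np.full((8, 8, 8), 3.0))
    np.testing.assert_allclose(gradient_magnitude_volume(const).values, 0.0)

    ii = np.meshgrid(*[np.arange(10)] * 3, indexing="ij")[0]
    a = 2.5  # intensity per mm with spacing 0.5 -> 5.0 per index
    ramp = ScalarVolume(a * ii * 0.5, spacing=(0.5, 1, 1))
    mag = gradient_magnitude_volume(ramp).values
    np.testing.assert_allclose(mag[1:-1], a, atol=1e-10)


def test_gradient_magnitude_matches_loop_oracle(rng):
    vol = ScalarVolume(rng.random((6, 5, 7)), spacing=(1.0, 2.0, 0.5))
    mag = gradient_magnitude_volume(vol).values
    v, sp = vol.values, vol.spacing
    for i in range(1, 5):
        for j in range(1, 4):
            for k in range(1, 6):
                gx = (v[i + 1, j, k] - v[i - 1, j, k]) / (2 * sp[0])
                gy = (v[i, j + 1, k] - v[i, j - 1, k]) / (2 * sp[1])
                gz = (v[i, j, k + 1] - v[i, j, k - 1]) / (2 * sp[2])
                assert mag[i, j, k] == pytest.approx(
                    np.sqrt(gx**2 + gy**2 + gz**2), abs=1e-10)


# --------------------------------------------------------------------- meshes
@pytest.mark.parametrize("suffix", [".stl", ".ply", ".vtp"])
def test_mesh_round_trip_cube(tmp_path, suffix):
    box = trimesh.creation.box()
    mesh = TriangleMesh(np.asarray(box.vertices), np.asarray(box.faces))
    path = tmp_path / f"cube{suffix}"
    write_mesh(mesh, path)
    back = read_mesh(path)
    assert back.n_vertices == 8
    assert back.n_faces == 12
    assert back.is_watertight


def test_empty_mesh_raises(tmp_path):
    with pytest.raises(ValueError):
        write_mesh(TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3))),
                   tmp_path / "x.stl")


def test_vtp_quads_are_triangulated(tmp_path):
    path = tmp_path / "quad.vtp"
    path.write_text(
        '<?xml version="1.0"?>\n'
        '<VTKFile type="PolyData"><PolyData>'
        '<Piece NumberOfPoints="4" NumberOfPolys="1">'
        '<Points><DataArray NumberOfComponents="3" format="ascii">'
        '0 0 0 1 0 0 1 1 0 0 1 0</DataArray></Points>'
        '<Polys><DataArray Name="connectivity" format="ascii">0 1 2 3</DataArray>'
        '<DataArray Name="offsets" format="ascii">4</DataArray></Polys>'
        '</Piece></PolyData></VTKFile>')
    mesh = read_mesh(path, triangulate=True)
    assert mesh.n_faces == 2
    with pytest.raises(ValueError):
        read_mesh(path, triangulate=False)


def test_boundary_loops_cylinder_and_sphere():
    cyl = trimesh.creation.cylinder(radius=4, height=10, sections=24)
    # remove the two cap fans to open the tube
    tm = TriangleMesh(np.asarray(cyl.vertices), np.asarray(cyl.faces))
    normals = tm.face_normals()
    side = np.abs(normals[:, 2]) < 0.99
    open_tube = TriangleMesh(tm.vertices, tm.faces[side])
    loops = open_tube.find_boundary_loops()
    assert len(loops) == 2

    ico = trimesh.creation.icosphere(subdivisions=2)
    sphere = TriangleMesh(np.asarray(ico.vertices), np.asarray(ico.faces))
    assert sphere.find_boundary_loops() == []
    assert sphere.euler_characteristic() == 2


def test_fill_caps_closes_open_tube():
    cyl = trimesh.creation.cylinder(radius=3, height=8, sections=16)
    tm = TriangleMesh(np.asarray(cyl.vertices), np.asarray(cyl.faces))
    side = np.abs(tm.face_normals()[:, 2]) < 0.99
    open_tube = TriangleMesh(tm.vertices, tm.faces[side])
    open_tube.boundary_loops = open_tube.find_boundary_loops()
    closed = open_tube.fill_caps()
    assert closed.is_watertight
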