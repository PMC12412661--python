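"""LDDMM kernels, Hamiltonian shooting, scaling gate, and mesh losses."""

import numpy as np
import pytest
import trimesh

import vesselforge.autodiff as ad
from vesselforge.mesh import TriangleMesh
from vesselforge.deform import (Cap, ControlPointSystem, MomentumPredictor,
                                apply_gate, compute_scaling_field,
                                detect_caps, edge_loss, gaussian_kernel,
                                hamiltonian, hamiltonian_rhs, integrate_flow,
                                laplacian_loss, mesh_laplacian,
                                misalignment_energy, normal_loss,
                                subsample_control_points, total_loss,
                                velocity_field)
from vesselforge.deform.lddmm import coverage_radius, shoot
from vesselforge.deform.losses import MeshTopology
from vesselforge.volume import ScalarVolume


@pytest.fixture
def rng():
    return np.random.default_rng(17)


def sphere_mesh(radius=10.0, center=(0, 0, 0), subdivisions=3):
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(ico.vertices) + center,
                        np.asarray(ico.faces))


def open_cylinder(radius=5.0, height=20.0, sections=24, rings=None):
    """Open tube along z with vertex rings spaced ~1 unit apart."""
    rings = rings or max(3, int(height))
    zs = np.linspace(-height / 2, height / 2, rings)
    theta = np.linspace(0, 2 * np.pi, sections, endpoint=False)
    verts = np.array([[radius * np.cos(t), radius * np.sin(t), z]
                      for z in zs for t in theta])
    faces = []
    for j in range(rings - 1):
        for i in range(sections):
            a = j * sections + i
            b = j * sections + (i + 1) % sections
            c = a + sections
            d = b + sections
            faces += [[a, b, c], [b, d, c]]
    out = TriangleMesh(verts, np.array(faces))
    out.boundary_loops = out.find_boundary_loops()
    return out


# ------------------------------------------------------------------- kernel
def test_gaussian_kernel_values(rng):
    assert gaussian_kernel([1, 2, 3], [1, 2, 3], 2.0) == 1.0
    x = np.zeros(3)
    y = np.array([3.0, 0, 0])
    assert gaussian_kernel(x, y, 3.0) == pytest.approx(np.exp(-1), abs=1e-12)
    for _ in range(10):
        a, b = rng.normal(size=(2, 3))
        s = rng.uniform(0.5, 3)
        assert gaussian_kernel(a, b, s) == pytest.approx(
            gaussian_kernel(b, a, s))


# ----------------------------------------------------------- control points
def test_subsample_extremes_and_coverage(rng):
    mesh = sphere_mesh(subdivisions=2)  # 162 vertices
    assert len(subsample_control_points(mesh, mesh.n_vertices)) == \
        mesh.n_vertices
    assert len(subsample_control_points(mesh, 1)) == 1
    with pytest.raises(ValueError):
        subsample_control_points(mesh, mesh.n_vertices + 1)

    big = sphere_mesh(subdivisions=3)  # 642 vertices
    fps = coverage_radius(big, subsample_control_points(big, 40, seed=0))
    best_random = min(
        coverage_radius(big, np.random.default_rng(s).choice(
            big.n_vertices, 40, replace=False)) for s in range(20))
    assert fps <= 2.0 * best_random


# ------------------------------------------------------------ velocity field
def test_velocity_single_control_point():
    cps = ControlPointSystem(points=[[0, 0, 0]], momenta=[[1.0, -2.0, 0.5]],
                             kernel_width=2.0)
    v = velocity_field([[0, 0, 0]], cps)
    np.testing.assert_allclose(v[0], [1.0, -2.0, 0.5])
    v = velocity_field([[2.0, 0, 0]], cps)  # distance sigma -> e^-1
    np.testing.assert_allclose(v[0], np.exp(-1) * np.array([1.0, -2.0, 0.5]),
                               atol=1e-12)


def test_velocity_linear_in_momenta(rng):
    pts = rng.normal(size=(5, 3))
    q = rng.normal(size=(7, 3))
    m1, m2 = rng.normal(size=(2, 5, 3))
    mk = lambda m: ControlPointSystem(pts, m, kernel_width=1.5)
    v = velocity_field(q, mk(m1 + m2))
    np.testing.assert_allclose(
        v, velocity_field(q, mk(m1)) + velocity_field(q, mk(m2)), atol=1e-12)


# -------------------------------------------------------------- Hamiltonian
def test_rhs_rest_state_and_lone_point(rng):
    cps = ControlPointSystem(points=rng.normal(size=(4, 3)),
                             momenta=np.zeros((4, 3)), kernel_width=1.0)
    ds, dxi = hamiltonian_rhs(cps)
    np.testing.assert_allclose(ds, 0)
    np.testing.assert_allclose(dxi, 0)

    lone = ControlPointSystem(points=[[1, 1, 1]], momenta=[[0.3, 0, -0.1]],
                              kernel_width=1.0)
    ds, dxi = hamiltonian_rhs(lone)
    np.testing.assert_allclose(ds, [[0.3, 0, -0.1]])
    np.testing.assert_allclose(dxi, 0, atol=1e-15)


def test_rhs_matches_finite_difference_of_hamiltonian(rng):
    """dxi/dt = -dH/ds, checked by central differences on random systems."""
    pts = rng.normal(size=(5, 3)) * 2
    mom = rng.normal(size=(5, 3)) * 0.5
    sigma = 1.3
    cps = ControlPointSystem(pts, mom, kernel_width=sigma)
    _, dxi = hamiltonian_rhs(cps)
    eps = 1e-6
    for i in range(5):
        for c in range(3):
            hi = pts.copy(); hi[i, c] += eps
            lo = pts.copy(); lo[i, c] -= eps
            num = (hamiltonian(hi, mom, sigma)
                   - hamiltonian(lo, mom, sigma)) / (2 * eps)
            assert dxi[i, c] == pytest.approx(-num, abs=1e-5)


# --------------------------------------------------------------- integration
def test_zero_momentum_identity():
    mesh = sphere_mesh()
    cps = ControlPointSystem(points=mesh.vertices[:50],
                             momenta=np.zeros((50, 3)), kernel_width=3.0)
    out, _, _ = integrate_flow(mesh, cps)
    assert np.max(np.abs(out.vertices - mesh.vertices)) == 0.0


def test_hamiltonian_drift_within_one_percent(rng):
    pts = rng.normal(size=(30, 3)) * 5
    sigma = 3.0
    mom = rng.normal(size=(30, 3))
    mom *= 2 * sigma / np.abs(velocity_field(
        pts, ControlPointSystem(pts, mom, sigma))).max()
    h0 = hamiltonian(pts, mom, sigma)
    s15, x15 = shoot(ControlPointSystem(pts, mom, sigma, steps=15))
    s150, x150 = shoot(ControlPointSystem(pts, mom, sigma, steps=150))
    h15 = hamiltonian(s15, x15, sigma)
    h150 = hamiltonian(s150, x150, sigma)
    assert abs(h15 - h0) / abs(h0) <= 0.01
    assert abs(h15 - h150) / abs(h150) <= 0.01


def test_wide_kernel_limit_is_rigid_translation(rng):
    mesh = sphere_mesh(radius=5.0)
    idx = subsample_control_points(mesh, 20, seed=0)
    sigma = 100.0 * 10.0  # 100x mesh diameter
    xi_bar = np.array([0.004, -0.002, 0.001])
    mom = np.tile(xi_bar, (20, 1))
    cps = ControlPointSystem(mesh.vertices[idx], mom, kernel_width=sigma)
    out, _, _ = integrate_flow(mesh, cps)
    expected = 20 * xi_bar * 1.0
    disp = out.vertices - mesh.vertices
    err = np.linalg.norm(disp - expected, axis=1).max()
    assert err <= 0.01 * np.linalg.norm(expected)


def test_no_face_inversions_in_momentum_regime(rng):
    """No triangle flips during the flow (checked step to step, since a
    large smooth rotation may legitimately reverse a normal vs. t=0)."""
    mesh = sphere_mesh(radius=10.0, subdivisions=3)  # 642 verts, 1280 faces
    idx = subsample_control_points(mesh, 80, seed=1)
    sigma = 5.0
    mom = rng.normal(size=(80, 3))
    cps = ControlPointSystem(mesh.vertices[idx], mom, kernel_width=sigma)
    vmax = np.abs(velocity_field(mesh.vertices, cps)).max()
    mom *= 2 * sigma / vmax   # max displacement ~ 2 sigma_K
    cps = ControlPointSystem(mesh.vertices[idx], mom, kernel_width=sigma)
    _, _, traj = integrate_flow(mesh, cps, record_trajectory=True)
    prev = None
    for verts in traj:
        n = TriangleMesh(verts, mesh.faces).face_normals()
        if prev is not None:
            assert np.all(np.einsum("ij,ij->i", prev, n) > 0)
        prev = n


# --------------------------------------------------------------- scaling gate
def test_detect_caps_counts_and_radius():
    cyl = open_cylinder(radius=5.0)
    caps = detect_caps(cyl)
    assert len(caps) == 2
    for cap in caps:
        assert cap.geodesic_radius == pytest.approx(5.0, abs=0.5)
    assert detect_caps(sphere_mesh()) == []


def test_scaling_field_three_regimes():
    cyl = open_cylinder(radius=4.0, height=40.0, sections=32)
    gate = compute_scaling_field(cyl, buffer_sigma=2.0)
    caps = gate.caps
    assert np.all(gate.alpha[[c for cap in caps for c in cap.loop]] == 0)
    mid = np.abs(cyl.vertices[:, 2]) < 2.0  # far from both caps
    assert np.all(gate.alpha[mid] == 1.0)
    assert gate.alpha.min() >= 0 and gate.alpha.max() <= 1


def test_scaling_field_half_value_at_analytic_distance():
    # alpha = 0.5 when (d - r) = sigma * sqrt(2 ln 2)
    r, sg = 3.0, 1.5
    d = r + sg * np.sqrt(2 * np.log(2))
    alpha = 1 - np.exp(-(d - r) ** 2 / (2 * sg ** 2))
    assert alpha == pytest.approx(0.5, abs=1e-12)


def test_closed_mesh_gate_warns_all_ones():
    with pytest.warns(UserWarning, match="no open caps"):
        gate = compute_scaling_field(sphere_mesh())
    assert np.all(gate.alpha == 1.0)


def test_gate_identity_and_frozen(rng):
    mom = rng.normal(size=(10, 3))
    np.testing.assert_array_equal(apply_gate(mom, np.ones(10)), mom)
    np.testing.assert_array_equal(apply_gate(mom, np.zeros(10)), 0 * mom)


def test_gated_flow_pins_cap_vertices(rng):
    cyl = open_cylinder(radius=4.0, height=30.0, sections=24)
    gate = compute_scaling_field(cyl, buffer_sigma=2.0)
    idx = subsample_control_points(cyl, 60, seed=2)
    mom = rng.normal(size=(60, 3)) * 0.5
    mom = apply_gate(mom, gate.alpha[idx])
    cps = ControlPointSystem(cyl.vertices[idx], mom, kernel_width=4.0)
    out, _, _ = integrate_flow(cyl, cps, vertex_alpha=gate.alpha)
    disp = np.linalg.norm(out.vertices - cyl.vertices, axis=1)
    cap_verts = [v for cap in gate.caps for v in cap.loop]
    assert np.max(disp[cap_verts]) == 0.0
    assert disp.max() > 0.1  # the wall did move


# -------------------------------------------------------------- mesh losses
def test_normal_loss_planar_and_right_angle():
    flat = TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]],
                        [[0, 1, 2], [1, 3, 2]])
    assert normal_loss(flat) == pytest.approx(0.0, abs=1e-12)
    # two faces meeting at a 90-degree dihedral along the shared edge AB
    bent = TriangleMesh([[0, 0, 0], [1, 0, 0], [0.5, 1, 0], [0.5, 0, 1]],
                        [[0, 1, 2], [0, 3, 1]])
    n = bent.face_normals()
    assert abs(np.dot(n[0], n[1])) == pytest.approx(0.0, abs=1e-12)
    assert normal_loss(bent) == pytest.approx(1.0, abs=1e-12)


def test_edge_loss_two_edge_example():
    lengths = np.array([1.0, 3.0])
    assert np.mean((lengths - lengths.mean()) ** 2) == 1.0
    # realized on a mesh: isoceles with edges 1, 3 and hypotenuse-ish third
    mesh = TriangleMesh([[0, 0, 0], [1, 0, 0], [1, 3, 0]],
                        [[0, 1, 2]])
    le = np.sort(mesh.edge_lengths())
    expected = np.mean((le - le.mean()) ** 2)
    assert edge_loss(mesh) == pytest.approx(expected, abs=1e-12)


def _triangular_lattice(nx=6, ny=6):
    verts, faces = [], []
    for j in range(ny):
        for i in range(nx):
            verts.append([i + 0.5 * (j % 2), j * np.sqrt(3) / 2, 0.0])
    at = lambda i, j: j * nx + i
    for j in range(ny - 1):
        for i in range(nx - 1):
            if j % 2 == 0:
                faces += [[at(i, j), at(i + 1, j), at(i, j + 1)],
                          [at(i + 1, j), at(i + 1, j + 1), at(i, j + 1)]]
            else:
                faces += [[at(i, j), at(i + 1, j), at(i + 1, j + 1)],
                          [at(i, j), at(i + 1, j + 1), at(i, j + 1)]]
    return TriangleMesh(np.array(verts), np.array(faces))


def test_laplacian_loss_lattice_and_single_displacement():
    lattice = _triangular_lattice()
    assert laplacian_loss(lattice) == pytest.approx(0.0, abs=1e-20)
    mesh = lattice.copy()
    topo = MeshTopology(mesh)
    vi = topo.included[len(topo.included) // 2]
    d = 0.37
    mesh.vertices[vi, 2] += d
    # the displaced vertex contributes d^2; its neighbors' centroids also
    # shift by d/deg each
    deg = np.asarray((topo.neighbor_mean[vi] != 0).sum())
    expected_terms = [d ** 2]
    for j in topo.included:
        if j != vi and topo.neighbor_mean[j, vi] != 0:
            expected_terms.append((d * topo.neighbor_mean[j, vi]) ** 2)
    assert laplacian_loss(mesh) == pytest.approx(
        np.sum(expected_terms) / len(topo.included), rel=1e-9)


@pytest.mark.parametrize("loss_fn", [normal_loss, edge_loss, laplacian_loss])
def test_losses_match_brute_force_loops(rng, loss_fn):
    mesh = sphere_mesh(radius=4.0, subdivisions=2)
    mesh.vertices += rng.normal(0, 0.1, mesh.vertices.shape)
    val = loss_fn(mesh)
    if loss_fn is normal_loss:
        inc = mesh.edge_face_incidence()
        n = mesh.face_normals()
        terms = [1 - np.dot(n[fs[0]], n[fs[1]])
                 for fs in inc.values() if len(fs) == 2]
        expected = np.mean(terms)
    elif loss_fn is edge_loss:
        seen = set()
        lengths = []
        for f in mesh.faces:
            for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                key = (min(a, b), max(a, b))
                if key not in seen:
                    seen.add(key)
                    lengths.append(np.linalg.norm(
                        mesh.vertices[a] - mesh.vertices[b]))
        lbar = np.mean(lengths)
        expected = np.mean([(l - lbar) ** 2 for l in lengths])
    else:
        nbrs = {}
        for f in mesh.faces:
            for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                nbrs.setdefault(a, set()).add(b)
                nbrs.setdefault(b, set()).add(a)
        terms = []
        for i in range(mesh.n_vertices):
            centroid = np.mean([mesh.vertices[j] for j in nbrs[i]], axis=0)
            terms.append(np.sum((mesh.vertices[i] - centroid) ** 2))
        expected = np.mean(terms)
    assert val == pytest.approx(expected, rel=1e-10)


# ------------------------------------------------------- misalignment energy
def test_misalignment_closed_forms(rng):
    g = 3.7
    vol = ScalarVolume(np.full((8, 8, 8), g))
    pts = rng.random((25, 3)) * 6 + 0.5
    w1 = 1.4
    e = misalignment_energy(pts, vol, w1=w1, eps=0.0)
    assert e == pytest.approx(-w1 * np.log(25 * g), abs=1e-9)
    vol2 = ScalarVolume(np.full((8, 8, 8), 2 * g))
    e2 = misalignment_energy(pts, vol2, w1=w1, eps=0.0)
    assert e2 - e == pytest.approx(-w1 * np.log(2), abs=1e-9)


def test_misalignment_matches_sample_sum_oracle(rng):
    from vesselforge.volume import sample_trilinear
    vol = ScalarVolume(rng.random((10, 10, 10)) + 0.5)
    pts = rng.random((40, 3)) * 8 + 0.5
    vals, _ = sample_trilinear(vol, pts)
    expected = -2.0 * np.log(vals.sum() + 1e-8)
    assert misalignment_energy(pts, vol, w1=2.0) == pytest.approx(
        expected, abs=1e-10)


def test_total_loss_composition(rng):
    mesh = sphere_mesh(radius=3.0, center=(5, 5, 5), subdivisions=2)
    vol = ScalarVolume(rng.random((12, 12, 12)) + 0.2)
    total, comps = total_loss(mesh, vol, weights=(1.0, 0.2, 0.01, 0.1))
    manual = (misalignment_energy(mesh.vertices, vol, 1.0)
              + 0.2 * normal_loss(mesh) + 0.01 * edge_loss(mesh)
              + 0.1 * laplacian_loss(mesh))
    assert total == pytest.approx(manual, rel=1e-9)
    zero, _ = total_loss(mesh, vol, weights=(0, 0, 0, 0))
    assert zero == 0.0


# --------------------------------------------------------- momentum predictor
def test_predictor_zero_head_permutation_and_determinism(rng):
    mesh = sphere_mesh(subdivisions=2)
    L = mesh_laplacian(mesh)
    pred = MomentumPredictor(hidden=16, order=3, seed=4)
    out = pred(mesh.vertices, L)
    np.testing.assert_allclose(out.data, 0.0)  # zero-initialized head
    # give the head weights and test permutation equivariance
    rng2 = np.random.default_rng(9)
    for w in pred.out.weights:
        w.data = rng2.standard_normal(w.shape) * 0.1
    base = pred(mesh.vertices, L).data
    perm = rng.permutation(mesh.n_vertices)
    inv = np.argsort(perm)
    pmesh = TriangleMesh(mesh.vertices[perm], inv[mesh.faces])
    pout = pred(pmesh.vertices, mesh_laplacian(pmesh)).data
    np.testing.assert_allclose(pout, base[perm], atol=1e-10)
    np.testing.assert_array_equal(base, pred(mesh.vertices, L).data)
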