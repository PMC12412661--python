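"""Image-alignment energy and mesh regularizers.

All four terms exist in two forms: a plain-float API operating on a
TriangleMesh (used by metrics/reporting and the mesh smoother's tests) and
a Tensor form on vertex positions (used inside the optimization loops).

* misalignment energy:  -w1 * log( sum_i G(s_i) + eps ), G = image gradient
  magnitude sampled trilinearly at the surface points — minimizing it pulls
  the surface onto intensity boundaries;
* normal loss: mean over interior edges of (1 - n1.n2), penalizing creases;
* edge loss: variance of edge lengths about their mean, penalizing sliver
  triangles;
* Laplacian loss: mean squared offset of each vertex from its neighbor
  centroid (boundary-loop vertices excluded — their neighbor centroid is
  biased inward).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .. import autodiff as ad
from ..mesh import TriangleMesh
from ..volume import ScalarVolume, trilinear_sample_tensor

__all__ = ["normal_loss", "edge_loss", "laplacian_loss",
           "misalignment_energy", "total_loss", "MeshTopology"]


def _cross(a: ad.Tensor, b: ad.Tensor) -> ad.Tensor:
    cols = []
    for i, j in ((1, 2), (2, 0), (0, 1)):
        cols.append((a[:, i] * b[:, j] - a[:, j] * b[:, i]).reshape(-1, 1))
    return ad.concatenate(cols, axis=1)


class MeshTopology:
    """Fixed connectivity needed by the Tensor losses (faces never change)."""

    def __init__(self, mesh: TriangleMesh):
        self.faces = mesh.faces.copy()
        self.edges = mesh.edges_unique()
        ie, pairs = mesh.interior_edges()
        if len(ie) == 0:
            raise ValueError("mesh has no interior edges")
        self.face_pairs = pairs
        boundary = set()
        for loop in (mesh.boundary_loops or mesh.find_boundary_loops()):
            boundary.update(loop)
        # uniform adjacency-average operator over included vertices
        nv = mesh.n_vertices
        rows, cols = [], []
        for a, b in self.edges:
            rows += [a, b]
            cols += [b, a]
        A = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(nv, nv))
        deg = np.asarray(A.sum(axis=1)).ravel()
        if np.any(deg == 0):
            raise ValueError("mesh has isolated vertices")
        self.neighbor_mean = sp.diags(1.0 / deg) @ A
        # boundary-loop vertices excluded: their neighbor centroid is biased
        # inward.  May be empty (all-boundary meshes); the Laplacian term
        # rejects that case at evaluation time.
        self.included = np.array(sorted(set(range(nv)) - boundary), dtype=int)


# ----------------------------------------------------------- tensor versions
def face_normals_t(verts: ad.Tensor, faces: np.ndarray,
                   eps: float = 1e-30) -> ad.Tensor:
    v0, v1, v2 = (verts[faces[:, i]] for i in range(3))
    n = _cross(v1 - v0, v2 - v0)
    norm = ((n * n).sum(axis=1, keepdims=True) + eps).sqrt()
    return n / norm


def normal_loss_t(verts: ad.Tensor, topo: MeshTopology) -> ad.Tensor:
    n = face_normals_t(verts, topo.faces)
    n1 = n[topo.face_pairs[:, 0]]
    n2 = n[topo.face_pairs[:, 1]]
    return (1.0 - (n1 * n2).sum(axis=1)).mean()


def edge_loss_t(verts: ad.Tensor, topo: MeshTopology) -> ad.Tensor:
    d = verts[topo.edges[:, 0]] - verts[topo.edges[:, 1]]
    lengths = ((d * d).sum(axis=1) + 1e-30).sqrt()
    mean = lengths.mean()
    dev = lengths - mean
    return (dev * dev).mean()


def laplacian_loss_t(verts: ad.Tensor, topo: MeshTopology) -> ad.Tensor:
    if len(topo.included) == 0:
        raise ValueError("no interior vertices for the Laplacian loss")
    centroid = ad.spmm(topo.neighbor_mean, verts)
    diff = (verts - centroid)[topo.included]
    return (diff * diff).sum(axis=1).mean()


def misalignment_energy_t(points: ad.Tensor, gradmag: ScalarVolume,
                          w1: float = 1.0, eps: float = 1e-8) -> ad.Tensor:
    g = trilinear_sample_tensor(gradmag, points)
    return -(w1 * (g.sum() + eps).log())


def total_loss_t(verts: ad.Tensor, topo: MeshTopology, gradmag: ScalarVolume,
                 weights=(1.0, 0.2, 0.01, 0.1), eps: float = 1e-8):
    """Weighted sum; returns (loss tensor, float components dict)."""
    w1, w2, w3, w4 = weights
    comps = {}
    loss = None

    def acc(term, name):
        nonlocal loss
        comps[name] = float(term.data)
        loss = term if loss is None else loss + term

    if w1 != 0:
        acc(misalignment_energy_t(verts, gradmag, w1, eps), "energy")
    else:
        comps["energy"] = 0.0
    for w, fn, name in ((w2, normal_loss_t, "normal"),
                        (w3, edge_loss_t, "edge"),
                        (w4, laplacian_loss_t, "laplacian")):
        if w != 0:
            acc(fn(verts, topo) * w, name)
        else:
            comps[name] = 0.0
    if loss is None:
        loss = ad.Tensor(np.zeros(()))
    comps["total"] = float(loss.data)
    return loss, comps


# ------------------------------------------------------------ float wrappers
def normal_loss(mesh: TriangleMesh) -> float:
    """Mean (1 - cos dihedral) over interior edges."""
    topo = MeshTopology(mesh)
    with ad.no_grad():
        return float(normal_loss_t(ad.Tensor(mesh.vertices), topo).data)


def edge_loss(mesh: TriangleMesh) -> float:
    """Mean squared deviation of edge lengths from their mean."""
    lengths = mesh.edge_lengths()
    if len(lengths) == 0:
        raise ValueError("mesh has no edges")
    return float(np.mean((lengths - lengths.mean()) ** 2))


def laplacian_loss(mesh: TriangleMesh) -> float:
    """Mean squared vertex offset from the neighbor centroid (interior only)."""
    topo = MeshTopology(mesh)
    with ad.no_grad():
        return float(laplacian_loss_t(ad.Tensor(mesh.vertices), topo).data)


def misalignment_energy(points: np.ndarray, gradmag: ScalarVolume,
                        w1: float = 1.0, eps: float = 1e-8) -> float:
    with ad.no_grad():
        return float(misalignment_energy_t(
            ad.Tensor(np.atleast_2d(points)), gradmag, w1, eps).data)


def total_loss(mesh: TriangleMesh, gradmag: ScalarVolume,
               weights=(1.0, 0.2, 0.01, 0.1), eps: float = 1e-8):
    """Weighted total with per-term components (floats)."""
    topo = MeshTopology(mesh)
    with ad.no_grad():
        _, comps = total_loss_t(ad.Tensor(mesh.vertices), topo, gradmag,
                                weights, eps)
    return comps["total"], comps
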