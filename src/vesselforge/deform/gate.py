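"""Scaling gate: freeze the open inlet/outlet caps during deformation.

Image gradients constrain the vessel wall but not the artificial planes
where the vessel was truncated; unconstrained, cap control points drift to
wherever the energy is locally lower and the inlets retract.  The gate is
a scalar mobility field alpha on the surface:

    alpha = 0                                   d <  r_i          (frozen cap)
    alpha = 1 - exp(-(d - r_i)^2 / (2 sigma^2)) r_i <= d < r_i + 3 sigma
    alpha = 1                                   d >= r_i + 3 sigma

with d the on-surface (graph-geodesic) distance to the cap center and r_i
the cap's geodesic radius.  Alpha multiplies both the control-point momenta
and the advected vertex velocities, so frozen points do not move at all and
the flow remains a smooth diffeomorphism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

from ..mesh import TriangleMesh

__all__ = ["Cap", "ScalingGateField", "detect_caps", "compute_scaling_field",
           "apply_gate"]


@dataclass
class Cap:
    center: np.ndarray        # world mm (mean of the boundary loop)
    center_vertex: int        # nearest mesh vertex to the center
    geodesic_radius: float    # mm, center -> farthest loop vertex on-surface
    loop: list                # ordered boundary vertex cycle


@dataclass
class ScalingGateField:
    caps: list
    buffer_sigma: np.ndarray  # per-cap sigma_g (mm)
    alpha: np.ndarray         # per-vertex mobility in [0, 1]

    def __post_init__(self):
        if np.any(self.alpha < 0) or np.any(self.alpha > 1):
            raise ValueError("alpha must lie in [0, 1]")


def _edge_graph(mesh: TriangleMesh) -> sp.csr_matrix:
    e = mesh.edges_unique()
    w = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    n = mesh.n_vertices
    g = sp.csr_matrix((np.concatenate([w, w]),
                       (np.concatenate([e[:, 0], e[:, 1]]),
                        np.concatenate([e[:, 1], e[:, 0]]))), shape=(n, n))
    return g


def detect_caps(mesh: TriangleMesh) -> list:
    """One cap per boundary loop; closed meshes yield an empty list."""
    loops = mesh.boundary_loops or mesh.find_boundary_loops()
    if not loops:
        return []
    caps = []
    for loop in loops:
        center = mesh.vertices[loop].mean(axis=0)
        rim = np.linalg.norm(mesh.vertices[loop] - center, axis=1)
        # with an open cap the center's surface projection lands on the rim
        # itself, so the rim radius is the faithful "geodesic radius" (on a
        # filled cap the two coincide)
        radius = float(rim.max())
        cv = int(loop[int(np.argmin(rim))])
        caps.append(Cap(center=center, center_vertex=cv,
                        geodesic_radius=radius, loop=list(loop)))
    return caps


def compute_scaling_field(mesh: TriangleMesh, caps: list | None = None,
                          buffer_sigma: float | None = None
                          ) -> ScalingGateField:
    """Per-vertex mobility field; buffer_sigma defaults to cap radius / 2."""
    if caps is None:
        caps = detect_caps(mesh)
    nv = mesh.n_vertices
    if not caps:
        import warnings
        warnings.warn("mesh has no open caps; scaling gate is all-ones")
        return ScalingGateField(caps=[], buffer_sigma=np.zeros(0),
                                alpha=np.ones(nv))
    graph = _edge_graph(mesh)
    alpha = np.ones(nv)
    sigmas = []
    for cap in caps:
        r = cap.geodesic_radius
        sg = buffer_sigma if buffer_sigma is not None else r / 2.0
        sigmas.append(sg)
        # on-surface distance to the virtual cap center: rim vertices sit at
        # geodesic distance r from it, wall vertices at r + (distance to rim)
        d_rim = dijkstra(graph, directed=False, indices=cap.loop).min(axis=0)
        d = r + d_rim
        d[cap.loop] = r - 1e-12   # the rim belongs to the frozen cap zone
        a = np.ones(nv)
        inside = d < r
        buffer = (d >= r) & (d < r + 3 * sg)
        a[inside] = 0.0
        a[buffer] = 1.0 - np.exp(-(d[buffer] - r) ** 2 / (2 * sg ** 2))
        alpha = np.minimum(alpha, a)
    return ScalingGateField(caps=caps, buffer_sigma=np.array(sigmas),
                            alpha=alpha)


def apply_gate(momenta, alpha: np.ndarray):
    """xi_i <- alpha_i * xi_i (works on arrays and on autodiff tensors)."""
    a = np.asarray(alpha, dtype=float).reshape(-1, 1)
    return momenta * a
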