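"""Per-case unsupervised optimization of the surface deformation.

Each case is its own training run: the momentum predictor's weights are
optimized so that the LDDMM flow it induces carries the initial surface
onto the image gradients while the mesh regularizers keep the triangulation
sane.  No surface labels are involved; convergence typically sets in within
a couple hundred epochs.  The iterate with the lowest total loss is
returned (the loss is not monotone under Adam).

Setting ``use_lddmm=False`` switches to direct per-vertex displacement
optimization (the classic deformable-surface baseline, used for ablations);
``use_gate=False`` disables the cap-freezing scaling gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .. import autodiff as ad
from ..mesh import TriangleMesh
from ..volume import ScalarVolume, gradient_magnitude_volume
from .gate import compute_scaling_field, detect_caps
from .gnn import MomentumPredictor, mesh_laplacian
from .lddmm import ControlPointSystem, integrate_flow, subsample_control_points
from .losses import MeshTopology, total_loss_t

__all__ = ["DeformConfig", "DeformResult", "optimize_deformation"]


@dataclass
class DeformConfig:
    weights: tuple = (1.0, 0.2, 0.01, 0.1)   # w1..w4 of the total loss
    epochs: int = 300
    learning_rate: float = 2e-3        # predictor weights
    direct_learning_rate: float = 0.05  # mm/step scale for the no-flow ablation
    n_control: int = 300
    kernel_width: float | None = None   # sigma_K; default 2x control spacing
    buffer_sigma: float | None = None   # sigma_g; default cap radius / 2
    steps: int = 15
    time_span: float = 1.0
    energy_eps: float = 1e-8
    presmooth_sigma: float = 1.0        # voxels, for the gradient volume
    gnn_hidden: int = 64
    gnn_order: int = 3
    use_lddmm: bool = True
    use_gate: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if any(w < 0 for w in self.weights):
            raise ValueError("loss weights must be nonnegative")


@dataclass
class DeformResult:
    mesh: TriangleMesh
    history: dict
    control_indices: np.ndarray
    alpha: np.ndarray
    predictor: object = field(repr=False, default=None)


def _auto_kernel_width(points: np.ndarray) -> float:
    tree = cKDTree(points)
    d, _ = tree.query(points, k=2, workers=-1)
    return 2.0 * float(np.mean(d[:, 1]))


def optimize_deformation(mesh: TriangleMesh, image: ScalarVolume,
                         config: DeformConfig | None = None,
                         gradmag: ScalarVolume | None = None,
                         predictor: MomentumPredictor | None = None
                         ) -> DeformResult:
    """Run the unsupervised deformation loop on one case.

    ``image`` is the (preprocessed) intensity volume; its gradient-magnitude
    field drives the alignment.  Pass ``gradmag`` to reuse a precomputed
    field, and ``predictor`` to resume from an earlier run's state.
    """
    config = config or DeformConfig()
    if gradmag is None:
        gradmag = gradient_magnitude_volume(image, config.presmooth_sigma)
    topo = MeshTopology(mesh)
    caps = detect_caps(mesh)
    if config.use_gate:
        gate = compute_scaling_field(mesh, caps, config.buffer_sigma)
        alpha = gate.alpha
    else:
        alpha = np.ones(mesh.n_vertices)

    rng = np.random.default_rng(config.seed)
    n_control = min(config.n_control, mesh.n_vertices)
    cp_idx = subsample_control_points(mesh, n_control,
                                      seed=int(rng.integers(2 ** 31)))
    sigma_k = config.kernel_width or _auto_kernel_width(mesh.vertices[cp_idx])

    if predictor is None:
        predictor = MomentumPredictor(hidden=config.gnn_hidden,
                                      order=config.gnn_order,
                                      seed=int(rng.integers(2 ** 31)))
    L = mesh_laplacian(mesh)
    direct_disp = None
    if config.use_lddmm:
        params = predictor.parameters()
    else:
        direct_disp = ad.Tensor(np.zeros_like(mesh.vertices),
                                requires_grad=True)
        params = [direct_disp]
    lr = config.learning_rate if config.use_lddmm else \
        config.direct_learning_rate
    opt = ad.Adam(params, lr=lr)

    cps = ControlPointSystem(points=mesh.vertices[cp_idx],
                             momenta=np.zeros((n_control, 3)),
                             kernel_width=sigma_k, steps=config.steps,
                             time_span=config.time_span)
    alpha_cp = alpha[cp_idx].reshape(-1, 1)
    verts0 = ad.Tensor(mesh.vertices.copy())

    history = {k: [] for k in ("total", "energy", "normal", "edge",
                               "laplacian")}
    best = (np.inf, mesh.vertices.copy())
    for epoch in range(config.epochs):
        if config.use_lddmm:
            mom_vertices = predictor(mesh.vertices, L)
            xi = mom_vertices[cp_idx] * alpha_cp
            _, verts_t, _ = integrate_flow(mesh.vertices, cps, momenta=xi,
                                           vertex_alpha=alpha)
        else:
            verts_t = verts0 + direct_disp * alpha.reshape(-1, 1)
        loss, comps = total_loss_t(verts_t, topo, gradmag,
                                   weights=config.weights,
                                   eps=config.energy_eps)
        if not np.isfinite(comps["total"]):
            break  # keep the last valid iterate
        for key in history:
            history[key].append(comps[key])
        if comps["total"] < best[0]:
            best = (comps["total"], verts_t.data.copy())
        opt.zero_grad()
        loss.backward()
        opt.step()

    out = TriangleMesh(best[1], mesh.faces.copy(),
                       [list(l) for l in mesh.boundary_loops])
    return DeformResult(mesh=out, history=history, control_indices=cp_idx,
                        alpha=alpha, predictor=predictor)
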