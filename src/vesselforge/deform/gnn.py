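"""Chebyshev graph-convolution momentum predictor.

Spectral graph convolutions of order K act on the mesh's vertex graph via
Chebyshev polynomials of the scaled Laplacian (lambda_max taken as 2, the
usual normalized-Laplacian bound), so each layer mixes information within a
K-hop neighborhood and is permutation-equivariant by construction.  The
predictor has two blocks of two layers with residual connections; the final
projection starts at zero, so optimization begins from the identity flow.
Inputs are the centered, scale-normalized vertex coordinates.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .. import autodiff as ad
from ..mesh import TriangleMesh

__all__ = ["mesh_laplacian", "ChebConv", "MomentumPredictor"]


def mesh_laplacian(mesh: TriangleMesh) -> sp.csr_matrix:
    """Scaled normalized graph Laplacian  L_tilde = L - I  (lambda_max ~ 2)."""
    e = mesh.edges_unique()
    n = mesh.n_vertices
    A = sp.csr_matrix((np.ones(2 * len(e)),
                       (np.concatenate([e[:, 0], e[:, 1]]),
                        np.concatenate([e[:, 1], e[:, 0]]))), shape=(n, n))
    deg = np.asarray(A.sum(axis=1)).ravel()
    if np.any(deg == 0):
        import warnings
        warnings.warn("mesh graph has isolated vertices")
        deg = np.maximum(deg, 1.0)
    dinv = sp.diags(1.0 / np.sqrt(deg))
    # L = I - D^-1/2 A D^-1/2 ; scaled by lambda_max = 2:  L_tilde = L - I
    return (-(dinv @ A @ dinv)).tocsr()


class ChebConv:
    """One Chebyshev spectral convolution: X -> sum_k T_k(L~) X W_k + b."""

    def __init__(self, fin: int, fout: int, order: int, rng,
                 zero_init: bool = False):
        self.order = order
        std = 0.0 if zero_init else np.sqrt(2.0 / (fin * order))
        self.weights = [ad.Tensor(rng.standard_normal((fin, fout)) * std,
                                  requires_grad=True) for _ in range(order)]
        self.bias = ad.Tensor(np.zeros(fout), requires_grad=True)

    def parameters(self):
        return [*self.weights, self.bias]

    def __call__(self, x: ad.Tensor, L: sp.csr_matrix) -> ad.Tensor:
        t_prev, t_cur = x, ad.spmm(L, x)
        out = t_prev @ self.weights[0]
        if self.order > 1:
            out = out + t_cur @ self.weights[1]
        for k in range(2, self.order):
            t_nxt = ad.spmm(L, t_cur) * 2.0 - t_prev
            out = out + t_nxt @ self.weights[k]
            t_prev, t_cur = t_cur, t_nxt
        return out + self.bias.reshape(1, -1)


class MomentumPredictor:
    """Two residual blocks of two ChebConv layers -> per-vertex 3-vector."""

    def __init__(self, hidden: int = 64, order: int = 3, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.inp = ChebConv(3, hidden, order, rng)
        self.blocks = [(ChebConv(hidden, hidden, order, rng),
                        ChebConv(hidden, hidden, order, rng))
                       for _ in range(2)]
        self.out = ChebConv(hidden, 3, order, rng, zero_init=True)

    def parameters(self):
        ps = self.inp.parameters()
        for a, b in self.blocks:
            ps += a.parameters() + b.parameters()
        return ps + self.out.parameters()

    @staticmethod
    def normalize_coords(verts: np.ndarray) -> np.ndarray:
        c = verts - verts.mean(axis=0)
        scale = np.max(np.linalg.norm(c, axis=1))
        return c / max(scale, 1e-12)

    def __call__(self, verts: np.ndarray, L: sp.csr_matrix) -> ad.Tensor:
        x = ad.Tensor(self.normalize_coords(np.asarray(verts, dtype=float)))
        h = self.inp(x, L).tanh()
        for a, b in self.blocks:
            r = b(a(h, L).tanh(), L)
            h = (h + r).tanh()
        return self.out(h, L)
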