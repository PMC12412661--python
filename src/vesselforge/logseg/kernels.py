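"""Hierarchical 3D Laplacian-of-Gaussian kernel bank.

The LoG filter at scale sigma responds most strongly to tubular/blob
structures whose radius is near sqrt(2)*sigma, so a bank of increasing
scales covers vessels from small supra-aortic branches up to the main
aorta.  The raw filter is

    LoG(x, y, z) = (x^2 + y^2 + z^2 - 2 sigma^2) / sigma^4
                   * exp(-(x^2 + y^2 + z^2) / (2 sigma^2))

evaluated at integer voxel offsets (the Gaussian normalizing prefactor is
deliberately omitted; stored kernels are mean-subtracted and L1-normalized
instead, which makes response magnitudes comparable across scales).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["log_kernel_raw", "build_log_kernel", "LoGKernelBank",
           "DEFAULT_LEVELS"]

# kernel size paired with LoG scale; the scale ladder doubles as the
# per-layer prior SD of the variational weights
DEFAULT_LEVELS = ((3, 0.5), (5, 1.0), (7, 1.5), (9, 2.0), (11, 2.5))


def log_kernel_raw(size: int, sigma: float) -> np.ndarray:
    """Unnormalized LoG kernel on a size^3 grid centered at the origin."""
    if size % 2 == 0:
        raise ValueError("kernel size must be odd")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    r = np.arange(size) - size // 2
    x, y, z = np.meshgrid(r, r, r, indexing="ij")
    r2 = (x ** 2 + y ** 2 + z ** 2).astype(float)
    return (r2 - 2 * sigma ** 2) / sigma ** 4 * np.exp(-r2 / (2 * sigma ** 2))


def build_log_kernel(size: int, sigma: float) -> np.ndarray:
    """Mean-subtracted, L1-normalized LoG kernel (zero response to constants)."""
    k = log_kernel_raw(size, sigma)
    k = k - k.mean()
    return k / np.abs(k).sum()


@dataclass
class LoGKernelBank:
    levels: tuple = DEFAULT_LEVELS
    kernels: list = field(init=False)

    def __post_init__(self):
        self.kernels = [build_log_kernel(s, sg) for s, sg in self.levels]
        for k in self.kernels:
            assert abs(k.mean()) <= 1e-8

    @property
    def sigmas(self):
        return [sg for _, sg in self.levels]

    @property
    def sizes(self):
        return [s for s, _ in self.levels]

    def responses(self, patch: np.ndarray) -> list:
        """Raw per-level filter responses (same shape as the input patch)."""
        from scipy.ndimage import correlate
        return [correlate(patch.astype(float), k, mode="nearest")
                for k in self.kernels]

    def argmax_level(self, patch: np.ndarray, mask: np.ndarray) -> int:
        """Level with the strongest mean response magnitude over ``mask``.

        Scale selectivity probe: for an ideal tube the winning level's sigma
        tracks radius / sqrt(2).
        """
        mags = [np.abs(r[mask]).mean() for r in self.responses(patch)]
        return int(np.argmax(mags))
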