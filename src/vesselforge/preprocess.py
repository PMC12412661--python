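"""Image preprocessing, augmentation, patch extraction and stitching.

Mirrors the standard preparation of CT angiography for patch-based
segmentation networks: cubic-spline upsampling, intensity clipping to the
contrast window and rescaling to [0, 1], background suppression for
training, flip/rotate/crop augmentation, and overlapping cubic patch
tiling with averaging on reassembly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates, rotate as nd_rotate

from .volume import LabelVolume, ProbabilityVolume, ScalarVolume

__all__ = [
    "PatchSpec",
    "resample_volume",
    "clip_normalize",
    "suppress_background",
    "random_augment",
    "extract_patches",
    "stitch_predictions",
]

DEFAULT_PATCH_SIZE = (64, 64, 64)
DEFAULT_OVERLAP = (16, 16, 16)


@dataclass(frozen=True)
class PatchSpec:
    """Placement of one cubic patch inside the (zero-padded) grid."""

    corner: tuple
    size: tuple

    def __post_init__(self):
        if any(s < 8 for s in self.size):
            raise ValueError("patch size components must be >= 8")


def resample_volume(vol: ScalarVolume, factor: float,
                    max_voxels: int = 768 ** 3) -> ScalarVolume:
    """Resample with tricubic (B-spline) interpolation.

    New spacing is ``old / factor``; the grid keeps the same origin and its
    world extent shrinks by at most one voxel (no extrapolation past the
    last input voxel center).
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    old_shape = np.array(vol.shape)
    new_shape = np.floor((old_shape - 1) * factor).astype(int) + 1
    if np.prod(new_shape) > max_voxels:
        raise MemoryError(
            f"resampled grid {tuple(new_shape)} exceeds the voxel guard")
    grids = [np.arange(n) / factor for n in new_shape]
    ii, jj, kk = np.meshgrid(*grids, indexing="ij")
    out = map_coordinates(vol.values.astype(float), [ii, jj, kk], order=3,
                          mode="nearest")
    return ScalarVolume(out, vol.spacing / factor, vol.origin.copy())


def clip_normalize(vol: ScalarVolume, lo: float = 0.0, hi: float = 500.0
                   ) -> ScalarVolume:
    """Clip intensities to [lo, hi] and rescale to [0, 1]."""
    if hi <= lo:
        raise ValueError("hi must exceed lo")
    out = (np.clip(vol.values.astype(float), lo, hi) - lo) / (hi - lo)
    return vol.with_values(out, cls=ScalarVolume)


def suppress_background(vol: ScalarVolume, label: LabelVolume) -> ScalarVolume:
    """Zero out voxels outside the vessel label (training images only)."""
    if not vol.same_grid(label):
        raise ValueError("image and label grids do not match")
    return vol.with_values(vol.values * (label.values > 0), cls=ScalarVolume)


def random_augment(vol: ScalarVolume, label: LabelVolume, seed: int,
                   crop_size=DEFAULT_PATCH_SIZE, arbitrary_rotation=False,
                   return_params: bool = False):
    """Seeded random flip, rotation, and crop applied jointly to image+label.

    Rotations default to 90-degree multiples about a random grid axis so the
    label needs no interpolation; ``arbitrary_rotation`` enables free-angle
    rotation with linear (image) / nearest (label) resampling.
    """
    if not vol.same_grid(label):
        raise ValueError("image and label grids do not match")
    crop_size = tuple(int(c) for c in np.broadcast_to(crop_size, 3))
    if any(c > s for c, s in zip(crop_size, vol.shape)):
        raise ValueError("crop larger than the grid")
    rng = np.random.default_rng(seed)
    img, lab = vol.values.astype(float), label.values.copy()

    flips = rng.random(3) < 0.5
    for ax in np.nonzero(flips)[0]:
        img = np.flip(img, axis=ax)
        lab = np.flip(lab, axis=ax)

    rot_axes = [(0, 1), (0, 2), (1, 2)][rng.integers(3)]
    if arbitrary_rotation:
        angle = float(rng.uniform(0, 360))
        img = nd_rotate(img, angle, axes=rot_axes, reshape=False, order=1,
                        mode="nearest")
        lab = nd_rotate(lab, angle, axes=rot_axes, reshape=False, order=0,
                        mode="nearest")
        k = 0
    else:
        angle = 0.0
        k = int(rng.integers(4))
        img = np.rot90(img, k=k, axes=rot_axes)
        lab = np.rot90(lab, k=k, axes=rot_axes)

    corner = [int(rng.integers(0, s - c + 1))
              for s, c in zip(img.shape, crop_size)]
    sl = tuple(slice(c, c + n) for c, n in zip(corner, crop_size))
    img, lab = np.ascontiguousarray(img[sl]), np.ascontiguousarray(lab[sl])
    out_v = ScalarVolume(img, vol.spacing.copy(), vol.origin.copy())
    out_l = LabelVolume(lab, vol.spacing.copy(), vol.origin.copy())
    if return_params:
        params = {"flips": flips.tolist(), "rot_axes": rot_axes,
                  "rot_k": k, "angle": angle, "corner": corner}
        return out_v, out_l, params
    return out_v, out_l


def extract_patches(vol: ScalarVolume, size=DEFAULT_PATCH_SIZE,
                    overlap=DEFAULT_OVERLAP):
    """Tile the volume into overlapping cubic patches.

    Corners sit at multiples of ``stride = size - overlap`` (ceil tiling), so
    every voxel is covered at least once; patches extending past the grid are
    zero padded.  Returns a list of (PatchSpec, values) pairs.
    """
    size = tuple(int(s) for s in np.broadcast_to(size, 3))
    overlap = tuple(int(o) for o in np.broadcast_to(overlap, 3))
    if any(o >= s for o, s in zip(overlap, size)):
        raise ValueError("overlap must be smaller than the patch size")
    stride = [s - o for s, o in zip(size, overlap)]
    counts = [int(np.ceil(n / st)) for n, st in zip(vol.shape, stride)]
    patches = []
    for ci in range(counts[0]):
        for cj in range(counts[1]):
            for ck in range(counts[2]):
                corner = (ci * stride[0], cj * stride[1], ck * stride[2])
                block = np.zeros(size, dtype=float)
                src = tuple(slice(c, min(c + s, n))
                            for c, s, n in zip(corner, size, vol.shape))
                dst = tuple(slice(0, sl.stop - sl.start) for sl in src)
                block[dst] = vol.values[src]
                patches.append((PatchSpec(corner, size), block))
    return patches


def stitch_predictions(patches, template: ScalarVolume,
                       blend: str = "mean") -> ProbabilityVolume:
    """Reassemble per-patch predictions into a full probability volume.

    Overlapping voxels are averaged; ``blend='cosine'`` weights each patch by
    a separable raised-cosine window instead of uniformly.
    """
    acc = np.zeros(template.shape, dtype=float)
    cnt = np.zeros(template.shape, dtype=float)
    for spec, values in patches:
        values = np.asarray(values, dtype=float)
        if blend == "cosine":
            wins = [np.sin(np.pi * (np.arange(n) + 0.5) / n) for n in spec.size]
            w = wins[0][:, None, None] * wins[1][None, :, None] * wins[2][None, None, :]
        else:
            w = np.ones(spec.size)
        src = tuple(slice(c, min(c + s, n))
                    for c, s, n in zip(spec.corner, spec.size, template.shape))
        cut = tuple(slice(0, sl.stop - sl.start) for sl in src)
        acc[src] += (values * w)[cut]
        cnt[src] += w[cut]
    if np.any(cnt == 0):
        raise ValueError("patches do not cover the grid")
    return ProbabilityVolume(acc / cnt, template.spacing.copy(),
                             template.origin.copy())
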