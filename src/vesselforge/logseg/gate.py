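"""Balanced gate: class-balanced batch assembly for vessel patches.

Randomly cropped training cubes overwhelmingly contain the large main
vessel; cubes dominated by thin branches are rare.  The gate classifies
each cube by the fraction of its (bounded, [0,1]) LoG feature voxels above
a threshold tau — large vessels light up more voxels — and maintains two
candidate pools, emitting batches with an equal number of patches from
each, so the optimizer sees both vessel calibres at parity regardless of
their prevalence in the stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["voxel_percentage", "classify_patch", "GateState",
           "assemble_balanced_batch", "PoolExhaustedError"]


class PoolExhaustedError(RuntimeError):
    """Raised when the patch stream ends before both pools are filled."""


def voxel_percentage(feature: np.ndarray, tau: float = 0.5) -> float:
    """Fraction of feature voxels strictly above ``tau``."""
    feature = np.asarray(feature)
    if feature.min() < -1e-9 or feature.max() > 1 + 1e-9:
        raise ValueError("voxel_percentage expects features in [0, 1]")
    return float(np.mean(feature > tau))


def classify_patch(vp: float, beta: float = 0.15) -> str:
    """'main' when the voxel percentage reaches beta (ties -> main)."""
    if not 0.0 <= vp <= 1.0:
        raise ValueError("voxel percentage must lie in [0, 1]")
    return "main" if vp >= beta else "branch"


@dataclass
class GateState:
    capacity: int = 10
    draw: int = 5
    tau: float = 0.5
    beta: float = 0.15
    seed: int = 0
    main_pool: list = field(default_factory=list)
    branch_pool: list = field(default_factory=list)

    def __post_init__(self):
        if not (0 < self.beta < 1 and 0 < self.tau < 1):
            raise ValueError("thresholds must lie strictly in (0, 1)")
        if self.draw > self.capacity:
            raise ValueError("draw cannot exceed pool capacity")
        self._rng = np.random.default_rng(self.seed)

    def offer(self, item, vp: float) -> None:
        pool = self.main_pool if classify_patch(vp, self.beta) == "main" \
            else self.branch_pool
        if len(pool) < self.capacity:
            pool.append(item)

    @property
    def full(self) -> bool:
        return (len(self.main_pool) >= self.capacity
                and len(self.branch_pool) >= self.capacity)


def assemble_balanced_batch(gate: GateState, stream, classifier):
    """Fill both pools from ``stream`` then draw an exactly balanced batch.

    ``classifier(item) -> vp`` maps a stream item to its voxel percentage.
    Returns a list of 2*draw items, ``draw`` per class, removed from the
    pools.  Raises PoolExhaustedError with a pool diagnostic if the stream
    ends first.
    """
    stream = iter(stream)
    max_consume = 200 * gate.capacity  # guard against a starved class
    consumed = 0
    while not gate.full:
        try:
            item = next(stream)
        except StopIteration:
            raise PoolExhaustedError(
                f"patch stream exhausted with pools main={len(gate.main_pool)}"
                f"/branch={len(gate.branch_pool)} of capacity {gate.capacity}")
        consumed += 1
        if consumed > max_consume:
            raise PoolExhaustedError(
                f"one class is starved: after {consumed} stream patches the "
                f"pools hold main={len(gate.main_pool)}/"
                f"branch={len(gate.branch_pool)} of capacity {gate.capacity}; "
                f"check the classification threshold beta")
        gate.offer(item, classifier(item))
    batch = []
    for pool in (gate.main_pool, gate.branch_pool):
        take = gate._rng.choice(len(pool), size=gate.draw, replace=False)
        for i in sorted(take, reverse=True):
            batch.append(pool.pop(i))
    return batch
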