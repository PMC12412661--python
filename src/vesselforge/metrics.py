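"""Segmentation and surface quality metrics, plus UQ summaries.

Surface metrics operate on vertex point clouds (stated in the report
metadata — point-to-triangle distances are not used):

* ASD: symmetric mean nearest-neighbor distance,
  [sum_{x in A} min_y d + sum_{y in B} min_x d] / (|A| + |B|);
* Hausdorff: the larger of the two directed sup-inf distances;
* SNR at a point: mean / population-SD over the 10^3-voxel window centered
  there (dimensionless).

The UQ summary measures, at each reference-surface point, the spread of an
ensemble of surfaces (SD of nearest-point distances) and relates log-SD to
local image SNR by Spearman correlation and a least-squares slope; noisier
image regions should carry larger surface uncertainty, i.e. the slope of
log-SD against SNR comes out negative.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import spearmanr

from .logseg.losses import dice_coefficient
from .volume import LabelVolume, ScalarVolume

__all__ = ["MetricsReport", "asd", "hausdorff", "snr_at_point",
           "uq_summary", "compare_segmentations"]


@dataclass
class MetricsReport:
    dice: float
    asd: float
    hausdorff: float
    point_definition: str = "mesh vertices"
    regions: dict | None = None

    def __post_init__(self):
        if not 0 <= self.dice <= 1:
            raise ValueError("dice must lie in [0, 1]")
        if self.asd < 0 or self.hausdorff < 0:
            raise ValueError("distances must be nonnegative")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _clouds(a, b):
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("point clouds must be nonempty")
    return a, b


def asd(points_a, points_b) -> float:
    """Symmetric average surface distance between two point clouds (mm)."""
    a, b = _clouds(points_a, points_b)
    d_ab, _ = cKDTree(b).query(a, workers=-1)
    d_ba, _ = cKDTree(a).query(b, workers=-1)
    return float((d_ab.sum() + d_ba.sum()) / (len(a) + len(b)))


def hausdorff(points_a, points_b) -> float:
    """Symmetric Hausdorff distance between two point clouds (mm)."""
    a, b = _clouds(points_a, points_b)
    d_ab, _ = cKDTree(b).query(a, workers=-1)
    d_ba, _ = cKDTree(a).query(b, workers=-1)
    return float(max(d_ab.max(), d_ba.max()))


def snr_at_point(vol: ScalarVolume, center, window: int = 10):
    """Relative SNR (mean / population SD) of the window around a point.

    ``center`` is in world mm; the window is clipped at the grid borders
    (with a warning flag in the return).  A constant window has no noise
    scale, so SNR is flagged infinite.

    Returns (snr, flags) with flags in {"ok", "clipped", "infinite",
    "clipped+infinite"}.
    """
    idx = np.round(vol.world_to_index(center)).astype(int)
    half = window // 2
    lo = idx - half
    hi = lo + window
    lo_c = np.maximum(lo, 0)
    hi_c = np.minimum(hi, vol.shape)
    clipped = np.any(lo_c != lo) or np.any(hi_c != hi)
    block = vol.values[lo_c[0]:hi_c[0], lo_c[1]:hi_c[1], lo_c[2]:hi_c[2]]
    if block.size == 0:
        raise ValueError("window lies entirely outside the volume")
    mean = float(block.mean())
    sd = float(block.std())  # population SD (1/n)
    flags = []
    if clipped:
        flags.append("clipped")
    if sd == 0:
        flags.append("infinite")
        return np.inf, "+".join(flags)
    return mean / sd, "+".join(flags) if flags else "ok"


def uq_summary(ensemble_points: list, reference_points: np.ndarray,
               vol: ScalarVolume, window: int = 10) -> dict:
    """Per-point ensemble SD and its relation to local image SNR.

    ``ensemble_points``: list of (V_i, 3) vertex arrays (>= 2 members).
    ``reference_points``: (V, 3) mean/reference surface vertices; for each,
    the distance to the nearest vertex of every member is collected and its
    SD across members is the local uncertainty.

    Returns dict with per-point ``sd``, ``snr``, Spearman ``correlation``,
    and least-squares ``slope`` of log-SD against SNR.
    """
    if len(ensemble_points) < 2:
        raise ValueError("need at least 2 ensemble members")
    ref = np.atleast_2d(np.asarray(reference_points, dtype=float))
    dists = []
    for pts in ensemble_points:
        d, _ = cKDTree(np.atleast_2d(pts)).query(ref, workers=-1)
        dists.append(d)
    dists = np.stack(dists)          # (n_members, V)
    sd = dists.std(axis=0)
    if np.allclose(sd, 0):
        raise ValueError("degenerate ensemble: all members identical")
    snr = np.empty(len(ref))
    for i, p in enumerate(ref):
        snr[i], _ = snr_at_point(vol, p, window=window)
    ok = np.isfinite(snr) & (sd > 0)
    log_sd = np.log(sd[ok])
    rho = spearmanr(log_sd, snr[ok]).statistic
    slope = float(np.polyfit(snr[ok], log_sd, 1)[0])
    return {"sd": sd, "snr": snr, "correlation": float(rho), "slope": slope,
            "n_points": int(ok.sum())}


def compare_segmentations(pred: LabelVolume, truth: LabelVolume,
                          pred_points=None, truth_points=None,
                          regions: ScalarVolume | None = None
                          ) -> MetricsReport:
    """Dice (+ optional surface distances and per-region breakdown).

    ``regions``: integer-valued volume (0 background, 1 main vessel, >= 2
    branches) used to split the Dice into main/branch reports.
    """
    d = dice_coefficient(pred, truth)
    a = h = 0.0
    if pred_points is not None and truth_points is not None:
        a = asd(pred_points, truth_points)
        h = hausdorff(pred_points, truth_points)
    per_region = None
    if regions is not None:
        per_region = {}
        reg = regions.values
        for name, mask in (("main", reg == 1), ("branch", reg >= 2)):
            if mask.any():
                per_region[name] = dice_coefficient(
                    pred.values * mask, truth.values * mask)
    return MetricsReport(dice=d, asd=a, hausdorff=h, regions=per_region)
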