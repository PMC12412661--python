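"""Desk-scale phantom studies: the package's standard validation runs.

These functions pin the conditions of the scaled-down experiments — the
phantom family, the tiny network, the recovery and uncertainty studies —
so the test suite and the reproduction script execute the identical
protocol.  Problem sizes are chosen for a single CPU (see
docs/methods.md); every function is fully seeded.
"""

from __future__ import annotations

import numpy as np

from .deform import DeformConfig, optimize_deformation
from .logseg import (LoGBNet, sample_segmentations, tiny_model_config,
                     tiny_train_config, train_segmenter)
from .logseg.train import holdout_dice
from .mesh import TriangleMesh
from .metrics import asd, uq_summary
from .phantom import curved_vessel_spec, make_phantom
from .preprocess import clip_normalize
from .surface import SmoothingWeights, extract_isosurface, remesh_uniform, \
    smooth_mesh
from .volume import ProbabilityVolume

__all__ = ["phantom_family", "train_desk_segmenter", "recovery_case",
           "run_recovery", "uq_study", "boundary_band_sd_ratio",
           "dense_surface_points"]


def phantom_family(n: int = 7, shape=(96, 96, 96), seed0: int = 0):
    """The segmentation study family: curved, branched 96^3 phantoms.

    Main-vessel radii cycle through 6/7/8 voxels with two branches each;
    intensities, blur, and noise are the generator defaults.  Returns a
    list of (normalized image, label) pairs.
    """
    cases = []
    for s in range(n):
        spec = curved_vessel_spec(grid_shape=tuple(shape),
                                  radius=6.0 + (s % 3), n_branches=2,
                                  seed=seed0 + s)
        vol, lab, _ = make_phantom(spec)
        cases.append((clip_normalize(vol), lab))
    return cases


def train_desk_segmenter(seed: int = 0, epochs: int = 8, n_train: int = 6):
    """Train the tiny network on the study family; returns (model, history,
    held-out Dice)."""
    cases = phantom_family(n=n_train + 1, seed0=seed)
    model, history = train_segmenter(cases[:n_train],
                                     tiny_model_config(seed),
                                     tiny_train_config(seed, epochs=epochs))
    dice = holdout_dice(model, cases[n_train][0], cases[n_train][1])
    return model, history, dice


# ------------------------------------------------------------------ recovery
def _smooth_random_field(verts: np.ndarray, rng, amplitude: float
                         ) -> np.ndarray:
    """Smooth random displacement field with max amplitude in mm."""
    out = np.zeros_like(verts)
    for _ in range(4):
        k = rng.normal(0, 0.08, 3)
        phase = rng.uniform(0, 2 * np.pi)
        out += np.sin(verts @ k + phase)[:, None] * rng.normal(0, 1, 3)
    # amplitude = peak displacement magnitude
    return out * (amplitude / np.linalg.norm(out, axis=1).max())


def recovery_case(seed: int = 3, shape=(64, 64, 64), radius: float = 7.0,
                  amplitude: float = 2.0, target_vertices: int = 1200):
    """Phantom + ground truth + smoothly perturbed starting surface.

    The ground-truth surface is uniformly remeshed, its caps re-opened, and
    displaced by a seeded smooth random field of the given amplitude (in
    voxels) — a stand-in for segmentation error near the wall.
    """
    from .pipeline import _open_phantom_caps
    spec = curved_vessel_spec(grid_shape=tuple(shape), radius=radius,
                              n_branches=1, seed=seed)
    image, label, gt_mesh = make_phantom(spec)
    norm = clip_normalize(image)
    start = remesh_uniform(gt_mesh.fill_caps(), target_vertices, seed=0)
    start = _open_phantom_caps(start, spec)
    rng = np.random.default_rng(seed + 8)
    pert = _smooth_random_field(start.vertices, rng,
                                amplitude * float(np.min(image.spacing)))
    init = TriangleMesh(start.vertices + pert, start.faces,
                        [list(l) for l in start.boundary_loops])
    return norm, gt_mesh, init


def dense_surface_points(mesh: TriangleMesh, max_edge: float = 0.6
                         ) -> np.ndarray:
    """Vertices of the flat-subdivided mesh (same surface, finer sampling).

    Point-cloud surface distances between meshes of different vertex
    density otherwise bottom out at the coarser mesh's half edge length.
    """
    import trimesh as _trimesh
    v, f = mesh.vertices, mesh.faces
    for _ in range(4):
        lengths = np.linalg.norm(v[f[:, 0]] - v[f[:, 1]], axis=1)
        if lengths.max() <= max_edge:
            break
        v, f = _trimesh.remesh.subdivide(v, f)
    return v


def run_recovery(epochs: int = 250, seed: int = 5, case_seed: int = 3,
                 use_gate: bool = True, use_lddmm: bool = True,
                 n_control: int = 250,
                 weights=(1.0, 0.2, 0.01, 0.1)) -> dict:
    """Deformation recovery study; returns ASDs, histories, cap motion.

    The structural ablations are run with ``weights=(1, 0, 0, 0)``: with
    the explicit regularizers active both arms stay smooth on phantoms and
    the comparison degenerates; energy-only optimization isolates what the
    flow prior itself contributes.
    """
    norm, gt_mesh, init = recovery_case(seed=case_seed)
    gt_pts = dense_surface_points(gt_mesh)
    initial_asd = asd(dense_surface_points(init), gt_pts)
    config = DeformConfig(epochs=epochs, n_control=n_control, seed=seed,
                          use_gate=use_gate, use_lddmm=use_lddmm,
                          weights=weights)
    result = optimize_deformation(init, norm, config)
    final_asd = asd(dense_surface_points(result.mesh), gt_pts)
    cap_verts = [v for loop in init.boundary_loops for v in loop]
    disp = np.linalg.norm(result.mesh.vertices - init.vertices, axis=1)
    return {
        "initial_asd": initial_asd,
        "final_asd": final_asd,
        "improvement": 1.0 - final_asd / initial_asd,
        "history": result.history,
        "cap_displacement": float(disp[cap_verts].max()) if cap_verts else 0.0,
        "max_displacement": float(disp.max()),
        "result": result,
        "ground_truth": gt_mesh,
        "initial_mesh": init,
    }


# ------------------------------------------------------------------------ UQ
def uq_study(model: LoGBNet, n_members: int = 4, seed: int = 0,
             shape=(64, 64, 64), deform_epochs: int = 80,
             target_vertices: int = 700) -> dict:
    """Uncertainty propagation on a graded-noise phantom.

    Noise SD rises from 5 to 35 along z; posterior weight samples yield a
    segmentation ensemble; each member becomes a smoothed surface and is
    then deformed with a shared configuration.  Summaries relate per-point
    surface SD to local SNR and compare smoothed- vs deformed-ensemble
    spread on the main vessel.
    """
    spec = curved_vessel_spec(grid_shape=tuple(shape), radius=7.0,
                              seed=seed + 40, noise_gradient=(2, 5.0, 35.0))
    image, label, gt_mesh = make_phantom(spec)
    norm = clip_normalize(image)
    members, mean_prob, sd_vol = sample_segmentations(
        model, norm, n=n_members, seed=seed, overlap=8)

    # SD-vs-SNR relation on the raw segmentation surfaces: the voxel-level
    # boundary variability carries the local image-quality signal that the
    # smoothing pipeline deliberately suppresses
    raw_ref = extract_isosurface(mean_prob, level=0.5).vertices
    raw_members = [extract_isosurface(ProbabilityVolume(
        m.values.astype(float), m.spacing, m.origin), level=0.5,
        presmooth=False).vertices for m in members]
    raw_summary = uq_summary(raw_members, raw_ref, image)

    ref = extract_isosurface(mean_prob, level=0.5)
    ref = remesh_uniform(ref, target_vertices, seed=seed)
    smoothing = SmoothingWeights(iterations=30)
    ref = smooth_mesh(ref, smoothing)

    dconf = DeformConfig(epochs=deform_epochs, n_control=150, seed=seed)
    smoothed, deformed = [], []
    for i, member in enumerate(members):
        m = extract_isosurface(ProbabilityVolume(
            member.values.astype(float), member.spacing, member.origin),
            level=0.5)
        m = remesh_uniform(m, target_vertices, seed=seed + i)
        m = smooth_mesh(m, smoothing)
        smoothed.append(m)
        deformed.append(optimize_deformation(m, norm, dconf).mesh)

    summary_smoothed = uq_summary([m.vertices for m in smoothed],
                                  ref.vertices, image)
    summary_deformed = uq_summary([m.vertices for m in deformed],
                                  ref.vertices, image)
    return {
        "label": label,
        "sd_volume": sd_vol,
        "members": members,
        "segmentation": raw_summary,
        "smoothed": summary_smoothed,
        "deformed": summary_deformed,
        "smoothed_mean_sd": float(np.mean(summary_smoothed["sd"])),
        "deformed_mean_sd": float(np.mean(summary_deformed["sd"])),
    }


def boundary_band_sd_ratio(sd_vol, label) -> float:
    """Mean ensemble SD in a 2-voxel band around the lumen boundary divided
    by the mean SD deep inside the lumen (> 2 voxels from the wall)."""
    from scipy.ndimage import distance_transform_edt
    inside = label.values > 0
    d_in = distance_transform_edt(inside)
    d_out = distance_transform_edt(~inside)
    band = (np.minimum(np.where(inside, d_in, np.inf),
                       np.where(~inside, d_out, np.inf)) <= 2.0)
    interior = inside & (d_in > 2.0)
    return float(sd_vol.values[band].mean()
                 / max(sd_vol.values[interior].mean(), 1e-12))
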