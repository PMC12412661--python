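"""End-to-end orchestration: image -> segmentation -> surface -> deformation.

The pipeline mirrors the automated model-construction workflow: a (phantom
or supplied) angiographic volume is normalized, segmented by the Bayesian
LoG network, turned into an initial surface (marching cubes + uniform
remeshing + smoothing), and refined by the unsupervised GNN-LDDMM
deformation against the image gradients.  Every stochastic stage draws
from a stage-scoped generator derived from the global seed, artifacts are
content-hashed, and the manifest captures everything needed to re-execute
the run.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .deform import DeformConfig, optimize_deformation
from .logseg import (LoGBNet, SegModelConfig, SegTrainConfig,
                     predict_volume, sample_segmentations, train_segmenter)
from .logseg.train import tiny_model_config, tiny_train_config
from .mesh import TriangleMesh, write_mesh
from .metrics import asd, compare_segmentations, hausdorff, uq_summary
from .phantom import PhantomSpec, make_phantom, region_volume
from .preprocess import clip_normalize
from .surface import SmoothingWeights, extract_isosurface, remesh_uniform, \
    smooth_mesh
from .volume import (LabelVolume, ProbabilityVolume, ScalarVolume,
                     read_volume, write_volume)

__all__ = ["PipelineConfig", "run_pipeline", "run_uq_pipeline"]


@dataclass
class PipelineConfig:
    output_dir: str = "vesselforge_run"
    seed: int = 0
    # input: either a phantom spec or paths to image (+ optional label)
    phantom: PhantomSpec | None = None
    image_path: str | None = None
    label_path: str | None = None
    # segmentation: checkpoint to load, or train on the input phantom set
    model_path: str | None = None
    train_volumes: list = field(default_factory=list)  # extra (vol, label)
    seg_model: SegModelConfig | None = None
    seg_train: SegTrainConfig | None = None
    # surface + deformation stages
    target_vertices: int = 900
    smoothing: SmoothingWeights | None = None
    deform: DeformConfig | None = None
    open_caps_from_phantom: bool = True
    run_deform: bool = True
    run_metrics: bool = True

    def __post_init__(self):
        if self.phantom is None and self.image_path is None:
            raise ValueError("need either a phantom spec or an image path")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


def _open_phantom_caps(mesh: TriangleMesh, spec: PhantomSpec) -> TriangleMesh:
    """Clip the deformed-pipeline surface at the phantom's open cap planes."""
    keep = np.ones(mesh.n_faces, dtype=bool)
    centroids = mesh.vertices[mesh.faces].mean(axis=1)
    for c in spec.centerlines:
        ends = []
        if c.open_start:
            ends.append((c.points[0], -c.tangent_at(0.0), c.radii[0]))
        if c.open_end:
            ends.append((c.points[-1], c.tangent_at(1.0), c.radii[-1]))
        for p, t, r in ends:
            beyond = (centroids - p) @ t > 0.0
            near = np.linalg.norm(centroids - p, axis=1) < 1.6 * r + 1.0
            keep &= ~(beyond & near)
    faces = mesh.faces[keep]
    used = np.unique(faces)
    remap = -np.ones(mesh.n_vertices, dtype=int)
    remap[used] = np.arange(len(used))
    out = TriangleMesh(mesh.vertices[used], remap[faces])
    out.boundary_loops = out.find_boundary_loops()
    return out


def _prepare_case(config: PipelineConfig, out: Path, manifest: dict):
    """Load or synthesize the case; returns (image, label, gt_mesh, spec)."""
    if config.phantom is not None:
        image, label, gt_mesh = make_phantom(config.phantom)
        write_volume(image, out / "image.mha")
        write_volume(label, out / "label.mha")
        write_mesh(gt_mesh, out / "ground_truth.ply")
        return image, label, gt_mesh, config.phantom
    path = Path(config.image_path)
    if not path.exists():
        raise FileNotFoundError(
            f"stage=input: image path does not exist: {path}")
    image = read_volume(path)
    label = None
    if config.label_path:
        lpath = Path(config.label_path)
        if not lpath.exists():
            raise FileNotFoundError(
                f"stage=input: label path does not exist: {lpath}")
        label = read_volume(lpath, cls=LabelVolume)
    return image, label, None, None


def _get_model(config: PipelineConfig, norm: ScalarVolume,
               label: LabelVolume | None, manifest: dict):
    if config.model_path:
        return LoGBNet.load(config.model_path), None
    dataset = list(config.train_volumes)
    if label is not None:
        dataset.append((norm, label))
    if not dataset:
        raise ValueError("stage=segment: no checkpoint and no labeled data "
                         "to train on")
    seg_model = config.seg_model or tiny_model_config(
        seed=_stage_seed(config.seed, "model-init"))
    seg_train = config.seg_train or tiny_train_config(
        seed=_stage_seed(config.seed, "train"))
    model, history = train_segmenter(dataset, seg_model, seg_train)
    return model, history


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full image-to-mesh workflow; returns the artifact bundle.

    Bundle keys: probability, segmentation, initial_mesh, deformed_mesh,
    histories, metrics, manifest (with content hashes and per-stage seeds).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "artifacts": {}}
    bundle: dict = {"output_dir": str(out)}

    def finish_stage(name, t0, **extra):
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3),
                                    "seed": _stage_seed(config.seed, name),
                                    **extra}

    t0 = time.time()
    image, label, gt_mesh, spec = _prepare_case(config, out, manifest)
    finish_stage("input", t0)

    t0 = time.time()
    norm = clip_normalize(image)
    finish_stage("preprocess", t0)

    t0 = time.time()
    model, train_history = _get_model(config, norm, label, manifest)
    probs = predict_volume(model, norm, overlap=8)
    seg = LabelVolume((probs.values >= 0.5).astype(np.uint8),
                      probs.spacing.copy(), probs.origin.copy())
    write_volume(probs, out / "probability.mha")
    write_volume(seg, out / "segmentation.mha")
    bundle["probability"], bundle["segmentation"] = probs, seg
    bundle["train_history"] = train_history
    finish_stage("segment", t0)

    t0 = time.time()
    mesh = extract_isosurface(probs, level=0.5)
    mesh = remesh_uniform(mesh, config.target_vertices,
                          seed=_stage_seed(config.seed, "remesh"))
    mesh = smooth_mesh(mesh, config.smoothing or SmoothingWeights())
    if spec is not None and config.open_caps_from_phantom:
        mesh = _open_phantom_caps(mesh, spec)
    write_mesh(mesh, out / "initial_surface.ply")
    bundle["initial_mesh"] = mesh
    finish_stage("surface", t0)

    if config.run_deform:
        t0 = time.time()
        dconf = config.deform or DeformConfig(
            epochs=150, n_control=200,
            seed=_stage_seed(config.seed, "deform"))
        result = optimize_deformation(mesh, norm, dconf)
        write_mesh(result.mesh, out / "deformed_surface.ply")
        bundle["deformed_mesh"] = result.mesh
        bundle["deform_history"] = result.history
        finish_stage("deform", t0)

    if config.run_metrics and gt_mesh is not None:
        t0 = time.time()
        metrics = {
            "dice": compare_segmentations(seg, label).dice,
            "initial_asd": asd(mesh.vertices, gt_mesh.vertices),
            "initial_hausdorff": hausdorff(mesh.vertices, gt_mesh.vertices),
        }
        if config.run_deform:
            dm = bundle["deformed_mesh"]
            metrics["deformed_asd"] = asd(dm.vertices, gt_mesh.vertices)
            metrics["deformed_hausdorff"] = hausdorff(dm.vertices,
                                                      gt_mesh.vertices)
        (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
        bundle["metrics"] = metrics
        finish_stage("metrics", t0)

    for p in sorted(out.glob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["artifacts"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    bundle["manifest"] = manifest
    return bundle


def run_uq_pipeline(config: PipelineConfig, n_samples: int,
                    model: LoGBNet | None = None) -> dict:
    """Propagate segmentation uncertainty through surfaces and deformation.

    Draws ``n_samples`` posterior segmentations, builds a smoothed surface
    per member, deforms each with a shared configuration, and summarizes
    per-point SD for both ensembles against the mean (reference) surface.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 ensemble members")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    image, label, gt_mesh, spec = _prepare_case(config, out, {})
    norm = clip_normalize(image)
    if model is None:
        model, _ = _get_model(config, norm, label, {})
    member_seed0 = _stage_seed(config.seed, "uq-members")
    members, mean_prob, sd_vol = sample_segmentations(
        model, norm, n=n_samples, seed=member_seed0, overlap=8)

    ref_mesh = extract_isosurface(mean_prob, level=0.5)
    ref_mesh = remesh_uniform(ref_mesh, config.target_vertices,
                              seed=_stage_seed(config.seed, "remesh"))
    smoothing = config.smoothing or SmoothingWeights()
    ref_mesh = smooth_mesh(ref_mesh, smoothing)

    smoothed, deformed = [], []
    dconf = config.deform or DeformConfig(epochs=100, n_control=150,
                                          seed=_stage_seed(config.seed,
                                                           "deform"))
    for i, member in enumerate(members):
        m = extract_isosurface(
            ProbabilityVolume(member.values.astype(float), member.spacing,
                              member.origin), level=0.5)
        m = remesh_uniform(m, config.target_vertices,
                           seed=_stage_seed(config.seed, f"remesh-{i}"))
        m = smooth_mesh(m, smoothing)
        smoothed.append(m)
        if config.run_deform:
            res = optimize_deformation(m, norm, dconf)
            deformed.append(res.mesh)

    summary = {
        "member_seeds": [member_seed0 + i for i in range(n_samples)],
        "sd_volume": sd_vol,
        "smoothed": uq_summary([m.vertices for m in smoothed],
                               ref_mesh.vertices, image),
    }
    if deformed:
        summary["deformed"] = uq_summary([m.vertices for m in deformed],
                                         ref_mesh.vertices, image)
    manifest = {"seed": config.seed, "n_samples": n_samples,
                "member_seeds": summary["member_seeds"]}
    (out / "uq_manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"members": members, "mean_probability": mean_prob,
            "smoothed_meshes": smoothed, "deformed_meshes": deformed,
            "reference_mesh": ref_mesh, "summary": summary,
            "manifest": manifest}
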