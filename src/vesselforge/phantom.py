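"""Synthetic branched-vessel phantoms with ground-truth labels and surfaces.

The phantom stands in for contrast-enhanced CT angiography of the aorta and
its supra-aortic branches: a bright tubular lumen over a darker background,
Gaussian partial-volume blur, and additive noise.  Each phantom provides a
mutually consistent triple (intensity volume, binary label, lumen surface
mesh with open inlet/outlet caps), which is what every downstream module is
tested against.

Intensities are kept inside the 0-500 HU-like window that the preprocessing
stage later clips to; defaults are lumen 300 over background 50.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter, label as cc_label
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes
import trimesh as _trimesh

from .mesh import TriangleMesh
from .volume import LabelVolume, ScalarVolume

__all__ = [
    "Centerline",
    "PhantomSpec",
    "make_phantom",
    "add_branch",
    "voxelize_surface",
    "region_volume",
    "connected_component_count",
    "curved_vessel_spec",
    "straight_tube_spec",
]


@dataclass
class Centerline:
    """Polyline centerline in world mm with a per-point radius profile."""

    points: np.ndarray
    radii: np.ndarray
    open_start: bool = True
    open_end: bool = True

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.radii = np.broadcast_to(
            np.asarray(self.radii, dtype=float), (len(self.points),)).copy()
        if np.any(self.radii <= 0):
            raise ValueError("centerline radii must be positive")

    def arclength(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def resample(self, step: float) -> "Centerline":
        s = self.arclength()
        n = max(int(np.ceil(s[-1] / step)) + 1, 2)
        si = np.linspace(0, s[-1], n)
        pts = np.column_stack([np.interp(si, s, self.points[:, c]) for c in range(3)])
        rad = np.interp(si, s, self.radii)
        return Centerline(pts, rad, self.open_start, self.open_end)

    def point_at(self, t: float) -> np.ndarray:
        """Point at normalized arclength t in [0, 1]."""
        s = self.arclength()
        si = t * s[-1]
        return np.array([np.interp(si, s, self.points[:, c]) for c in range(3)])

    def tangent_at(self, t: float) -> np.ndarray:
        s = self.arclength()
        si = np.clip(t * s[-1], s[0], s[-1])
        i = min(np.searchsorted(s, si), len(s) - 1)
        i = max(i, 1)
        d = self.points[i] - self.points[i - 1]
        return d / np.linalg.norm(d)

    def radius_at(self, t: float) -> float:
        s = self.arclength()
        return float(np.interp(t * s[-1], s, self.radii))


@dataclass
class PhantomSpec:
    grid_shape: tuple = (64, 64, 64)
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)
    centerlines: list = field(default_factory=list)
    lumen_intensity: float = 300.0
    background_intensity: float = 50.0
    blur_sigma: float = 1.0
    noise_sd: float = 15.0
    # optional linear noise grading along one axis: (axis, sd_at_low, sd_at_high)
    noise_gradient: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.background_intensity < self.lumen_intensity <= 500):
            raise ValueError(
                "require 0 <= background < lumen <= 500 pre-noise intensity")

    # ------------------------------------------------------------- config
    def to_dict(self) -> dict:
        d = asdict(self)
        d["centerlines"] = [
            {"points": c.points.tolist(), "radii": c.radii.tolist(),
             "open_start": c.open_start, "open_end": c.open_end}
            for c in self.centerlines]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        d["centerlines"] = [Centerline(np.array(c["points"]), np.array(c["radii"]),
                                       c.get("open_start", True),
                                       c.get("open_end", True))
                            for c in d["centerlines"]]
        for key in ("grid_shape", "spacing", "origin"):
            d[key] = tuple(d[key])
        if d.get("noise_gradient") is not None:
            d["noise_gradient"] = tuple(d["noise_gradient"])
        return cls(**d)

    def save(self, path):
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def load(cls, path) -> "PhantomSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    # ----------------------------------------------------------- geometry
    def bounds(self):
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + (np.array(self.grid_shape) - 1) * np.array(self.spacing)
        return lo, hi

    def _check_inside(self):
        """The whole tube (centerline +- local radius) must stay inside the
        grid, otherwise marching cubes truncates the surface open at the
        volume border."""
        lo, hi = self.bounds()
        for c in self.centerlines:
            r = c.radii[:, None]
            if np.any(c.points - r < lo) or np.any(c.points + r > hi):
                raise ValueError("centerline (or its tube) exits the grid")


# ----------------------------------------------------------------- builders
def straight_tube_spec(grid_shape=(64, 64, 64), spacing=(1, 1, 1),
                       radius=5.0, axis=2, **kw) -> PhantomSpec:
    """Straight tube along one axis, margin chosen so the caps stay inside."""
    shape = np.array(grid_shape)
    sp = np.array(spacing, dtype=float)
    center = (shape - 1) * sp / 2.0
    margin = radius + 2.0 * sp[axis]   # keep the rounded ends inside
    p0, p1 = center.copy(), center.copy()
    p0[axis] = margin
    p1[axis] = (shape[axis] - 1) * sp[axis] - margin
    line = Centerline(np.linspace(p0, p1, 16), np.full(16, float(radius)))
    return PhantomSpec(grid_shape=tuple(grid_shape), spacing=tuple(spacing),
                       centerlines=[line], **kw)


def curved_vessel_spec(grid_shape=(64, 64, 64), spacing=(1, 1, 1),
                       radius=7.0, bend=0.18, n_branches=0, seed=0,
                       **kw) -> PhantomSpec:
    """Gently curved main vessel (aorta-like arc), optionally with branches."""
    shape = np.array(grid_shape)
    sp = np.array(spacing, dtype=float)
    extent = (shape - 1) * sp
    zmargin = radius + 2.0 * sp[2]     # keep the rounded ends inside
    z = np.linspace(zmargin, extent[2] - zmargin, 32)
    xc = extent[0] / 2 + bend * extent[0] * np.sin(np.pi * (z - z[0]) / (z[-1] - z[0]))
    yc = np.full_like(z, extent[1] / 2)
    main = Centerline(np.column_stack([xc, yc, z]), np.full(len(z), float(radius)))
    spec = PhantomSpec(grid_shape=tuple(grid_shape), spacing=tuple(spacing),
                       centerlines=[main], seed=seed, **kw)
    rng = np.random.default_rng(seed)
    for b in range(n_branches):
        t = 0.3 + 0.4 * (b + 1) / (n_branches + 1)
        br = max(2.5, 0.36 * radius)
        # re-draw the take-off direction until the branch fits cleanly;
        # retries drift toward a perpendicular take-off (clears the parent
        # fastest per unit length) and widen the azimuth search
        for attempt in range(18):
            angle = min(55.0 + 15 * rng.random() + 3.0 * attempt, 90.0)
            spread = 50.0 if attempt < 6 else 360.0
            azimuth = 90.0 + 180.0 * b + spread * (rng.random() - 0.5)
            need = (radius + 1.6 * br + 4.0) / np.sin(np.radians(angle))
            desired = max(0.30 * float(np.min(extent)), need)
            length = _feasible_branch_length(
                spec, parent=0, takeoff=t, angle=angle, azimuth=azimuth,
                radius=br, desired=desired)
            try:
                spec = add_branch(spec, parent=0, takeoff=t, angle=angle,
                                  azimuth=azimuth, radius=br, length=length)
                break
            except ValueError:
                continue
        else:
            raise ValueError(
                f"could not place branch {b} inside the grid; enlarge the "
                f"grid or reduce the main radius")
    return spec


def _branch_direction(pc: Centerline, takeoff: float, angle: float,
                      azimuth: float) -> tuple:
    """(takeoff point, unit direction) for a branch leaving the parent."""
    p = pc.point_at(takeoff)
    t = pc.tangent_at(takeoff)
    a = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(a, t)) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    n1 = np.cross(t, a)
    n1 /= np.linalg.norm(n1)
    n2 = np.cross(t, n1)
    ang, az = np.radians(angle), np.radians(azimuth)
    direction = (np.cos(ang) * t
                 + np.sin(ang) * (np.cos(az) * n1 + np.sin(az) * n2))
    return p, direction


def _feasible_branch_length(spec: PhantomSpec, parent: int, takeoff: float,
                            angle: float, azimuth: float, radius: float,
                            desired: float) -> float:
    """Longest straight run (capped at ``desired``) keeping the tube inside."""
    pc = spec.centerlines[parent]
    p, direction = _branch_direction(pc, takeoff, angle, azimuth)
    lo, hi = spec.bounds()
    tmax = desired
    for c in range(3):
        if direction[c] > 1e-9:
            tmax = min(tmax, (hi[c] - radius - 1.0 - p[c]) / direction[c])
        elif direction[c] < -1e-9:
            tmax = min(tmax, (lo[c] + radius + 1.0 - p[c]) / direction[c])
    return max(tmax, 0.0)


def add_branch(spec: PhantomSpec, parent: int = 0, takeoff: float = 0.5,
               angle: float = 60.0, azimuth: float = 0.0,
               radius: float = 4.0, length: float = 20.0) -> PhantomSpec:
    """Append a straight branch leaving the parent centerline.

    ``takeoff`` is the normalized arclength along the parent; ``angle`` (deg)
    is measured from the parent tangent and ``azimuth`` (deg) rotates the
    branch around it.  Returns a new spec; the parent is unchanged.
    """
    pc = spec.centerlines[parent]
    if radius > pc.radius_at(takeoff):
        warnings.warn("branch radius exceeds parent radius at the takeoff point")
    p, direction = _branch_direction(pc, takeoff, angle, azimuth)
    pts = p[None] + np.linspace(0, length, 12)[:, None] * direction[None]
    branch = Centerline(pts, np.full(12, float(radius)),
                        open_start=False, open_end=True)
    new = PhantomSpec(**{**spec.to_dict(), "centerlines": []})
    new.centerlines = list(spec.centerlines) + [branch]
    lo, hi = new.bounds()
    r = branch.radii[:, None]
    if np.any(branch.points - r < lo) or np.any(branch.points + r > hi):
        raise ValueError("branch (or its tube) exits the grid")
    # the branch may touch the parent only in one connected junction at its
    # root; separating and re-touching would fuse into a topological handle
    parent_r = pc.radius_at(takeoff)
    samples = branch.resample(0.5).points
    d_par, _ = cKDTree(pc.resample(0.5).points).query(samples)
    touching = d_par < parent_r + radius + 1.0   # 1 voxel merge safety
    detached = np.where(~touching)[0]
    if len(detached) == 0:
        raise ValueError("branch is entirely buried in the parent vessel")
    if np.any(touching[detached[0]:]):
        raise ValueError("branch re-enters the parent vessel")
    # the open-end cap is clipped within a (1.6*radius + 1) ball of the
    # endpoint, so neither the parent wall nor other branches may sit there
    clip = 1.6 * radius + 2.0
    if d_par[-1] < parent_r + clip:
        raise ValueError("branch end sits too close to the parent vessel")
    outside = d_par > parent_r  # root samples buried in the parent are fine
    for j, other in enumerate(spec.centerlines):
        if j == parent:
            continue
        d_o, _ = cKDTree(other.resample(0.5).points).query(samples)
        if np.any(d_o[outside] < other.radii.max() + radius + 1.0):
            raise ValueError("branch collides with another centerline")
    return new


# --------------------------------------------------------------- generation
def _signed_field(spec: PhantomSpec, return_ids: bool = False):
    """r_local - distance_to_centerline on the voxel grid (positive inside)."""
    spec._check_inside()
    if not spec.centerlines:
        raise ValueError("phantom spec has no centerlines")
    step = 0.25 * float(np.min(spec.spacing))
    shape = spec.grid_shape
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    centers = (np.asarray(spec.origin)
               + np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
               * np.asarray(spec.spacing, dtype=float))
    # union of tubes: per-centerline signed value, then the max over tubes
    f = np.full(centers.shape[0], -np.inf)
    ids = np.zeros(centers.shape[0], dtype=int)
    for ci, c in enumerate(spec.centerlines):
        cs = c.resample(step)
        d, nearest = cKDTree(cs.points).query(centers, workers=-1)
        fc = cs.radii[nearest] - d
        better = fc > f
        f[better] = fc[better]
        ids[better] = ci
    f = f.reshape(shape)
    if return_ids:
        return f, ids.reshape(shape)
    return f


def _extract_gt_mesh(spec: PhantomSpec, f: np.ndarray) -> TriangleMesh:
    sp = np.asarray(spec.spacing, dtype=float)
    # mild smoothing welds sub-voxel tunnels that the trilinear interpolant
    # develops in the branch-junction crotch (they would add spurious genus);
    # the surface shift is well below half a voxel
    fs = gaussian_filter(f, 0.7, mode="nearest")
    if fs.max() <= 0:  # very thin tubes: smoothing can erase the interior
        fs = f
    verts, faces, _, _ = marching_cubes(fs, level=0.0, spacing=tuple(sp))
    verts = verts + np.asarray(spec.origin, dtype=float)
    tm = _trimesh.Trimesh(verts, faces, process=True)
    _trimesh.repair.fix_normals(tm)
    if tm.volume < 0:
        tm.invert()
    verts, faces = np.asarray(tm.vertices), np.asarray(tm.faces)
    # open the designated inlet/outlet caps: drop faces beyond the end planes
    keep = np.ones(len(faces), dtype=bool)
    centroids = verts[faces].mean(axis=1)
    for ci, c in enumerate(spec.centerlines):
        ends = []
        if c.open_start:
            ends.append((c.points[0], -c.tangent_at(0.0), c.radii[0]))
        if c.open_end:
            ends.append((c.points[-1], c.tangent_at(1.0), c.radii[-1]))
        for p, t, r in ends:
            beyond = (centroids - p) @ t > 0.0
            near = np.linalg.norm(centroids - p, axis=1) < 1.6 * r + 1.0
            keep &= ~(beyond & near)   # local clip: open only this cap
    faces = faces[keep]
    used = np.unique(faces)
    remap = -np.ones(len(verts), dtype=int)
    remap[used] = np.arange(len(used))
    mesh = TriangleMesh(verts[used], remap[faces])
    mesh.boundary_loops = mesh.find_boundary_loops()
    return mesh


def make_phantom(spec: PhantomSpec):
    """Generate (image, label, ground-truth surface) for a phantom spec.

    The label is the exact tube indicator (distance to nearest centerline
    sample < local radius); the image is the blurred two-level field plus
    seeded Gaussian noise; the mesh is the lumen isosurface of the noise-free
    field with the inlet/outlet caps opened.
    """
    f = _signed_field(spec)
    label = (f > 0).astype(np.uint8)
    clean = np.where(label > 0, spec.lumen_intensity, spec.background_intensity
                     ).astype(float)
    if spec.blur_sigma > 0:
        clean = gaussian_filter(clean, spec.blur_sigma, mode="nearest")
    rng = np.random.default_rng(spec.seed)
    if spec.noise_gradient is not None:
        axis, sd0, sd1 = spec.noise_gradient
        axis = int(axis)
        n = spec.grid_shape[axis]
        profile = np.linspace(sd0, sd1, n)
        shape = [1, 1, 1]
        shape[axis] = n
        sd_field = profile.reshape(shape)
        noise = rng.standard_normal(spec.grid_shape) * sd_field
    elif spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, spec.grid_shape)
    else:
        noise = 0.0
    image = clean + noise
    sp, org = np.asarray(spec.spacing, dtype=float), np.asarray(spec.origin,
                                                                dtype=float)
    vol = ScalarVolume(image, sp, org)
    lab = LabelVolume(label, sp, org)
    mesh = _extract_gt_mesh(spec, f)
    return vol, lab, mesh


def region_volume(spec: PhantomSpec) -> ScalarVolume:
    """Per-voxel region id volume: 0 background, 1 + centerline index inside.

    Used for the main-vessel / branch breakdown of the quality metrics.
    """
    f, ids = _signed_field(spec, return_ids=True)
    regions = np.where(f > 0, ids + 1, 0).astype(np.uint8)
    return ScalarVolume(regions, np.asarray(spec.spacing, dtype=float),
                        np.asarray(spec.origin, dtype=float))


def connected_component_count(label: LabelVolume) -> int:
    _, n = cc_label(label.values)
    return int(n)


# -------------------------------------------------------------- voxelization
def voxelize_surface(mesh: TriangleMesh, template: ScalarVolume) -> LabelVolume:
    """Hole-filling voxelization of a closed surface mesh.

    For every voxel center the nearest surface mesh vertex is found; the
    voxel is inside when the angle between that vertex's outward normal and
    the vector from the voxel to the vertex is strictly below 90 degrees
    (ties classify outside).  Vertex normals are area-weighted averages of
    incident face normals; inconsistent orientations are repaired first.
    """
    if not mesh.is_watertight:
        raise ValueError(
            "voxelize_surface needs a closed mesh; fill caps first")
    tm = mesh.to_trimesh()
    _trimesh.repair.fix_normals(tm)
    if tm.volume < 0:
        tm.invert()
    fixed = TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
    normals = fixed.vertex_normals()
    tree = cKDTree(fixed.vertices)
    shape = template.shape
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    centers = template.index_to_world(
        np.stack([ii, jj, kk], axis=-1).reshape(-1, 3))
    _, nearest = tree.query(centers, workers=-1)
    to_vertex = fixed.vertices[nearest] - centers
    inside = np.einsum("ij,ij->i", normals[nearest], to_vertex) > 0.0
    return LabelVolume(inside.reshape(shape).astype(np.uint8),
                       template.spacing.copy(), template.origin.copy())
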