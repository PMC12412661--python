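"""Triangle surface meshes in world mm, with STL/PLY/VTP I/O.

The mesh is the central geometric object of the pipeline: the initial lumen
surface extracted from a segmentation and every deformed iterate of it.
Vertices live in physical (mm) coordinates; faces are oriented consistently
with outward normals for closed surfaces.  Inlet/outlet openings are plain
boundary loops and can be carried explicitly so that the deformation's
scaling gate knows where the vessel was truncated.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

__all__ = ["TriangleMesh", "read_mesh", "write_mesh"]


@dataclass
class TriangleMesh:
    vertices: np.ndarray
    faces: np.ndarray
    boundary_loops: list = field(default_factory=list)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=int).reshape(-1, 3)
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")
        if len(self.faces):
            f = self.faces
            if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2])
                      | (f[:, 0] == f[:, 2])):
                raise ValueError("degenerate face repeats a vertex")

    # ------------------------------------------------------------- basics
    @property
    def n_vertices(self):
        return len(self.vertices)

    @property
    def n_faces(self):
        return len(self.faces)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(),
                            [list(l) for l in self.boundary_loops])

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(),
                               process=False)

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh) -> "TriangleMesh":
        m = cls(np.asarray(tm.vertices), np.asarray(tm.faces))
        m.boundary_loops = m.find_boundary_loops()
        return m

    # ------------------------------------------------------------ topology
    def edges_unique(self):
        """(E, 2) sorted unique undirected edges."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                       self.faces[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def edge_face_incidence(self):
        """dict sorted-edge -> list of incident face indices."""
        inc: dict = {}
        for fi, f in enumerate(self.faces):
            for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                key = (a, b) if a < b else (b, a)
                inc.setdefault(key, []).append(fi)
        return inc

    def interior_edges(self):
        """(M, 2) edges shared by exactly two faces, plus the face pairs (M, 2)."""
        inc = self.edge_face_incidence()
        edges, pairs = [], []
        for e, fs in inc.items():
            if len(fs) == 2:
                edges.append(e)
                pairs.append(fs)
        return np.array(edges, dtype=int).reshape(-1, 2), \
            np.array(pairs, dtype=int).reshape(-1, 2)

    def boundary_edges(self):
        inc = self.edge_face_incidence()
        return np.array([e for e, fs in inc.items() if len(fs) == 1],
                        dtype=int).reshape(-1, 2)

    def find_boundary_loops(self) -> list:
        """Ordered vertex cycles of the open boundary (inlets/outlets)."""
        be = self.boundary_edges()
        if len(be) == 0:
            return []
        adj: dict = {}
        for a, b in be:
            adj.setdefault(a, []).append(b)
            adj.setdefault(b, []).append(a)
        loops, seen = [], set()
        for start in adj:
            if start in seen:
                continue
            loop, prev, cur = [start], None, start
            seen.add(start)
            while True:
                nxts = [v for v in adj[cur] if v != prev and v not in seen]
                if not nxts:
                    break
                prev, cur = cur, nxts[0]
                seen.add(cur)
                loop.append(cur)
            if len(loop) >= 3:
                loops.append(loop)
        return loops

    @property
    def is_watertight(self) -> bool:
        return len(self.boundary_edges()) == 0

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges_unique()) + self.n_faces

    # ------------------------------------------------------------ geometry
    def face_normals(self, normalized: bool = True) -> np.ndarray:
        v = self.vertices
        f = self.faces
        n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        if normalized:
            norms = np.linalg.norm(n, axis=1, keepdims=True)
            n = n / np.maximum(norms, 1e-30)
        return n

    def face_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.face_normals(normalized=False), axis=1)

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted average of incident face normals, unit length."""
        fn = self.face_normals(normalized=False)  # magnitude = 2*area
        vn = np.zeros_like(self.vertices)
        for c in range(3):
            np.add.at(vn, self.faces[:, c], fn)
        norms = np.linalg.norm(vn, axis=1, keepdims=True)
        return vn / np.maximum(norms, 1e-30)

    def edge_lengths(self) -> np.ndarray:
        e = self.edges_unique()
        return np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]],
                              axis=1)

    # ---------------------------------------------------------- operations
    def fill_caps(self) -> "TriangleMesh":
        """Close every boundary loop with a fan from the loop centroid.

        Fan orientation is chosen per cap so the new faces point away from
        the mesh interior (consistent with outward orientation).
        """
        loops = self.boundary_loops or self.find_boundary_loops()
        if not loops:
            return self.copy()
        verts = [self.vertices]
        faces = [self.faces]
        nv = self.n_vertices
        interior_ref = self.vertices.mean(axis=0)
        for loop in loops:
            center = self.vertices[loop].mean(axis=0)
            verts.append(center[None])
            new = []
            for a, b in zip(loop, loop[1:] + loop[:1]):
                new.append([a, b, nv])
            new = np.array(new, dtype=int)
            # orient cap outward: normal should point away from the mesh centroid
            va, vb = self.vertices[new[0, 0]], self.vertices[new[0, 1]]
            n = np.cross(vb - va, center - va)
            if np.dot(n, center - interior_ref) < 0:
                new = new[:, [1, 0, 2]]
            faces.append(new)
            nv += 1
        out = TriangleMesh(np.vstack(verts), np.vstack(faces))
        return out


# ------------------------------------------------------------------------ I/O
_MESH_SUFFIXES = (".stl", ".ply", ".vtp")


def read_mesh(path, triangulate: bool = True) -> TriangleMesh:
    """Read an STL, PLY, or VTP surface mesh.

    STL soups are merged to shared vertices (tolerance ~1e-6 mm via trimesh's
    vertex merging).  Polygonal faces are fan-triangulated when
    ``triangulate`` is set, otherwise a non-triangular file raises.
    """
    path = Path(path)
    if path.suffix.lower() not in _MESH_SUFFIXES:
        raise ValueError(f"unsupported mesh format: {path.suffix}")
    if path.suffix.lower() == ".vtp":
        verts, polys = _read_vtp(path)
    else:
        tm = trimesh.load(str(path), force="mesh")
        verts, polys = np.asarray(tm.vertices), [list(f) for f in tm.faces]
    if len(verts) == 0 or len(polys) == 0:
        raise ValueError(f"empty mesh in {path}")
    faces = []
    for p in polys:
        if len(p) == 3:
            faces.append(p)
        elif triangulate:
            for i in range(1, len(p) - 1):
                faces.append([p[0], p[i], p[i + 1]])
        else:
            raise ValueError("non-triangular face and triangulate=False")
    mesh = TriangleMesh(verts, np.array(faces, dtype=int))
    mesh.boundary_loops = mesh.find_boundary_loops()
    return mesh


def write_mesh(mesh: TriangleMesh, path) -> None:
    path = Path(path)
    if path.suffix.lower() not in _MESH_SUFFIXES:
        raise ValueError(f"unsupported mesh format: {path.suffix}")
    if mesh.n_faces == 0:
        raise ValueError("refusing to write an empty mesh")
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".vtp":
        _write_vtp(mesh, path)
    else:
        mesh.to_trimesh().export(str(path))


def _read_vtp(path) -> tuple:
    """Minimal ASCII VTK XML PolyData reader (points + polys)."""
    root = ET.parse(str(path)).getroot()
    piece = root.find(".//Piece")
    pts_da = piece.find("./Points/DataArray")
    if pts_da.get("format", "ascii") != "ascii":
        raise IOError("only ASCII VTP files are supported")
    pts = np.fromstring(pts_da.text, sep=" ").reshape(-1, 3)
    polys = piece.find("./Polys")
    conn = offs = None
    for da in polys.findall("DataArray"):
        arr = np.fromstring(da.text, sep=" ").astype(int)
        if da.get("Name") == "connectivity":
            conn = arr
        elif da.get("Name") == "offsets":
            offs = arr
    faces, start = [], 0
    for end in offs:
        faces.append(list(conn[start:end]))
        start = end
    return pts, faces


def _write_vtp(mesh: TriangleMesh, path) -> None:
    v, f = mesh.vertices, mesh.faces
    pts = " ".join(f"{x:.9g}" for x in v.ravel())
    conn = " ".join(str(i) for i in f.ravel())
    offs = " ".join(str(3 * (i + 1)) for i in range(len(f)))
    xml = (
        '<?xml version="1.0"?>\n'
        '<VTKFile type="PolyData" version="0.1" byte_order="LittleEndian">\n'
        f'<PolyData><Piece NumberOfPoints="{len(v)}" NumberOfPolys="{len(f)}">\n'
        '<Points><DataArray type="Float64" NumberOfComponents="3" format="ascii">\n'
        f'{pts}\n</DataArray></Points>\n'
        '<Polys><DataArray type="Int64" Name="connectivity" format="ascii">\n'
        f'{conn}\n</DataArray>\n'
        '<DataArray type="Int64" Name="offsets" format="ascii">\n'
        f'{offs}\n</DataArray></Polys>\n'
        '</Piece></PolyData></VTKFile>\n'
    )
    Path(path).write_text(xml)
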