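"""Labelled triangular-mesh source spaces.

The source space of each generative model is a set of closed triangular
meshes — a cortical shell plus small ellipsoidal deep structures (bilateral
hippocampus and amygdala) — in a head-centred coordinate frame:
millimetres, +x right, +y anterior, +z superior.  Sources live at mesh
vertices and are oriented along the outward vertex normal.

The synthetic anatomy is a deliberately simplified stand-in for
MRI-derived segmentations: a deformed-sphere cortex and ellipsoidal deep
structures preserve the size, depth and neighbour relations that make the
deep-source inverse problem hard, without requiring anatomical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import trimesh as _trimesh

REGION_LABELS = (
    "cortex",
    "hippocampus_L",
    "hippocampus_R",
    "amygdala_L",
    "amygdala_R",
)

#: displacement axes in the head frame (+y anterior, +z superior)
AXES = {
    "AP": np.array([0.0, 1.0, 0.0]),
    "IS": np.array([0.0, 0.0, 1.0]),
    "LR": np.array([1.0, 0.0, 0.0]),
}


class GeometryError(ValueError):
    """Raised for invalid or inconsistent mesh geometry."""


@dataclass
class TriMesh:
    """A labelled triangular surface mesh.

    vertices : (Nv, 3) float64, mm, head frame
    faces    : (Nf, 3) int, 0-based vertex indices, outward winding
    label    : region name (one of REGION_LABELS)
    """

    vertices: np.ndarray
    faces: np.ndarray
    label: str

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise GeometryError("vertices must be (Nv, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise GeometryError("faces must be (Nf, 3)")
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise GeometryError(
                    f"face index out of range [0, {len(self.vertices)}) "
                    f"in mesh '{self.label}'"
                )
            f = self.faces
            if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
                raise GeometryError(f"degenerate face in mesh '{self.label}'")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def copy(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.faces.copy(), self.label)


@dataclass
class MeshStats:
    vertex_count: int
    mean_edge_length: float
    volume: float  # signed, mm^3, divergence theorem


@dataclass
class AnatomicalModel:
    """Ordered set of labelled meshes with a global vertex index.

    Global source index ``i`` maps to ``(mesh label, local vertex index)``
    via :attr:`region_of_vertex`; indices are contiguous blocks in mesh
    order and partition the union of all mesh vertices.
    """

    meshes: list[TriMesh]
    model_name: str = "HA"
    region_of_vertex: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self):
        if not self.region_of_vertex:
            self.region_of_vertex = [
                (m.label, j) for m in self.meshes for j in range(m.n_vertices)
            ]
        if len(self.region_of_vertex) != self.n_vertices:
            raise GeometryError("region map does not partition the vertex set")

    @property
    def n_vertices(self) -> int:
        return sum(m.n_vertices for m in self.meshes)

    @property
    def labels(self) -> list[str]:
        return [m.label for m in self.meshes]

    def mesh(self, label: str) -> TriMesh:
        for m in self.meshes:
            if m.label == label:
                return m
        raise KeyError(f"no mesh labelled '{label}'")

    def vertex_slice(self, label: str) -> slice:
        """Global-index slice of the vertices of one mesh."""
        start = 0
        for m in self.meshes:
            if m.label == label:
                return slice(start, start + m.n_vertices)
            start += m.n_vertices
        raise KeyError(f"no mesh labelled '{label}'")

    def global_indices(self, labels: Sequence[str]) -> np.ndarray:
        return np.concatenate(
            [np.arange(self.vertex_slice(l).start, self.vertex_slice(l).stop)
             for l in labels]
        )

    @property
    def all_vertices(self) -> np.ndarray:
        return np.vstack([m.vertices for m in self.meshes])

    def submodel(self, labels: Sequence[str], name: str) -> "AnatomicalModel":
        """Model restricted to a subset of meshes (used by EBB variants)."""
        return AnatomicalModel([self.mesh(l).copy() for l in labels], name)

    def copy(self) -> "AnatomicalModel":
        return AnatomicalModel([m.copy() for m in self.meshes], self.model_name)


# ---------------------------------------------------------------------------
# mesh measures


def mesh_stats(mesh: TriMesh) -> MeshStats:
    return MeshStats(mesh.n_vertices, mean_edge_length(mesh), signed_volume(mesh))


def mean_edge_length(mesh: TriMesh) -> float:
    f = mesh.faces
    e = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    e = np.unique(np.sort(e, axis=1), axis=0)
    d = mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]]
    return float(np.linalg.norm(d, axis=1).mean())


def signed_volume(mesh: TriMesh) -> float:
    """Signed enclosed volume via the divergence theorem (positive for
    outward winding)."""
    v = mesh.vertices
    a, b, c = v[mesh.faces[:, 0]], v[mesh.faces[:, 1]], v[mesh.faces[:, 2]]
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def vertex_normals(mesh: TriMesh) -> np.ndarray:
    """Area-weighted outward unit vertex normals.

    The cross product of face edges is twice the face area times the face
    normal, so accumulating raw cross products at each vertex gives the
    area weighting for free.
    """
    v, f = mesh.vertices, mesh.faces
    fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    out = np.zeros_like(v)
    for k in range(3):
        np.add.at(out, f[:, k], fn)
    norms = np.linalg.norm(out, axis=1)
    if np.any(norms == 0):
        bad = int(np.flatnonzero(norms == 0)[0])
        raise GeometryError(
            f"vertex {bad} of mesh '{mesh.label}' has no adjacent face"
        )
    return out / norms[:, None]


def displace_mesh(mesh: TriMesh, axis: np.ndarray, distance: float) -> TriMesh:
    """Rigidly translate a mesh by ``distance`` mm along a unit ``axis``.

    Vertices move; faces, winding and label are untouched (no remeshing),
    so edge lengths, normals and signed volume are preserved exactly.
    """
    axis = np.asarray(axis, dtype=np.float64)
    if axis.shape != (3,) or not np.isclose(np.linalg.norm(axis), 1.0, atol=1e-8):
        raise ValueError("displacement axis must be a unit 3-vector")
    return TriMesh(mesh.vertices + distance * axis, mesh.faces.copy(), mesh.label)


def displace_deep_meshes(model: AnatomicalModel, axis: np.ndarray,
                         distance: float) -> AnatomicalModel:
    """Translate every non-cortical mesh; the cortex stays fixed."""
    meshes = [m.copy() if m.label == "cortex" else displace_mesh(m, axis, distance)
              for m in model.meshes]
    return AnatomicalModel(meshes, model.model_name)


def points_inside_surface(points: np.ndarray, surface: TriMesh) -> np.ndarray:
    """Point-in-closed-surface test via the generalized winding number.

    The summed signed solid angle of all faces seen from a point is 4π
    inside a closed outward-wound surface and 0 outside (van Oosterom &
    Strackee solid-angle formula per triangle); robust to rays grazing
    edges, unlike crossing-parity ray casts.
    """
    points = np.atleast_2d(np.asarray(points, float))
    v, f = surface.vertices, surface.faces
    w = np.zeros(len(points))
    # chunk over faces to bound memory
    for k0 in range(0, len(f), 2048):
        fk = f[k0:k0 + 2048]
        a = v[fk[:, 0]][None] - points[:, None]   # (Np, Nf, 3)
        b = v[fk[:, 1]][None] - points[:, None]
        c = v[fk[:, 2]][None] - points[:, None]
        la = np.linalg.norm(a, axis=2)
        lb = np.linalg.norm(b, axis=2)
        lc = np.linalg.norm(c, axis=2)
        num = np.einsum("pfi,pfi->pf", a, np.cross(b, c))
        den = (la * lb * lc + np.einsum("pfi,pfi->pf", a, b) * lc
               + np.einsum("pfi,pfi->pf", b, c) * la
               + np.einsum("pfi,pfi->pf", a, c) * lb)
        w += 2.0 * np.arctan2(num, den).sum(axis=1)
    return w > 2.0 * np.pi


# ---------------------------------------------------------------------------
# synthetic anatomy


@dataclass
class GeometryConfig:
    """Parameters of the synthetic desk-scale head.

    The head is a uniformly scaled-down model (~0.42 of adult linear
    dimensions) so that a realistically fine mesh resolution (mean edge
    ~4.5 mm cortex / ~3.5 mm hippocampus) coexists with a small source
    count; relative depths and structure sizes are preserved.
    """

    cortex_radius: float = 32.0          # mm, mean shell radius
    cortex_bumpiness: float = 6.0        # mm, radial deformation amplitude
    cortex_n_bumps: int = 24
    cortex_edge_target: float = 4.5      # mm
    deep_edge_target: float = 3.5        # mm
    # semi-axes (x, y, z) mm and centres; hippocampus elongated along A-P
    hippocampus_axes: tuple = (3.4, 9.5, 3.6)
    amygdala_axes: tuple = (3.2, 3.6, 3.0)
    hippocampus_center: tuple = (13.0, -5.0, -8.0)
    amygdala_center: tuple = (13.0, 6.5, -9.0)
    include_deep: bool = True


def _icosphere(subdiv: int) -> tuple[np.ndarray, np.ndarray]:
    m = _trimesh.creation.icosphere(subdivisions=subdiv, radius=1.0)
    return np.asarray(m.vertices, float), np.asarray(m.faces, np.int64)


def _fit_subdivision(map_fn, target_edge: float, label: str,
                     max_subdiv: int = 5) -> TriMesh:
    """Pick the icosphere subdivision whose mapped mean edge is closest to
    the target."""
    best = None
    for n in range(max_subdiv + 1):
        uv, uf = _icosphere(n)
        mesh = TriMesh(map_fn(uv), uf, label)
        err = abs(mean_edge_length(mesh) - target_edge)
        if best is None or err < best[0]:
            best = (err, mesh)
    return best[1]


def _ellipsoid_mesh(axes, center, label, target_edge) -> TriMesh:
    """Inscribed icosphere mapped to the ellipsoid, then rescaled about its
    centre so the enclosed mesh volume equals the analytic 4/3·π·abc (a
    coarse inscribed polyhedron otherwise underestimates the volume)."""
    axes = np.asarray(axes, float)
    center = np.asarray(center, float)
    mesh = _fit_subdivision(lambda u: u * axes + center, target_edge, label)
    target_vol = 4.0 / 3.0 * np.pi * np.prod(axes)
    scale = (target_vol / signed_volume(
        TriMesh(mesh.vertices - center, mesh.faces, label))) ** (1.0 / 3.0)
    return TriMesh((mesh.vertices - center) * scale + center, mesh.faces, label)


def build_synthetic_anatomy(config: GeometryConfig | None = None,
                            seed: int = 0) -> AnatomicalModel:
    """Construct the synthetic labelled source space.

    The cortex is a closed deformed-sphere shell (seeded sum of Gaussian
    bumps on the sphere — the deformation is what gives cortical sources a
    tangential dipole component in the spherical conductor); the four deep
    structures are ellipsoids at medio-temporal positions, strictly inside
    the cortical surface.  Deterministic given ``seed``.
    """
    config = config or GeometryConfig()
    if config.cortex_radius <= 0:
        raise GeometryError("cortex_radius must be positive")
    rng = np.random.default_rng(seed)

    # bump field: smooth seeded radial perturbation of the sphere
    centers = rng.normal(size=(config.cortex_n_bumps, 3))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    amps = rng.uniform(-1.0, 1.0, config.cortex_n_bumps) * config.cortex_bumpiness
    kappa = 12.0  # angular bump concentration; broad enough to tilt normals

    def map_cortex(u):
        r = config.cortex_radius + (
            amps[None, :] * np.exp(kappa * (u @ centers.T - 1.0))
        ).sum(axis=1)
        return u * r[:, None]

    cortex = _fit_subdivision(map_cortex, config.cortex_edge_target, "cortex")
    meshes = [cortex]

    if config.include_deep:
        specs = [
            ("hippocampus_L", config.hippocampus_axes, config.hippocampus_center, -1),
            ("hippocampus_R", config.hippocampus_axes, config.hippocampus_center, +1),
            ("amygdala_L", config.amygdala_axes, config.amygdala_center, -1),
            ("amygdala_R", config.amygdala_axes, config.amygdala_center, +1),
        ]
        for label, axes, center, side in specs:
            if np.any(np.asarray(axes) <= 0):
                raise GeometryError(f"{label}: semi-axes must be positive")
            c = np.asarray(center, float) * np.array([side, 1.0, 1.0])
            mesh = _ellipsoid_mesh(axes, c, label, config.deep_edge_target)
            if not points_inside_surface(mesh.vertices, cortex).all():
                raise GeometryError(
                    f"deep structure '{label}' is not strictly inside the "
                    "cortical shell"
                )
            meshes.append(mesh)

    return AnatomicalModel(meshes, "HA" if config.include_deep else "C")


# ---------------------------------------------------------------------------
# file I/O (ASCII PLY and GIfTI surfaces)


class MeshParseError(ValueError):
    """Raised when a surface file cannot be parsed."""


def write_ply(path, mesh: TriMesh) -> None:
    """Write an ASCII PLY with full float64 precision (17 significant
    digits), storing the region label as a comment."""
    if mesh.faces.size == 0:
        raise MeshParseError("refusing to write a mesh with an empty face list")
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"comment label {mesh.label}\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write(f"element face {len(mesh.faces)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def read_ply(path) -> TriMesh:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or lines[0].strip() != "ply":
        raise MeshParseError(f"{path}: missing 'ply' magic line")
    label = "cortex"
    counts: dict[str, int] = {}
    order: list[str] = []
    i = 1
    while i < len(lines):
        tok = lines[i].split()
        if tok[:1] == ["end_header"]:
            i += 1
            break
        if tok[:2] == ["comment", "label"] and len(tok) >= 3:
            label = tok[2]
        elif tok[:1] == ["format"] and tok[1] != "ascii":
            raise MeshParseError(f"{path}: only ASCII PLY is supported")
        elif tok[:1] == ["element"]:
            counts[tok[1]] = int(tok[2])
            order.append(tok[1])
        i += 1
    else:
        raise MeshParseError(f"{path}: header has no end_header")
    nv, nf = counts.get("vertex", 0), counts.get("face", 0)
    verts = np.empty((nv, 3))
    for k in range(nv):
        tok = lines[i + k].split()
        if len(tok) < 3:
            raise MeshParseError(f"{path}: vertex {k} has {len(tok)} coordinates")
        verts[k] = [float(t) for t in tok[:3]]
    i += nv
    faces = np.empty((nf, 3), np.int64)
    for k in range(nf):
        tok = lines[i + k].split()
        if not tok or tok[0] != "3":
            raise MeshParseError(f"{path}: face {k} is not a triangle")
        faces[k] = [int(t) for t in tok[1:4]]
    if nf and faces.max() >= nv:
        raise MeshParseError(
            f"{path}: face index {int(faces.max())} out of range for "
            f"{nv} vertices"
        )
    if nf == 0:
        raise MeshParseError(f"{path}: empty face list")
    return TriMesh(verts, faces, label)


def write_gifti(path, mesh: TriMesh) -> None:
    import nibabel as nib

    # the GIfTI surface standard stores coordinates as float32; PLY is the
    # full-precision (float64) interchange path
    coords = nib.gifti.GiftiDataArray(
        mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET",
        datatype="NIFTI_TYPE_FLOAT32",
    )
    tris = nib.gifti.GiftiDataArray(
        mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE",
        datatype="NIFTI_TYPE_INT32",
    )
    img = nib.gifti.GiftiImage(darrays=[coords, tris])
    img.meta["label"] = mesh.label
    nib.save(img, str(path))


def read_gifti(path) -> TriMesh:
    import nibabel as nib

    img = nib.load(str(path))
    coords = tris = None
    for da in img.darrays:
        if da.intent == 1008:   # POINTSET
            coords = np.asarray(da.data, np.float64)
        elif da.intent == 1009:  # TRIANGLE
            tris = np.asarray(da.data, np.int64)
    if coords is None or tris is None:
        raise MeshParseError(f"{path}: GIfTI file lacks pointset/triangle arrays")
    label = dict(img.meta).get("label", "cortex")
    return TriMesh(coords, tris, label)


def save_mesh(path, mesh: TriMesh) -> None:
    path = str(path)
    if path.endswith(".ply"):
        write_ply(path, mesh)
    elif path.endswith(".gii"):
        write_gifti(path, mesh)
    else:
        raise ValueError(f"unsupported mesh format: {path}")


def load_mesh(path) -> TriMesh:
    path = str(path)
    if path.endswith(".ply"):
        return read_ply(path)
    if path.endswith(".gii"):
        return read_gifti(path)
    raise ValueError(f"unsupported mesh format: {path}")
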