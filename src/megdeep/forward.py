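"""Forward model: spherical-conductor lead fields and the smooth patch basis.

The conductor is a single homogeneous sphere fitted to the cortical
vertices.  The magnetic field of a current dipole in a conducting sphere
has the Sarvas closed form, in which the radial dipole component is
exactly silent — the depth penalty and radial blindness that make deep
MEG sources hard are therefore built in.

Each source is a dipole at a mesh vertex oriented along the outward
vertex normal.  Axial gradiometers are modelled as the difference of the
field projected on the coil axis at the pickup coil and at a second coil
``baseline`` mm further out along the same axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .anatomy import AnatomicalModel, vertex_normals


@dataclass
class SensorArray:
    """MEG sensor layout.

    positions/orientations are (Ns, 3); orientations are unit coil axes.
    ``baseline`` is the axial-gradiometer coil separation in mm and is
    ignored for magnetometers.  ``sphere_origin`` is the centre of the
    conductor sphere in head coordinates.
    """

    positions: np.ndarray
    orientations: np.ndarray
    kind: str = "axial_gradiometer"
    baseline: float = 50.0
    sphere_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float)
        self.orientations = np.asarray(self.orientations, float)
        self.sphere_origin = np.asarray(self.sphere_origin, float)
        n = np.linalg.norm(self.orientations, axis=1)
        if not np.allclose(n, 1.0, atol=1e-6):
            raise ValueError("sensor orientations must be unit vectors")
        if self.kind not in ("magnetometer", "axial_gradiometer"):
            raise ValueError(f"unknown sensor kind: {self.kind}")
        if not self.names:
            self.names = [f"MEG{i:03d}" for i in range(len(self.positions))]

    @property
    def n_sensors(self) -> int:
        return len(self.positions)


@dataclass
class LeadField:
    """Sensor gain matrix: (Ns, Nsrc) field per unit dipole moment."""

    gain: np.ndarray
    source_index: np.ndarray  # global vertex indices into the AnatomicalModel

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]


@dataclass
class PatchBasis:
    """Block-diagonal smoothing (Green's function) matrix over mesh graphs.

    ``green[:, i]`` is the smooth patch seeded at vertex i; blocks are
    independent per mesh so no patch straddles two structures.
    """

    green: np.ndarray
    sigma: float


def helmet_sensors(n_sensors: int = 100, radius: float = 55.0,
                   kind: str = "axial_gradiometer", baseline: float = 50.0,
                   coverage_deg: float = 105.0,
                   sphere_origin=(0.0, 0.0, 0.0)) -> SensorArray:
    """Radially oriented sensors on a spherical helmet cap.

    A Fibonacci lattice over the cap from the +z pole down to
    ``coverage_deg`` of polar angle gives a roughly uniform layout.
    """
    zmin = np.cos(np.deg2rad(coverage_deg))
    i = np.arange(n_sensors)
    z = 1.0 - (1.0 - zmin) * (i + 0.5) / n_sensors
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(1.0 - z ** 2)
    unit = np.c_[s * np.cos(phi), s * np.sin(phi), z]
    origin = np.asarray(sphere_origin, float)
    return SensorArray(origin + radius * unit, unit, kind, baseline, origin)


def fit_sphere(model: AnatomicalModel) -> tuple[np.ndarray, float]:
    """Least-squares sphere through the cortical vertices.

    Linearised fit: minimise |v|^2 - 2 c.v - (R^2 - |c|^2) over centre c.
    """
    v = model.mesh("cortex").vertices
    A = np.c_[2.0 * v, np.ones(len(v))]
    b = (v ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    radius = float(np.sqrt(sol[3] + center @ center))
    return center, radius


def _sarvas(r0: np.ndarray, q: np.ndarray, coils: np.ndarray) -> np.ndarray:
    """Magnetic field of dipoles in a conducting sphere at the origin.

    r0 : (Nsrc, 3) dipole positions, q : (Nsrc, 3) moments,
    coils : (Nc, 3) field points.  Returns (Nc, Nsrc, 3).
    The leading mu0/4pi constant is dropped (consistent arbitrary units).
    """
    r = coils[:, None, :]                # (Nc, 1, 3)
    a_vec = r - r0[None, :, :]           # (Nc, Nsrc, 3)
    a = np.linalg.norm(a_vec, axis=2)
    rn = np.linalg.norm(coils, axis=1)[:, None]
    r0r = (r * r0[None]).sum(axis=2)
    F = a * (rn * a + rn ** 2 - r0r)
    ar = (a_vec * r).sum(axis=2)
    gradF = ((a ** 2 / rn + ar / a + 2.0 * a + 2.0 * rn)[..., None] * r
             - (a + 2.0 * rn + ar / a)[..., None] * r0[None])
    qxr0 = np.cross(q, r0)               # (Nsrc, 3)
    qxr0_r = (qxr0[None] * r).sum(axis=2)
    B = (F[..., None] * qxr0[None] - qxr0_r[..., None] * gradF) / (F ** 2)[..., None]
    return B


def leadfield_sphere(model: AnatomicalModel, sensors: SensorArray) -> LeadField:
    """Gain matrix for unit dipoles at mesh vertices, normal orientation.

    Raises on sources at the sphere origin (the closed form is singular
    there) or outside the fitted conductor sphere.
    """
    origin = sensors.sphere_origin
    src = model.all_vertices - origin
    nrm = np.vstack([vertex_normals(m) for m in model.meshes])
    dist = np.linalg.norm(src, axis=1)
    if np.any(dist < 1e-6):
        raise FloatingPointError("source at the sphere origin: field undefined")
    coil_dist = np.linalg.norm(sensors.positions - origin, axis=1)
    if np.any(dist >= coil_dist.min()):
        raise ValueError("source outside the conductor sphere")

    pos1 = sensors.positions - origin
    B1 = _sarvas(src, nrm, pos1)
    gain = np.einsum("csj,cj->cs", B1, sensors.orientations)
    if sensors.kind == "axial_gradiometer":
        pos2 = pos1 + sensors.baseline * sensors.orientations
        B2 = _sarvas(src, nrm, pos2)
        gain = gain - np.einsum("csj,cj->cs", B2, sensors.orientations)
    if not np.all(np.isfinite(gain)):
        raise FloatingPointError("non-finite lead field values")
    return LeadField(gain, np.arange(model.n_vertices))


def mesh_adjacency(mesh) -> np.ndarray:
    """Symmetric 0/1 vertex adjacency of a triangular mesh."""
    n = mesh.n_vertices
    A = np.zeros((n, n))
    f = mesh.faces
    for i, j in ((0, 1), (1, 2), (2, 0)):
        A[f[:, i], f[:, j]] = 1.0
        A[f[:, j], f[:, i]] = 1.0
    return A


def patch_basis(model: AnatomicalModel, sigma: float = 0.6) -> PatchBasis:
    """Green's-function smoothing G = exp(sigma (A_n - I)) per mesh block.

    A_n is the degree-normalised adjacency D^-1/2 A D^-1/2 (symmetric, so
    each block is symmetric positive definite; spectrally equivalent to
    the row-normalised random-walk operator).  sigma = 0 gives the
    identity (point patches).
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    n = model.n_vertices
    G = np.zeros((n, n))
    for m in model.meshes:
        sl = model.vertex_slice(m.label)
        if sigma == 0 or m.n_vertices == 1:
            G[sl, sl] = np.eye(m.n_vertices)
            continue
        A = mesh_adjacency(m)
        deg = A.sum(axis=1)
        if np.any(deg == 0):
            warnings.warn(
                f"mesh '{m.label}' has isolated vertices; their patches "
                "stay confined to the vertex"
            )
            deg = np.maximum(deg, 1.0)
        from scipy.sparse.csgraph import connected_components
        ncomp, _ = connected_components(A > 0, directed=False)
        if ncomp > 1:
            warnings.warn(
                f"mesh '{m.label}' has {ncomp} connected components; "
                "patches stay confined to their component"
            )
        d = 1.0 / np.sqrt(deg)
        An = A * d[:, None] * d[None, :]
        block = expm(sigma * (An - np.eye(m.n_vertices)))
        G[sl, sl] = 0.5 * (block + block.T)
    return PatchBasis(G, sigma)


def spatial_projector(L: LeadField, n_modes: int = 120) -> np.ndarray:
    """Orthonormal spatial-mode basis: leading left singular vectors of the
    gain matrix.  ``n_modes`` greater than the numerical rank is clipped
    with a warning."""
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    U, s, _ = np.linalg.svd(L.gain, full_matrices=False)
    rank = int((s > s[0] * max(L.gain.shape) * np.finfo(float).eps).sum())
    if n_modes > rank:
        warnings.warn(f"n_modes={n_modes} exceeds rank {rank}; clipping")
        n_modes = rank
    return U[:, :n_modes]


def sensors_to_csv(path, sensors: SensorArray) -> None:
    import pandas as pd

    df = pd.DataFrame(
        np.c_[sensors.positions, sensors.orientations],
        columns=["x", "y", "z", "ox", "oy", "oz"],
    )
    df.insert(0, "name", sensors.names)
    df["kind"] = sensors.kind
    df.to_csv(path, index=False)


def sensors_from_csv(path, baseline: float = 50.0,
                     sphere_origin=(0.0, 0.0, 0.0)) -> SensorArray:
    import pandas as pd

    df = pd.read_csv(path)
    return SensorArray(
        df[["x", "y", "z"]].to_numpy(float),
        df[["ox", "oy", "oz"]].to_numpy(float),
        str(df["kind"].iloc[0]),
        baseline,
        np.asarray(sphere_origin, float),
        [str(n) for n in df["name"]],
    )
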