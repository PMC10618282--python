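"""Surface-mesh handling for multi-compartment head models.

A head model is an ordered collection of closed, outward-oriented triangle
surfaces, one per tissue conductivity interface.  Each facet carries the
conductivity contrast

    K = (sigma_in - sigma_out) / (sigma_in + sigma_out)

of its interface, where ``sigma_in`` is the conductivity just inside the
closed surface (the side the outward normal points away from) and
``sigma_out`` just outside.  All lengths are meters, conductivities S/m,
indexing 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: SimNIBS-style default conductivities (S/m).  Configuration, not ground truth.
DEFAULT_CONDUCTIVITIES = {
    "scalp": 0.465,
    "bone": 0.010,
    "csf": 1.654,
    "gm": 0.275,
    "wm": 0.126,
}

#: Default four-layer sphere geometry: outer radii (m) of scalp, skull,
#: CSF and brain (gray-matter) interfaces.
FOUR_LAYER_RADII = (0.092, 0.086, 0.080, 0.078)

#: Conductivity just inside each of the four default interfaces; the
#: outermost sits in air (sigma_out = 0).
FOUR_LAYER_SIGMAS = (
    DEFAULT_CONDUCTIVITIES["scalp"],
    DEFAULT_CONDUCTIVITIES["bone"],
    DEFAULT_CONDUCTIVITIES["csf"],
    DEFAULT_CONDUCTIVITIES["gm"],
)


class MeshValidationError(ValueError):
    """Raised for degenerate or non-manifold input meshes."""


# ---------------------------------------------------------------------------
# TriangleMesh
# ---------------------------------------------------------------------------


class TriangleMesh:
    """A triangulated surface: shared vertices plus 0-based index triples.

    Facet geometry (normals, areas, centroids) is computed once at
    construction.  Normal direction follows the right-hand rule on the
    vertex winding.
    """

    def __init__(self, vertices: np.ndarray, triangles: np.ndarray):
        vertices = np.ascontiguousarray(vertices, dtype=np.float64)
        triangles = np.ascontiguousarray(triangles, dtype=np.int64)
        if vertices.ndim != 2 or vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be (V, 3)")
        if triangles.ndim != 2 or triangles.shape[1] != 3:
            raise MeshValidationError("triangles must be (F, 3)")
        if triangles.size and (triangles.min() < 0 or triangles.max() >= len(vertices)):
            raise MeshValidationError("triangle index out of range")
        self.vertices = vertices
        self.triangles = triangles

        fv = vertices[triangles]  # (F, 3, 3)
        cross = np.cross(fv[:, 1] - fv[:, 0], fv[:, 2] - fv[:, 0])
        twice_area = np.linalg.norm(cross, axis=1)
        bad = np.flatnonzero(twice_area <= 0.0)
        if bad.size:
            raise MeshValidationError(f"zero-area facets at indices {bad.tolist()}")
        self.areas = 0.5 * twice_area
        self.normals = cross / twice_area[:, None]
        self.centroids = fv.mean(axis=1)

    # -- derived geometry ---------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_facets(self) -> int:
        return len(self.triangles)

    @property
    def face_vertices(self) -> np.ndarray:
        """Per-facet vertex coordinates, shape (F, 3, 3)."""
        return self.vertices[self.triangles]

    @property
    def circumradii(self) -> np.ndarray:
        """Max centroid-to-vertex distance per facet (near-field radius)."""
        d = self.face_vertices - self.centroids[:, None, :]
        return np.linalg.norm(d, axis=2).max(axis=1)

    def total_area(self) -> float:
        return float(self.areas.sum())

    def signed_volume(self) -> float:
        """Divergence-theorem volume; positive iff normals point outward."""
        fv = self.face_vertices
        return float(np.einsum("ij,ij->", fv[:, 0], np.cross(fv[:, 1], fv[:, 2])) / 6.0)

    def flipped(self) -> "TriangleMesh":
        """Same surface with reversed winding (normals negated)."""
        return TriangleMesh(self.vertices, self.triangles[:, ::-1])

    def __repr__(self) -> str:  # pragma: no cover
        return f"TriangleMesh(V={self.n_vertices}, F={self.n_facets})"


# ---------------------------------------------------------------------------
# STL I/O (via trimesh) with vertex welding
# ---------------------------------------------------------------------------


def _weld(vertices: np.ndarray, triangles: np.ndarray, tol: float):
    """Merge vertices closer than ``tol`` and drop degenerate triangles."""
    if tol <= 0:
        return vertices, triangles
    key = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    verts = vertices[first]
    tris = inverse[triangles]
    return verts, tris


def load_stl(path, unit_scale: float = 1.0) -> TriangleMesh:
    """Read a binary or ASCII STL file into a :class:`TriangleMesh`.

    STL stores one duplicated vertex triple per facet; vertices are welded
    within ``1e-8`` of the bounding-box diagonal so manifold checks work.
    ``unit_scale`` multiplies coordinates (STL carries no units; pass 1e-3
    for millimeter files).
    """
    import trimesh

    try:
        tm = trimesh.load_mesh(str(path), process=False)
    except Exception as exc:  # pragma: no cover - backend specific
        raise MeshValidationError(f"cannot parse STL file {path!r}: {exc}") from exc
    if not hasattr(tm, "faces") or len(tm.faces) == 0:
        raise MeshValidationError(f"no triangles found in {path!r}")
    verts = np.asarray(tm.vertices, dtype=np.float64) * float(unit_scale)
    tris = np.asarray(tm.faces, dtype=np.int64)
    diag = float(np.linalg.norm(verts.max(axis=0) - verts.min(axis=0)))
    verts, tris = _weld(verts, tris, 1e-8 * diag)
    degenerate = np.flatnonzero(
        (tris[:, 0] == tris[:, 1]) | (tris[:, 1] == tris[:, 2]) | (tris[:, 0] == tris[:, 2])
    )
    if degenerate.size:
        raise MeshValidationError(
            f"zero-area facets at indices {degenerate.tolist()} after welding"
        )
    return TriangleMesh(verts, tris)


def write_stl(mesh: TriangleMesh, path, ascii: bool = False) -> None:
    """Write a mesh to STL (binary by default)."""
    import trimesh

    tm = trimesh.Trimesh(mesh.vertices, mesh.triangles, process=False)
    tm.export(str(path), file_type="stl_ascii" if ascii else "stl")


# ---------------------------------------------------------------------------
# Manifold validation
# ---------------------------------------------------------------------------


@dataclass
class ManifoldReport:
    is_closed: bool
    is_oriented: bool          # consistently wound and outward (signed volume > 0)
    genus: int                 # per closed connected surface, -1 if open
    signed_volume: float
    n_components: int
    euler_characteristic: int
    boundary_edges: np.ndarray  # (B, 2) vertex pairs on a boundary


def validate_closed_manifold(mesh: TriangleMesh) -> ManifoldReport:
    """Report closedness, orientation and genus; never raises.

    A closed 2-manifold has every edge shared by exactly two triangles with
    opposite traversal direction; genus follows from V - E + F = 2 - 2g per
    connected component.
    """
    tris = mesh.triangles
    directed = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    undirected = np.sort(directed, axis=1)
    edges, counts = np.unique(undirected, axis=0, return_counts=True)
    boundary = edges[counts == 1]
    closed = bool(boundary.size == 0 and np.all(counts == 2))

    # consistent winding: each undirected edge traversed once per direction
    consistent = False
    if closed:
        _, dcounts = np.unique(directed, axis=0, return_counts=True)
        consistent = bool(np.all(dcounts == 1))

    vol = mesh.signed_volume()

    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    v = mesh.n_vertices
    adj = coo_matrix(
        (np.ones(len(directed)), (directed[:, 0], directed[:, 1])), shape=(v, v)
    )
    used = np.zeros(v, dtype=bool)
    used[tris.ravel()] = True
    n_comp_all, _ = connected_components(adj, directed=False)
    n_comp = n_comp_all - int((~used).sum())

    euler = int(used.sum()) - len(edges) + mesh.n_facets
    genus = -1
    if closed and n_comp > 0 and (2 * n_comp - euler) % 2 == 0:
        genus = (2 * n_comp - euler) // 2

    return ManifoldReport(
        is_closed=closed,
        is_oriented=bool(closed and consistent and vol > 0),
        genus=genus,
        signed_volume=vol,
        n_components=n_comp,
        euler_characteristic=euler,
        boundary_edges=boundary,
    )


# ---------------------------------------------------------------------------
# Subdivision and synthetic spheres
# ---------------------------------------------------------------------------


def subdivide_1to4(mesh: TriangleMesh, sphere_radius: float | None = None) -> TriangleMesh:
    """Uniform 1:4 refinement: split every triangle at its edge midpoints.

    Without ``sphere_radius`` the children are coplanar with the parent, so
    shape, total area and volume are preserved to rounding.  With
    ``sphere_radius`` the new midpoint vertices are reprojected onto the
    sphere of that radius about the origin (synthetic sphere models only).
    Applying the operation three times yields the 1:64 refinement used for
    reference solutions.
    """
    report = validate_closed_manifold(mesh)
    if not report.is_closed:
        raise MeshValidationError("subdivide_1to4 requires a closed manifold mesh")

    tris = mesh.triangles
    verts = mesh.vertices
    edges = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    edges_sorted = np.sort(edges, axis=1)
    uniq, inverse = np.unique(edges_sorted, axis=0, return_inverse=True)
    midpoints = 0.5 * (verts[uniq[:, 0]] + verts[uniq[:, 1]])
    if sphere_radius is not None:
        midpoints *= sphere_radius / np.linalg.norm(midpoints, axis=1)[:, None]

    mid_idx = inverse.reshape(3, -1).T + len(verts)  # (F, 3): m01, m12, m20
    new_verts = np.vstack([verts, midpoints])
    a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
    m01, m12, m20 = mid_idx[:, 0], mid_idx[:, 1], mid_idx[:, 2]
    new_tris = np.concatenate(
        [
            np.stack([a, m01, m20], axis=1),
            np.stack([m01, b, m12], axis=1),
            np.stack([m20, m12, c], axis=1),
            np.stack([m01, m12, m20], axis=1),
        ]
    )
    return TriangleMesh(new_verts, new_tris)


def icosahedron(radius: float = 1.0) -> TriangleMesh:
    """Regular icosahedron with vertices on the sphere of given radius."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    v = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=np.float64,
    )
    v *= radius / np.linalg.norm(v[0])
    f = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    mesh = TriangleMesh(v, f)
    if mesh.signed_volume() < 0:  # pragma: no cover - fixed table is outward
        mesh = mesh.flipped()
    return mesh


def icosphere(radius: float, subdiv_level: int) -> TriangleMesh:
    """Icosahedron refined ``subdiv_level`` times with reprojection onto the
    sphere: 20 * 4**level facets, outward normals, vertices exactly on the
    sphere."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if subdiv_level < 0:
        raise ValueError("subdiv_level must be >= 0")
    mesh = icosahedron(radius)
    for _ in range(subdiv_level):
        mesh = subdivide_1to4(mesh, sphere_radius=radius)
    return mesh


def make_nested_spheres(radii, subdiv_level: int) -> list[TriangleMesh]:
    """One icosphere per radius; radii must be strictly decreasing."""
    radii = [float(r) for r in radii]
    if any(r <= 0 for r in radii):
        raise ValueError("radii must be positive")
    if any(b >= a for a, b in zip(radii, radii[1:])):
        raise ValueError("radii must be strictly decreasing (outermost first)")
    return [icosphere(r, subdiv_level) for r in radii]


# ---------------------------------------------------------------------------
# Interfaces and head model
# ---------------------------------------------------------------------------


@dataclass
class Interface:
    """One closed conductivity interface.

    ``sigma_in`` / ``sigma_out``: conductivity just inside / outside with
    respect to the outward normal direction.
    """

    mesh: TriangleMesh
    sigma_in: float
    sigma_out: float
    name: str = ""

    def __post_init__(self):
        if self.sigma_in < 0 or self.sigma_out < 0:
            raise ValueError(f"interface {self.name!r}: conductivities must be >= 0")
        if self.sigma_in == 0 and self.sigma_out == 0:
            raise ValueError(
                f"interface {self.name!r}: sigma_in = sigma_out = 0, contrast undefined"
            )

    @property
    def contrast(self) -> float:
        return (self.sigma_in - self.sigma_out) / (self.sigma_in + self.sigma_out)


@dataclass
class HeadModel:
    """Flat facet-level view of an ordered set of interfaces.

    Arrays are concatenated over interfaces in order; ``interface_slices``
    maps each interface to its facet index range.
    """

    interfaces: list
    normals: np.ndarray       # (N, 3)
    areas: np.ndarray         # (N,)
    centroids: np.ndarray     # (N, 3)
    face_vertices: np.ndarray  # (N, 3, 3)
    contrast: np.ndarray      # (N,), K per facet
    sigma_in: np.ndarray      # (N,)
    sigma_out: np.ndarray     # (N,)
    circumradii: np.ndarray   # (N,)
    interface_slices: list = field(default_factory=list)

    @property
    def n_facets(self) -> int:
        return len(self.areas)


def build_head_model(interfaces, audit_nesting: bool = False) -> HeadModel:
    """Assemble a :class:`HeadModel` from closed outward-oriented interfaces.

    Inward-wound meshes (signed volume < 0) are auto-corrected with a logged
    warning.  Nesting consistency is the caller's responsibility; with
    ``audit_nesting`` every vertex of interface i+1 is checked to lie inside
    interface i (suitable for nested-shell models only).
    """
    interfaces = list(interfaces)
    if not interfaces:
        raise ValueError("at least one interface required")
    fixed = []
    for iface in interfaces:
        report = validate_closed_manifold(iface.mesh)
        if not report.is_closed:
            raise MeshValidationError(
                f"interface {iface.name!r} is not a closed manifold "
                f"({len(report.boundary_edges)} boundary edges)"
            )
        mesh = iface.mesh
        if report.signed_volume < 0:
            logger.warning(
                "interface %r has inward normals (signed volume %.3g); flipping",
                iface.name, report.signed_volume,
            )
            mesh = mesh.flipped()
        fixed.append(Interface(mesh, iface.sigma_in, iface.sigma_out, iface.name))

    if audit_nesting:
        for outer, inner in zip(fixed, fixed[1:]):
            if not _all_points_inside(outer.mesh, inner.mesh.vertices):
                raise MeshValidationError(
                    f"interface {inner.name!r} is not strictly inside {outer.name!r}"
                )

    slices = []
    start = 0
    for iface in fixed:
        n = iface.mesh.n_facets
        slices.append(slice(start, start + n))
        start += n

    return HeadModel(
        interfaces=fixed,
        normals=np.concatenate([i.mesh.normals for i in fixed]),
        areas=np.concatenate([i.mesh.areas for i in fixed]),
        centroids=np.concatenate([i.mesh.centroids for i in fixed]),
        face_vertices=np.concatenate([i.mesh.face_vertices for i in fixed]),
        contrast=np.concatenate(
            [np.full(i.mesh.n_facets, i.contrast) for i in fixed]
        ),
        sigma_in=np.concatenate(
            [np.full(i.mesh.n_facets, i.sigma_in) for i in fixed]
        ),
        sigma_out=np.concatenate(
            [np.full(i.mesh.n_facets, i.sigma_out) for i in fixed]
        ),
        circumradii=np.concatenate([i.mesh.circumradii for i in fixed]),
        interface_slices=slices,
    )


def _all_points_inside(mesh: TriangleMesh, points: np.ndarray) -> bool:
    """Winding-number containment: interior points see a total solid angle
    of -4 pi (the convention is positive on the outward-normal side)."""
    from .operator import triangle_solid_angles

    omega = triangle_solid_angles(mesh.face_vertices, points)
    return bool(np.all(omega.sum(axis=1) < -2.0 * np.pi))


def four_layer_sphere_model(
    subdiv_level: int = 3,
    radii=FOUR_LAYER_RADII,
    sigmas=FOUR_LAYER_SIGMAS,
) -> HeadModel:
    """Synthetic four-layer sphere head model (scalp, skull, CSF, brain).

    Outer radii default to 92/86/80/78 mm with SimNIBS-style conductivities;
    the outermost interface sits in air.
    """
    meshes = make_nested_spheres(radii, subdiv_level)
    sigmas = list(sigmas)
    names = ["scalp", "skull", "csf", "brain"][: len(meshes)]
    if len(sigmas) != len(meshes):
        raise ValueError("one conductivity per layer required")
    ifaces = []
    for k, mesh in enumerate(meshes):
        sigma_out = 0.0 if k == 0 else sigmas[k - 1]
        name = names[k] if k < len(names) else f"layer{k}"
        ifaces.append(Interface(mesh, sigmas[k], sigma_out, name))
    return build_head_model(ifaces)


# ---------------------------------------------------------------------------
# Head-model manifest (TOML)
# ---------------------------------------------------------------------------


def load_head_manifest(path) -> HeadModel:
    """Build a head model from a TOML manifest.

    Format: one ``[[interface]]`` table per surface, outermost first::

        [[interface]]
        stl = "scalp.stl"
        name = "scalp"
        sigma_in = 0.465
        sigma_out = 0.0
        unit_scale = 1.0      # optional, default 1 (meters)
    """
    import tomllib
    from pathlib import Path

    path = Path(path)
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    entries = cfg.get("interface", [])
    if not entries:
        raise ValueError(f"no [[interface]] entries in manifest {path}")
    ifaces = []
    for ent in entries:
        stl = Path(ent["stl"])
        if not stl.is_absolute():
            stl = path.parent / stl
        mesh = load_stl(stl, unit_scale=float(ent.get("unit_scale", 1.0)))
        ifaces.append(
            Interface(
                mesh,
                float(ent["sigma_in"]),
                float(ent["sigma_out"]),
                str(ent.get("name", stl.stem)),
            )
        )
    return build_head_model(ifaces)
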