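"""Triangle-mesh primitives, STL I/O and validity reporting.

Everything downstream (neck framing, morphometry, scaling) operates on the
:class:`TriangleMesh` defined here.  Coordinates are millimetres throughout:
STL carries no unit metadata, and clinical vessel diameters (~1-4 mm) make
mm the only sensible convention, which the CLI documents.

STL reading merges duplicated facet corners within ``MERGE_TOL`` so that
shared edges become topological, not merely coincident; STL stores float32,
so 1e-6 mm fuses numerical duplicates without welding distinct features at
clinical scale.
"""

from __future__ import annotations

import io
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from .errors import EmptyMeshError, GeometryError, STLParseError

#: Vertex merge tolerance on STL read (mm).
MERGE_TOL = 1e-6

#: Vertex label codes.
LABEL_VESSEL = 0
LABEL_SAC = 1
LABEL_NECK = 2

LABEL_NAMES = {LABEL_VESSEL: "vessel", LABEL_SAC: "sac", LABEL_NECK: "neck"}


# ---------------------------------------------------------------------------
# core types
# ---------------------------------------------------------------------------


@dataclass
class TriangleMesh:
    """Indexed triangle surface.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in mm.
    faces : (m, 3) int array
        Vertex-index triples; counter-clockwise seen from outside for an
        outward-oriented surface.
    labels : (n,) int array, optional
        Per-vertex region labels (``LABEL_VESSEL`` / ``LABEL_SAC`` /
        ``LABEL_NECK``).
    """

    vertices: np.ndarray
    faces: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must have shape (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must have shape (m, 3)")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face index out of range")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int8)
            if self.labels.shape != (len(self.vertices),):
                raise ValueError("labels must be per-vertex")

    # -- basic queries ------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.labels is None else self.labels.copy(),
        )

    def triangles(self) -> np.ndarray:
        """(m, 3, 3) array of face corner coordinates."""
        return self.vertices[self.faces]

    def face_normals(self, normalize: bool = True) -> np.ndarray:
        tri = self.triangles()
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        if normalize:
            lens = np.linalg.norm(n, axis=1)
            lens[lens == 0] = 1.0
            n = n / lens[:, None]
        return n

    def face_areas(self) -> np.ndarray:
        tri = self.triangles()
        return 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )

    def volume(self) -> float:
        """Signed enclosed volume (divergence theorem); positive when the
        surface is closed and outward-oriented."""
        tri = self.triangles()
        return float(
            np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum()
            / 6.0
        )

    def edges(self, directed: bool = False) -> np.ndarray:
        e = self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
        if directed:
            return e
        return np.sort(e, axis=1)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion stored as a 4x4 homogeneous matrix.

    The rotation block must be orthonormal with determinant +1 (checked to
    1e-9).  ``from_params`` composes translation with three elementary
    rotations in the fixed order translation . Rz(phi) . Ry(omega) . Rx(theta),
    using the sign convention of the printed 2x2 cos/sin blocks (the
    transpose of the more common right-handed convention; the composition
    order and block layout are taken as authoritative).
    """

    matrix: np.ndarray
    angles: tuple | None = None

    def __post_init__(self) -> None:
        m = np.ascontiguousarray(self.matrix, dtype=np.float64)
        if m.shape != (4, 4):
            raise ValueError("matrix must be 4x4")
        R = m[:3, :3]
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation block is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation block must have determinant +1")
        if not (np.allclose(m[3, :3], 0.0) and np.isclose(m[3, 3], 1.0)):
            raise ValueError("last row must be [0, 0, 0, 1]")
        object.__setattr__(self, "matrix", m)

    # -- constructors -------------------------------------------------------

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_params(
        cls,
        p: float = 0.0,
        q: float = 0.0,
        r: float = 0.0,
        phi: float = 0.0,
        omega: float = 0.0,
        theta: float = 0.0,
    ) -> "RigidTransform":
        """Translation (p, q, r) composed with Rz(phi), Ry(omega), Rx(theta)."""
        cphi, sphi = np.cos(phi), np.sin(phi)
        com, som = np.cos(omega), np.sin(omega)
        cth, sth = np.cos(theta), np.sin(theta)
        T = np.eye(4)
        T[:3, 3] = (p, q, r)
        Rz = np.eye(4)
        Rz[:2, :2] = [[cphi, sphi], [-sphi, cphi]]
        Ry = np.eye(4)
        Ry[0, 0], Ry[0, 2], Ry[2, 0], Ry[2, 2] = com, -som, som, com
        Rx = np.eye(4)
        Rx[1:3, 1:3] = [[cth, sth], [-sth, cth]]
        return cls(T @ Rz @ Ry @ Rx, angles=(phi, omega, theta))

    @classmethod
    def from_rotation_translation(
        cls, rotation: np.ndarray, translation=(0.0, 0.0, 0.0)
    ) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = rotation
        m[:3, 3] = translation
        return cls(m)

    @classmethod
    def rotation_between(cls, a: np.ndarray, b: np.ndarray) -> "RigidTransform":
        """Minimal (geodesic) rotation taking unit vector ``a`` onto ``b``."""
        a = np.asarray(a, dtype=np.float64)
        b = np.asarray(b, dtype=np.float64)
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na < 1e-12 or nb < 1e-12:
            raise GeometryError("degenerate direction vector")
        a, b = a / na, b / nb
        v = np.cross(a, b)
        c = float(np.dot(a, b))
        s = np.linalg.norm(v)
        if s < 1e-15:
            if c > 0:
                return cls.identity()
            # antiparallel: rotate pi about any axis orthogonal to a
            axis = np.cross(a, [1.0, 0.0, 0.0])
            if np.linalg.norm(axis) < 1e-6:
                axis = np.cross(a, [0.0, 1.0, 0.0])
            axis /= np.linalg.norm(axis)
            K = np.array(
                [
                    [0, -axis[2], axis[1]],
                    [axis[2], 0, -axis[0]],
                    [-axis[1], axis[0], 0],
                ]
            )
            return cls.from_rotation_translation(np.eye(3) + 2.0 * (K @ K))
        K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + K + K @ K * ((1 - c) / s**2)
        return cls.from_rotation_translation(R)

    # -- algebra ------------------------------------------------------------

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def inverse(self) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = self.rotation.T
        m[:3, 3] = -self.rotation.T @ self.translation
        return RigidTransform(m)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self.compose(other)).apply(x) == self(other(x))."""
        return RigidTransform(self.matrix @ other.matrix)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = pts @ self.rotation.T + self.translation
        return out[0] if single else out


def apply_transform(mesh: TriangleMesh, rigid: RigidTransform) -> TriangleMesh:
    """Map every vertex through the homogeneous matrix; topology unchanged."""
    return TriangleMesh(
        rigid.apply(mesh.vertices),
        mesh.faces.copy(),
        None if mesh.labels is None else mesh.labels.copy(),
    )


# ---------------------------------------------------------------------------
# STL I/O
# ---------------------------------------------------------------------------

_BINARY_FACET = struct.Struct("<12fH")


def _weld(points: np.ndarray, tol: float = MERGE_TOL):
    """Merge coordinates that agree within ``tol`` (grid quantisation)."""
    decimals = max(0, int(round(-np.log10(tol))))
    key = np.round(points, decimals=decimals)
    # round negative zeros away so -0.0 and 0.0 share a key
    key = key + 0.0
    _, first, inverse = np.unique(
        key.view([("x", "f8"), ("y", "f8"), ("z", "f8")]).ravel(),
        return_index=True,
        return_inverse=True,
    )
    return points[first], inverse


def _mesh_from_soup(tri_points: np.ndarray) -> TriangleMesh:
    """Build an indexed mesh from a (m, 3, 3) facet-corner soup."""
    if len(tri_points) == 0:
        raise EmptyMeshError("STL file contains no facets")
    flat = tri_points.reshape(-1, 3).astype(np.float64)
    verts, inverse = _weld(flat)
    faces = inverse.reshape(-1, 3)
    # drop degenerate facets (repeated corner after welding)
    ok = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 2] != faces[:, 0])
    )
    faces = faces[ok]
    if len(faces) == 0:
        raise EmptyMeshError("STL file contains only degenerate facets")
    return TriangleMesh(verts, faces)


def _read_stl_binary(data: bytes) -> TriangleMesh:
    if len(data) < 84:
        raise STLParseError(
            f"binary STL truncated: {len(data)} bytes, need at least 84"
        )
    (count,) = struct.unpack_from("<I", data, 80)
    expected = 84 + 50 * count
    if len(data) != expected:
        raise STLParseError(
            f"binary STL size mismatch at byte 80: facet count {count} "
            f"implies {expected} bytes, file has {len(data)}"
        )
    if count == 0:
        raise EmptyMeshError("STL file contains no facets")
    raw = np.frombuffer(
        data,
        dtype=np.dtype(
            [("normal", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")]
        ),
        count=count,
        offset=84,
    )
    return _mesh_from_soup(np.array(raw["v"], dtype=np.float64))


def _read_stl_ascii(text: str) -> TriangleMesh:
    tris: list = []
    current: list = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        tokens = line.split()
        if not tokens:
            continue
        if tokens[0] == "vertex":
            if len(tokens) != 4:
                raise STLParseError(f"ASCII STL line {lineno}: malformed vertex")
            try:
                current.append([float(t) for t in tokens[1:4]])
            except ValueError as exc:
                raise STLParseError(
                    f"ASCII STL line {lineno}: non-numeric vertex"
                ) from exc
        elif tokens[0] == "endloop":
            if len(current) != 3:
                raise STLParseError(
                    f"ASCII STL line {lineno}: loop has {len(current)} vertices"
                )
            tris.append(current)
            current = []
        elif tokens[0] in (
            "solid",
            "endsolid",
            "facet",
            "endfacet",
            "outer",
        ):
            continue
        else:
            raise STLParseError(
                f"ASCII STL line {lineno}: unexpected token {tokens[0]!r}"
            )
    if current:
        raise STLParseError("ASCII STL ends inside a vertex loop")
    if not tris:
        raise EmptyMeshError("STL file contains no facets")
    return _mesh_from_soup(np.asarray(tris, dtype=np.float64))


def read_stl(path) -> TriangleMesh:
    """Read a binary or ASCII STL file into an indexed :class:`TriangleMesh`.

    Duplicated facet corners are merged within ``MERGE_TOL`` (1e-6 mm) so
    shared edges are topological.  Units are taken as mm.
    """
    path = Path(path)
    data = path.read_bytes()
    if not data:
        raise EmptyMeshError(f"{path}: empty file")
    # Binary iff the declared facet count matches the file size; ASCII files
    # start with 'solid' but so may binary headers, hence the size check.
    if len(data) >= 84:
        (count,) = struct.unpack_from("<I", data, 80)
        if len(data) == 84 + 50 * count and count > 0:
            return _read_stl_binary(data)
    if data.lstrip()[:5] == b"solid":
        return _read_stl_ascii(data.decode("ascii", errors="replace"))
    if len(data) >= 84:
        return _read_stl_binary(data)  # will raise a size-mismatch error
    raise STLParseError(f"{path}: not a recognisable STL file")


def write_stl(mesh: TriangleMesh, path, dialect: str = "binary") -> None:
    """Write ``mesh`` as STL.

    The binary dialect is byte-stable for identical input (fixed header, no
    timestamps).  Facet normals are recomputed from geometry.
    """
    if mesh.n_faces == 0:
        raise EmptyMeshError("refusing to write an empty mesh")
    if dialect not in ("binary", "ascii"):
        raise ValueError(f"unknown STL dialect {dialect!r}")
    path = Path(path)
    tri = mesh.triangles()
    normals = mesh.face_normals()
    if dialect == "binary":
        buf = io.BytesIO()
        header = b"aneuscale binary STL".ljust(80, b" ")
        buf.write(header)
        buf.write(struct.pack("<I", mesh.n_faces))
        rec = np.zeros(
            mesh.n_faces,
            dtype=np.dtype(
                [("normal", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")]
            ),
        )
        rec["normal"] = normals
        rec["v"] = tri
        buf.write(rec.tobytes())
        path.write_bytes(buf.getvalue())
    else:
        lines = ["solid aneuscale"]
        for n, t in zip(normals, tri):
            lines.append(f"  facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}")
            lines.append("    outer loop")
            for v in t:
                lines.append(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}")
            lines.append("    endloop")
            lines.append("  endfacet")
        lines.append("endsolid aneuscale")
        path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# validity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ValidityReport:
    """Outcome of :func:`check_validity`; reports, never throws."""

    watertight: bool
    manifold: bool
    oriented: bool
    n_components: int
    min_face_area: float
    n_boundary_edges: int
    n_nonmanifold_edges: int
    self_intersecting: bool | None = None

    def as_dict(self) -> dict:
        return {
            "watertight": self.watertight,
            "manifold": self.manifold,
            "oriented": self.oriented,
            "n_components": self.n_components,
            "min_face_area": self.min_face_area,
            "n_boundary_edges": self.n_boundary_edges,
            "n_nonmanifold_edges": self.n_nonmanifold_edges,
            "self_intersecting": self.self_intersecting,
        }


def _edge_stats(mesh: TriangleMesh):
    directed = mesh.edges(directed=True)
    und = np.sort(directed, axis=1)
    uniq, inverse, counts = np.unique(
        und.view([("a", "i8"), ("b", "i8")]).ravel(),
        return_inverse=True,
        return_counts=True,
    )
    return directed, inverse, counts


def check_validity(mesh: TriangleMesh, self_intersections: bool = False) -> ValidityReport:
    """Report watertightness, edge-manifoldness, orientation consistency,
    connected-component count and minimum face area.

    A mesh is watertight when every undirected edge borders exactly two
    faces; it is consistently oriented when those two incidences traverse
    the edge in opposite directions.
    """
    if mesh.n_faces == 0:
        return ValidityReport(False, False, False, 0, 0.0, 0, 0)
    directed, inverse, counts = _edge_stats(mesh)
    n_boundary = int((counts == 1).sum())
    n_nonmanifold = int((counts > 2).sum())
    manifold = n_nonmanifold == 0
    watertight = bool((counts == 2).all())
    # orientation: every directed edge unique, and its reverse present for
    # interior edges
    dview = directed.view([("a", "i8"), ("b", "i8")]).ravel()
    _, dcounts = np.unique(dview, return_counts=True)
    oriented = bool((dcounts == 1).all()) and manifold
    if oriented and watertight:
        # interior edges must appear once per direction; with unique
        # directed edges and count==2 everywhere this already holds
        pass
    e = mesh.edges()
    adj = coo_matrix(
        (np.ones(len(e)), (e[:, 0], e[:, 1])),
        shape=(mesh.n_vertices, mesh.n_vertices),
    )
    used = np.zeros(mesh.n_vertices, dtype=bool)
    used[mesh.faces.ravel()] = True
    n_comp_all, comp = connected_components(adj, directed=False)
    n_components = int(len(np.unique(comp[used])))
    report = ValidityReport(
        watertight=watertight,
        manifold=manifold,
        oriented=oriented,
        n_components=n_components,
        min_face_area=float(mesh.face_areas().min()),
        n_boundary_edges=n_boundary,
        n_nonmanifold_edges=n_nonmanifold,
        self_intersecting=(
            bool(find_self_intersections(mesh)) if self_intersections else None
        ),
    )
    return report


def orient_consistently(mesh: TriangleMesh) -> TriangleMesh:
    """Return a copy with face windings made consistent per component and
    flipped so every closed component has positive (outward) volume.

    Requires an edge-manifold mesh.
    """
    faces = mesh.faces.copy()
    m = len(faces)
    und = np.sort(faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    uview = und.view([("a", "i8"), ("b", "i8")]).ravel()
    uniq, inverse, counts = np.unique(uview, return_inverse=True, return_counts=True)
    if (counts > 2).any():
        raise GeometryError("cannot orient a non-manifold mesh")
    # undirected edge (min, max) -> incident faces
    edge_faces: dict = {}
    for fid in range(m):
        a, b, c = (int(v) for v in faces[fid])
        for u, v in ((a, b), (b, c), (c, a)):
            edge_faces.setdefault((u, v) if u < v else (v, u), []).append(fid)

    def directed_edges(f):
        a, b, c = (int(v) for v in faces[f])
        return ((a, b), (b, c), (c, a))

    visited = np.zeros(m, dtype=bool)
    face_comp = np.full(m, -1, dtype=np.int64)
    comp_id = 0
    for start in range(m):
        if visited[start]:
            continue
        stack = [start]
        visited[start] = True
        face_comp[start] = comp_id
        while stack:
            f = stack.pop()
            for a, b in directed_edges(f):
                key = (a, b) if a < b else (b, a)
                for g in edge_faces[key]:
                    if g == f or visited[g]:
                        continue
                    # consistent orientation: neighbour traverses (b, a)
                    if (a, b) in directed_edges(g):
                        faces[g] = faces[g][::-1]
                    visited[g] = True
                    face_comp[g] = comp_id
                    stack.append(g)
        comp_id += 1
    out = TriangleMesh(
        mesh.vertices.copy(),
        faces,
        None if mesh.labels is None else mesh.labels.copy(),
    )
    # flip closed components with negative signed volume
    tri = out.triangles()
    vols = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0
    for cid in range(comp_id):
        sel = face_comp == cid
        if vols[sel].sum() < 0:
            out.faces[sel] = out.faces[sel][:, ::-1]
    return out


# ---------------------------------------------------------------------------
# self-intersection scan
# ---------------------------------------------------------------------------


def _tri_tri_intersect(t1: np.ndarray, t2: np.ndarray, eps: float = 1e-10) -> bool:
    """Moller-style interval test for two triangles given as (3, 3) arrays."""
    n1 = np.cross(t1[1] - t1[0], t1[2] - t1[0])
    d1 = -np.dot(n1, t1[0])
    dv2 = t2 @ n1 + d1
    # strict straddle: grazing contact (a vertex on the other's plane) is
    # zero-measure and not reported as an intersection
    if (dv2 >= -eps).all() or (dv2 <= eps).all():
        if not (np.abs(dv2) <= eps).all():
            return False
    n2 = np.cross(t2[1] - t2[0], t2[2] - t2[0])
    d2 = -np.dot(n2, t2[0])
    dv1 = t1 @ n2 + d2
    if (dv1 >= -eps).all() or (dv1 <= eps).all():
        if not (np.abs(dv1) <= eps).all():
            return False
    if (np.abs(dv1) <= eps).all() and (np.abs(dv2) <= eps).all():
        # coplanar: 2D separating-axis test in the dominant plane
        axis = int(np.argmax(np.abs(n1)))
        keep = [i for i in range(3) if i != axis]
        a, b = t1[:, keep], t2[:, keep]
        for poly, other in ((a, b), (b, a)):
            for i in range(3):
                edge = poly[(i + 1) % 3] - poly[i]
                normal = np.array([-edge[1], edge[0]])
                pa = poly @ normal
                pb = other @ normal
                if pb.min() > pa.max() + eps or pb.max() < pa.min() - eps:
                    return False
        return True

    def interval(t, dv, direction):
        proj = t @ direction
        # order so the odd vertex (opposite sign) is in the middle
        signs = dv > 0
        if signs[0] == signs[1]:
            order = (0, 2, 1)
        elif signs[0] == signs[2]:
            order = (0, 1, 2)
        else:
            order = (1, 0, 2)
        p0, p1, p2 = proj[list(order)]
        v0, v1, v2 = dv[list(order)]
        denom1 = v0 - v1
        denom2 = v2 - v1
        a = p0 + (p1 - p0) * (v0 / denom1) if abs(denom1) > eps else p0
        b = p2 + (p1 - p2) * (v2 / denom2) if abs(denom2) > eps else p2
        return min(a, b), max(a, b)

    direction = np.cross(n1, n2)
    direction = direction / max(np.linalg.norm(direction), eps)
    lo1, hi1 = interval(t1, dv1, direction)
    lo2, hi2 = interval(t2, dv2, direction)
    return not (hi1 < lo2 + eps or hi2 < lo1 + eps)


def _broadphase_pairs(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Candidate face pairs from a uniform grid over face bounding boxes."""
    extent = hi - lo
    cell = 2.0 * max(float(np.median(extent)), 1e-9)
    ilo = np.floor(lo / cell).astype(np.int64)
    ihi = np.floor(hi / cell).astype(np.int64)
    entries_face = []
    entries_cell = []
    for f in range(len(lo)):
        xs = range(ilo[f, 0], ihi[f, 0] + 1)
        ys = range(ilo[f, 1], ihi[f, 1] + 1)
        zs = range(ilo[f, 2], ihi[f, 2] + 1)
        for cx in xs:
            for cy in ys:
                for cz in zs:
                    entries_face.append(f)
                    entries_cell.append((cx, cy, cz))
    cells = np.asarray(entries_cell, dtype=np.int64)
    faces = np.asarray(entries_face, dtype=np.int64)
    _, inv = np.unique(cells, axis=0, return_inverse=True)
    order = np.argsort(inv, kind="stable")
    inv, faces = inv[order], faces[order]
    boundaries = np.flatnonzero(np.diff(inv)) + 1
    pairs = []
    for grp in np.split(faces, boundaries):
        if len(grp) > 1:
            i, j = np.triu_indices(len(grp), k=1)
            pairs.append(np.column_stack([grp[i], grp[j]]))
    if not pairs:
        return np.empty((0, 2), dtype=np.int64)
    pairs = np.unique(np.sort(np.vstack(pairs), axis=1), axis=0)
    return pairs


def find_self_intersections(mesh: TriangleMesh, limit: int | None = None) -> list:
    """Return pairs of non-adjacent face indices whose triangles intersect.

    Candidate pairs come from a uniform-grid broadphase over face bounding
    boxes, then pass bounding-box overlap and a vectorised plane-straddle
    rejection before the exact triangle-triangle test.  ``limit`` stops the
    scan early once that many pairs are found.
    """
    tri = mesh.triangles()
    lo = tri.min(axis=1)
    hi = tri.max(axis=1)
    pairs = _broadphase_pairs(lo, hi)
    if len(pairs) == 0:
        return []
    a, b = pairs[:, 0], pairs[:, 1]
    box_ok = ((lo[a] <= hi[b] + 1e-12) & (lo[b] <= hi[a] + 1e-12)).all(axis=1)
    pairs = pairs[box_ok]
    if len(pairs) == 0:
        return []
    # exclude pairs sharing a vertex
    fa = mesh.faces[pairs[:, 0]]
    fb = mesh.faces[pairs[:, 1]]
    shares = (fa[:, :, None] == fb[:, None, :]).any(axis=(1, 2))
    pairs = pairs[~shares]
    if len(pairs) == 0:
        return []
    # vectorised strict-straddle rejection on both planes; coplanar pairs
    # (all distances ~0) are kept for the exact test
    eps = 1e-10
    ta, tb = tri[pairs[:, 0]], tri[pairs[:, 1]]

    def straddles(t_ref, t_other):
        n = np.cross(t_ref[:, 1] - t_ref[:, 0], t_ref[:, 2] - t_ref[:, 0])
        dv = np.einsum("pij,pj->pi", t_other - t_ref[:, 0:1, :], n)
        strict = ~((dv >= -eps).all(axis=1) | (dv <= eps).all(axis=1))
        coplanar = (np.abs(dv) <= eps).all(axis=1)
        return strict | coplanar

    keep = straddles(ta, tb) & straddles(tb, ta)
    pairs = pairs[keep]
    hits = []
    for i, j in pairs:
        if _tri_tri_intersect(tri[i], tri[j]):
            hits.append((int(i), int(j)))
            if limit is not None and len(hits) >= limit:
                break
    return hits
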