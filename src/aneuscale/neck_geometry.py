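"""Neck-frame construction, neck-curve extraction and sac/vessel splitting.

The neck cutting plane is user input (point + normal, or three points); no
automatic neck detection is attempted.  ``build_neck_frame`` re-expresses
the model in a frame where the neck plane is ``{z = d}`` with the sac on
the +z side, using the minimal rotation taking the plane normal onto +z
(the in-plane rotation is under-determined and fixed to zero).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from shapely.geometry import Point as _ShapelyPoint
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import GeometryError
from .mesh_core import (
    LABEL_NECK,
    LABEL_SAC,
    LABEL_VESSEL,
    RigidTransform,
    TriangleMesh,
    apply_transform,
)

#: "on the plane" tolerance (mm), matching the STL merge tolerance.
PLANE_TOL = 1e-6


@dataclass(frozen=True)
class Plane:
    """Plane given by a point on it and a unit normal oriented toward the
    sac side."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.point, dtype=np.float64).reshape(3)
        n = np.asarray(self.normal, dtype=np.float64).reshape(3)
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            raise GeometryError("degenerate plane normal")
        n = n / norm
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "normal", n)

    @classmethod
    def from_three_points(cls, p1, p2, p3, sac_side=None) -> "Plane":
        """Plane through three points; ``sac_side`` orients the normal
        toward that point when given."""
        p1, p2, p3 = (np.asarray(p, dtype=np.float64) for p in (p1, p2, p3))
        n = np.cross(p2 - p1, p3 - p1)
        if np.linalg.norm(n) < 1e-12:
            raise GeometryError("three points are collinear")
        plane = cls(p1, n)
        if sac_side is not None and plane.signed_distance(sac_side) < 0:
            plane = cls(p1, -plane.normal)
        return plane

    @classmethod
    def from_json(cls, spec) -> "Plane":
        """Parse ``{"point": [...], "normal": [...]}`` or
        ``{"three_points": [[...]]*3, "sac_side": [...]}`` (dict, JSON
        string, or path to a JSON file)."""
        if isinstance(spec, (str, bytes)):
            spec = json.loads(spec)
        elif hasattr(spec, "read_text"):
            spec = json.loads(spec.read_text())
        if "three_points" in spec:
            pts = spec["three_points"]
            return cls.from_three_points(*pts, sac_side=spec.get("sac_side"))
        return cls(spec["point"], spec["normal"])

    def signed_distance(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        return (pts - self.point) @ self.normal

    def to_json(self) -> dict:
        return {"point": self.point.tolist(), "normal": self.normal.tolist()}


@dataclass(frozen=True)
class NeckCurve:
    """Closed polyline of the neck ostium on the neck plane.

    ``points`` is (n+1, 3) with ``points[0] == points[-1]``; ``perimeter``
    is the polyline length and ``centroid`` the arc-length-weighted mean
    (robust to non-uniform tessellation, unlike the vertex mean).
    """

    points: np.ndarray
    perimeter: float
    centroid: np.ndarray

    @classmethod
    def from_loop(cls, loop: np.ndarray) -> "NeckCurve":
        loop = np.asarray(loop, dtype=np.float64)
        if not np.allclose(loop[0], loop[-1]):
            loop = np.vstack([loop, loop[0]])
        seg = np.diff(loop, axis=0)
        lengths = np.linalg.norm(seg, axis=1)
        perimeter = float(lengths.sum())
        if perimeter <= 0:
            raise GeometryError("neck curve has zero perimeter")
        mids = 0.5 * (loop[:-1] + loop[1:])
        centroid = (mids * lengths[:, None]).sum(axis=0) / perimeter
        return cls(points=loop, perimeter=perimeter, centroid=centroid)

    @property
    def ring(self) -> np.ndarray:
        """Loop points without the duplicated closing point."""
        return self.points[:-1]


@dataclass
class NeckFrameModel:
    """Model re-expressed in the neck frame: plane is ``{z = d}``, sac above.

    ``transform`` maps original coordinates into the frame;
    ``extract_neck_curve`` and ``split_sac`` populate ``neck_curve`` and the
    vertex labels.
    """

    mesh: TriangleMesh
    transform: RigidTransform
    d: float
    neck_curve: NeckCurve | None = None

    @property
    def plane(self) -> Plane:
        return Plane(point=(0.0, 0.0, self.d), normal=(0.0, 0.0, 1.0))

    @property
    def sac_vertices(self) -> np.ndarray:
        if self.mesh.labels is None:
            raise GeometryError("sac not labeled; call split_sac first")
        return np.flatnonzero(self.mesh.labels == LABEL_SAC)

    @property
    def vessel_vertices(self) -> np.ndarray:
        if self.mesh.labels is None:
            raise GeometryError("sac not labeled; call split_sac first")
        return np.flatnonzero(self.mesh.labels == LABEL_VESSEL)


def build_neck_frame(mesh: TriangleMesh, plane: Plane) -> NeckFrameModel:
    """Rigidly re-express ``mesh`` so the neck plane becomes ``{z = d}``.

    The rotation is the geodesic rotation taking ``plane.normal`` to +z and
    the translation is zero, so ``d = plane.point . plane.normal`` and the
    construction is deterministic.
    """
    rot = RigidTransform.rotation_between(plane.normal, np.array([0.0, 0.0, 1.0]))
    d = float(np.dot(plane.point, plane.normal))
    return NeckFrameModel(mesh=apply_transform(mesh, rot), transform=rot, d=d)


# ---------------------------------------------------------------------------
# mesh / plane intersection
# ---------------------------------------------------------------------------


def cross_section(
    mesh: TriangleMesh,
    z: float,
    face_mask: np.ndarray | None = None,
    tol: float = PLANE_TOL,
):
    """Intersect the horizontal plane at height ``z`` with the mesh.

    Returns a list of closed loops, each an (n, 3) array of points ordered
    along the loop (not repeating the first point).  Segment endpoints are
    keyed topologically (by crossed edge or on-plane vertex), so chaining is
    exact and independent of floating-point noise.  Vertices within ``tol``
    of the plane are treated as lying below it, which makes a ring of
    vertices exactly on the plane reproduce its own polygon.
    """
    faces = mesh.faces if face_mask is None else mesh.faces[face_mask]
    if len(faces) == 0:
        raise GeometryError("plane misses mesh: no faces to intersect")
    dz = mesh.vertices[:, 2] - z
    above = dz > tol

    fa = above[faces]
    n_above = fa.sum(axis=1)
    crossing = (n_above > 0) & (n_above < 3)
    if not crossing.any():
        raise GeometryError(f"plane misses mesh at z={z}")

    segments = {}  # frozenset of endpoint keys -> (key_a, key_b, pt_a, pt_b)
    for tri in faces[crossing]:
        pts = []
        keys = []
        for e in range(3):
            i, j = int(tri[e]), int(tri[(e + 1) % 3])
            if above[i] == above[j]:
                continue
            if above[j]:  # orient edge below -> above
                i, j = j, i
            # now i above, j below-or-on
            if abs(dz[j]) <= tol:
                key = ("v", j)
                pt = mesh.vertices[j]
            else:
                a, b = (i, j) if i < j else (j, i)  # canonical edge order
                t = dz[a] / (dz[a] - dz[b])
                pt = mesh.vertices[a] + t * (mesh.vertices[b] - mesh.vertices[a])
                key = ("e", a, b)
            keys.append(key)
            pts.append(pt)
        if len(keys) != 2 or keys[0] == keys[1]:
            continue  # grazing contact, zero-length
        skey = frozenset(keys)
        segments.setdefault(skey, (keys[0], keys[1], pts[0], pts[1]))
    if not segments:
        raise GeometryError(f"plane at z={z} only grazes the mesh")

    # endpoint adjacency
    adjacency: dict = {}
    for ka, kb, pa, pb in segments.values():
        adjacency.setdefault(ka, []).append((kb, pa, pb))
        adjacency.setdefault(kb, []).append((ka, pb, pa))
    for key, nbrs in adjacency.items():
        if len(nbrs) == 1:
            pt = nbrs[0][1]
            raise GeometryError(
                "open intersection chain (non-watertight cut); gap near "
                f"({pt[0]:.4f}, {pt[1]:.4f}, {pt[2]:.4f})"
            )
        if len(nbrs) > 2:
            raise GeometryError(
                "non-manifold intersection: endpoint shared by "
                f"{len(nbrs)} segments at z={z}"
            )

    loops = []
    visited = set()
    for start in adjacency:
        if start in visited:
            continue
        loop_keys = [start]
        loop_pts = [adjacency[start][0][1]]
        visited.add(start)
        prev, current = start, adjacency[start][0][0]
        current_pt = adjacency[start][0][2]
        while current != start:
            loop_keys.append(current)
            loop_pts.append(current_pt)
            visited.add(current)
            nxt = [
                (k, pb)
                for k, pa, pb in adjacency[current]
                if k != prev
            ]
            prev, (current, current_pt) = current, nxt[0]
        loops.append(np.asarray(loop_pts))
    return loops


def _loop_polygon(loop: np.ndarray) -> _ShapelyPolygon:
    return _ShapelyPolygon(loop[:, :2])


def select_loop(loops, inside_xy) -> np.ndarray:
    """Pick the loop whose in-plane polygon contains ``inside_xy``."""
    target = _ShapelyPoint(float(inside_xy[0]), float(inside_xy[1]))
    containing = [lp for lp in loops if _loop_polygon(lp).contains(target)]
    if not containing:
        raise GeometryError(
            "no intersection loop encloses the sac-side reference point"
        )
    # innermost loop if nested
    return min(containing, key=lambda lp: _loop_polygon(lp).area)


def extract_neck_curve(frame_model: NeckFrameModel) -> NeckFrameModel:
    """Cut the mesh at the neck plane and chain the loop enclosing the
    sac-side centroid projection into the neck curve."""
    mesh = frame_model.mesh
    loops = cross_section(mesh, frame_model.d)
    above = mesh.vertices[:, 2] > frame_model.d + PLANE_TOL
    if not above.any():
        raise GeometryError("no vertices above the neck plane")
    ref = mesh.vertices[above, :2].mean(axis=0)
    loop = select_loop(loops, ref)
    poly = _loop_polygon(loop)
    if not poly.is_simple:
        raise GeometryError("neck curve self-intersects in-plane")
    curve = NeckCurve.from_loop(loop)
    if np.abs(curve.points[:, 2] - frame_model.d).max() > PLANE_TOL:
        raise GeometryError("neck curve deviates from the neck plane")
    return replace(frame_model, neck_curve=curve)


# ---------------------------------------------------------------------------
# sac / vessel split
# ---------------------------------------------------------------------------


def split_sac(
    frame_model: NeckFrameModel, apex_seed, tol: float = PLANE_TOL
) -> NeckFrameModel:
    """Label vertices as sac / vessel / neck.

    Vertices strictly above the neck plane are partitioned into connected
    components; the component containing the vertex nearest ``apex_seed``
    is the sac (a curved parent vessel may also rise above the plane and
    must not be labeled sac).  On-plane vertices adjacent to the sac are
    labeled neck; everything else is vessel.
    """
    mesh = frame_model.mesh
    apex_seed = np.asarray(apex_seed, dtype=np.float64).reshape(3)
    if apex_seed[2] <= frame_model.d + tol:
        raise GeometryError("apex seed must lie strictly above the neck plane")
    z = mesh.vertices[:, 2]
    above = z > frame_model.d + tol
    if not above.any():
        raise GeometryError("no vertices above the neck plane")

    idx_above = np.flatnonzero(above)
    seed_vertex = idx_above[
        np.argmin(np.linalg.norm(mesh.vertices[idx_above] - apex_seed, axis=1))
    ]
    # components of the above-plane vertex subgraph
    e = mesh.edges()
    keep = above[e[:, 0]] & above[e[:, 1]]
    e = e[keep]
    adj = coo_matrix(
        (np.ones(len(e)), (e[:, 0], e[:, 1])),
        shape=(mesh.n_vertices, mesh.n_vertices),
    )
    _, comp = connected_components(adj, directed=False)
    sac = above & (comp == comp[seed_vertex])

    # neck = on-plane vertices sharing an edge with a sac vertex
    all_edges = mesh.edges()
    on_plane = np.abs(z - frame_model.d) <= tol
    neck = np.zeros(mesh.n_vertices, dtype=bool)
    touches = sac[all_edges[:, 0]] | sac[all_edges[:, 1]]
    neck[all_edges[touches].ravel()] = True
    neck &= on_plane

    labels = np.full(mesh.n_vertices, LABEL_VESSEL, dtype=np.int8)
    labels[sac] = LABEL_SAC
    labels[neck] = LABEL_NECK

    # warn when the sac component reaches an open boundary ring (the parent
    # vessel probably crosses the cutting plane)
    und = mesh.edges()
    uview = und.view([("a", "i8"), ("b", "i8")]).ravel()
    uniq, counts = np.unique(uview, return_counts=True)
    if (counts == 1).any():
        boundary_vertices = np.unique(
            np.array([(u["a"], u["b"]) for u in uniq[counts == 1]]).ravel()
        )
        if sac[boundary_vertices].any():
            warnings.warn(
                "sac component touches an open boundary ring; the parent "
                "vessel likely crosses the neck plane",
                stacklevel=2,
            )

    labeled = TriangleMesh(mesh.vertices.copy(), mesh.faces.copy(), labels)
    return replace(frame_model, mesh=labeled)
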