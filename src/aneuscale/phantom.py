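"""Synthetic vessel + sac phantoms with analytic ground truth.

The phantom stands in for a patient-derived surface in every test: a capped
tube (the parent vessel) below the neck plane and a half-ellipsoid sac
closed by a planar base disk sitting on it.  Because the sac is a half
ellipsoid with base radius ``r`` and polar semi-axis ``c_h``, the neck
perimeter is exactly ``2 pi r`` and the analytic size ratio is
``c_h / (2 r)`` — a hemisphere (``c_h = r``) has ratio 0.5.

The default vessel diameter of 3.478 mm mirrors a typical inlet diameter of
an intracranial parent artery, keeping the scale clinically realistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError
from .mesh_core import TriangleMesh, orient_consistently
from .morphometry import Morphometry
from .neck_geometry import Plane

#: default vessel diameter (mm)
DEFAULT_VESSEL_DIAMETER = 3.478


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic vessel + sac model (mm)."""

    vessel_radius: float = DEFAULT_VESSEL_DIAMETER / 2.0
    vessel_length: float = 20.0
    sac_radius: float = 1.0
    sac_height: float = 1.0
    neck_offset: float = 0.0
    gap: float = 0.1
    tessellation: int = 64
    jitter: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "vessel_radius",
            "vessel_length",
            "sac_radius",
            "sac_height",
            "gap",
        ):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if self.tessellation < 16:
            raise GeometryError("tessellation must be at least 16")

    @property
    def neck_plane_z(self) -> float:
        return self.vessel_radius + self.gap

    @property
    def analytic(self) -> Morphometry:
        return Morphometry.from_height_perimeter(
            self.sac_height, 2.0 * np.pi * self.sac_radius
        )


@dataclass(frozen=True)
class PhantomResult:
    mesh: TriangleMesh
    plane: Plane
    apex_seed: np.ndarray
    analytic: Morphometry
    #: vertex count strictly above the neck plane belonging to the sac
    expected_sac_vertices: int


def _sac_component(spec: PhantomSpec):
    """Half-ellipsoid dome closed by its base disk; returns (verts, faces)."""
    n = spec.tessellation
    stacks = max(4, n // 4)
    r, ch = spec.sac_radius, spec.sac_height
    x0, y0, z0 = spec.neck_offset, 0.0, spec.neck_plane_z
    theta = 2.0 * np.pi * np.arange(n) / n

    verts = []
    for i in range(stacks):  # ring 0 on the plane, rings rise toward apex
        phi = 0.5 * np.pi * i / stacks
        ring = np.column_stack(
            [
                x0 + r * np.cos(phi) * np.cos(theta),
                y0 + r * np.cos(phi) * np.sin(theta),
                np.full(n, z0 + ch * np.sin(phi)),
            ]
        )
        verts.append(ring)
    apex = np.array([[x0, y0, z0 + ch]])
    disk_center = np.array([[x0, y0, z0]])
    verts = np.vstack(verts + [apex, disk_center])
    apex_i = stacks * n
    center_i = apex_i + 1

    faces = []
    for i in range(stacks - 1):
        base = i * n
        nxt = base + n
        for j in range(n):
            j2 = (j + 1) % n
            faces.append((base + j, base + j2, nxt + j2))
            faces.append((base + j, nxt + j2, nxt + j))
    top = (stacks - 1) * n
    for j in range(n):
        faces.append((top + j, top + (j + 1) % n, apex_i))
    for j in range(n):  # base disk, wound downward
        faces.append((center_i, (j + 1) % n, j))
    return verts, np.asarray(faces, dtype=np.int64)


def _tube_component(spec: PhantomSpec, bend_radius: float | None):
    """Capped tube along x; optionally arched upward in the xz plane."""
    n = spec.tessellation
    R, L = spec.vessel_radius, spec.vessel_length
    circumference_step = 2.0 * np.pi * R / n
    nx = max(8, int(round(L / circumference_step)))
    theta = 2.0 * np.pi * np.arange(n) / n

    rings = []
    centers = []
    if bend_radius is None:
        xs = np.linspace(-L / 2.0, L / 2.0, nx + 1)
        for x in xs:
            rings.append(
                np.column_stack(
                    [np.full(n, x), R * np.cos(theta), R * np.sin(theta)]
                )
            )
            centers.append(np.array([x, 0.0, 0.0]))
    else:
        B = bend_radius
        T = L / (2.0 * B)
        if T >= np.pi / 2.0:
            raise GeometryError("bend too tight for the vessel length")
        for t in np.linspace(-T, T, nx + 1):
            center = np.array([B * np.sin(t), 0.0, B * (1.0 - np.cos(t))])
            nu = np.array([-np.sin(t), 0.0, np.cos(t)])  # in-plane normal
            ey = np.array([0.0, 1.0, 0.0])
            rings.append(
                center
                + R * np.cos(theta)[:, None] * nu
                + R * np.sin(theta)[:, None] * ey
            )
            centers.append(center)
    verts = np.vstack(rings + [centers[0][None, :], centers[-1][None, :]])
    cap0 = (nx + 1) * n
    cap1 = cap0 + 1

    faces = []
    for i in range(nx):
        base = i * n
        nxt2 = base + n
        for j in range(n):
            j2 = (j + 1) % n
            faces.append((base + j, nxt2 + j, nxt2 + j2))
            faces.append((base + j, nxt2 + j2, base + j2))
    for j in range(n):
        faces.append((cap0, (j + 1) % n, j))
        faces.append((cap1, nx * n + j, nx * n + (j + 1) % n))
    return verts, np.asarray(faces, dtype=np.int64)


def _assemble(spec: PhantomSpec, bend_radius: float | None) -> PhantomResult:
    if abs(spec.neck_offset) + spec.sac_radius > spec.vessel_length / 2.0:
        raise GeometryError("sac overlaps the tube ends")
    sac_v, sac_f = _sac_component(spec)
    tube_v, tube_f = _tube_component(spec, bend_radius)

    d = spec.neck_plane_z
    if bend_radius is not None:
        near_sac = np.abs(tube_v[:, 0] - spec.neck_offset) < spec.sac_radius + spec.vessel_radius
        if (tube_v[near_sac, 2] > d - 1e-9).any():
            raise GeometryError("bend intersects the sac region")

    verts = np.vstack([sac_v, tube_v])
    faces = np.vstack([sac_f, tube_f + len(sac_v)])

    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        onplane = np.abs(verts[:, 2] - d) <= 1e-9
        noise = rng.normal(scale=spec.jitter, size=verts.shape)
        noise[onplane] = 0.0
        verts = verts + noise

    mesh = orient_consistently(TriangleMesh(verts, faces))
    plane = Plane(point=(spec.neck_offset, 0.0, d), normal=(0.0, 0.0, 1.0))
    apex_seed = np.array([spec.neck_offset, 0.0, d + spec.sac_height])
    stacks = max(4, spec.tessellation // 4)
    expected_sac = (stacks - 1) * spec.tessellation + 1
    return PhantomResult(
        mesh=mesh,
        plane=plane,
        apex_seed=apex_seed,
        analytic=spec.analytic,
        expected_sac_vertices=expected_sac,
    )


def make_phantom(spec: PhantomSpec) -> PhantomResult:
    """Straight-vessel phantom: watertight two-component surface (closed
    tube, closed sac) with the sac base plane as neck plane."""
    return _assemble(spec, bend_radius=None)


def make_curved_phantom(spec: PhantomSpec, bend_radius: float) -> PhantomResult:
    """Phantom whose vessel arches upward so its far ends rise above the
    neck plane — exercises seeded sac selection in ``split_sac``."""
    if bend_radius <= spec.vessel_radius:
        raise GeometryError("bend_radius must exceed vessel_radius")
    return _assemble(spec, bend_radius=bend_radius)
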