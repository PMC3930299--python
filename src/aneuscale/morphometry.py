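"""Sac morphometry: height, perimeter-derived neck diameter, size ratio,
and the three parallel measurement planes used for quantitative analysis.

The size ratio (ASR) is the perpendicular sac height above the neck plane
divided by the average neck diameter, where the average diameter is the
neck perimeter divided by pi.  Unlike the classical aspect ratio (height
over neck width), it does not depend on a viewing direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .errors import GeometryError
from .neck_geometry import (
    LABEL_NECK,
    LABEL_SAC,
    NeckFrameModel,
    Plane,
    cross_section,
    select_loop,
)


@dataclass(frozen=True)
class Morphometry:
    """Height ``h`` (mm), neck perimeter (mm), perimeter-derived average
    neck diameter ``D = perimeter / pi`` (mm) and ``asr = h / D``."""

    h: float
    neck_perimeter: float
    avg_neck_diameter: float
    asr: float

    @classmethod
    def from_height_perimeter(cls, h: float, perimeter: float) -> "Morphometry":
        if h <= 0:
            raise GeometryError(f"non-positive sac height {h}")
        if perimeter <= 0:
            raise GeometryError(f"non-positive neck perimeter {perimeter}")
        d = perimeter / np.pi
        return cls(h=h, neck_perimeter=perimeter, avg_neck_diameter=d, asr=h / d)

    def as_dict(self) -> dict:
        return {
            "h_mm": self.h,
            "perimeter_mm": self.neck_perimeter,
            "D_mm": self.avg_neck_diameter,
            "ASR": self.asr,
        }


@dataclass(frozen=True)
class MeasurementPlanes:
    """Three planes parallel to the neck plane partitioning the sac height
    into equal thirds: P3 at the neck (z = d), P2 at d + h/3, P1 at
    d + 2h/3.  Each plane carries its sac cross-section polygon."""

    p1: Plane
    p2: Plane
    p3: Plane
    sections: tuple  # (loop_p1, loop_p2, loop_p3) as (n, 3) arrays

    @property
    def planes(self) -> tuple:
        return (self.p1, self.p2, self.p3)

    @property
    def heights(self) -> np.ndarray:
        return np.array([p.point[2] for p in self.planes])


def measure(frame_model: NeckFrameModel) -> Morphometry:
    """Morphometry of a labeled neck-frame model.

    The height is the maximum perpendicular distance of sac vertices above
    the neck plane (the apex); no smoothing or percentile is applied.
    """
    if frame_model.neck_curve is None:
        raise GeometryError("neck curve not extracted")
    sac = frame_model.sac_vertices
    if len(sac) == 0:
        raise GeometryError("no sac vertices above the neck plane")
    h = float(frame_model.mesh.vertices[sac, 2].max() - frame_model.d)
    return Morphometry.from_height_perimeter(h, frame_model.neck_curve.perimeter)


def measurement_planes(
    frame_model: NeckFrameModel, morph: Morphometry | None = None
) -> MeasurementPlanes:
    """The P1/P2/P3 planes with their sac cross-section polygons.

    P3 reuses the neck curve; P1 and P2 are cut through the sac-labeled
    faces only, so a parent vessel rising above the neck plane cannot
    contribute spurious loops.
    """
    if morph is None:
        morph = measure(frame_model)
    d, h = frame_model.d, morph.h
    mesh = frame_model.mesh
    normal = (0.0, 0.0, 1.0)
    xy = frame_model.neck_curve.centroid[:2]

    sac_like = (mesh.labels == LABEL_SAC) | (mesh.labels == LABEL_NECK)
    face_mask = sac_like[mesh.faces].all(axis=1)

    sections = []
    for frac in (2.0 / 3.0, 1.0 / 3.0):
        zc = d + frac * h
        try:
            loops = cross_section(mesh, zc, face_mask=face_mask)
        except GeometryError as exc:
            raise GeometryError(
                f"measurement plane at z={zc:.4f} fails to intersect the sac"
            ) from exc
        sections.append(select_loop(loops, xy))
    sections.append(frame_model.neck_curve.ring)

    p1 = Plane(point=(xy[0], xy[1], d + 2.0 * h / 3.0), normal=normal)
    p2 = Plane(point=(xy[0], xy[1], d + h / 3.0), normal=normal)
    p3 = Plane(point=(xy[0], xy[1], d), normal=normal)
    return MeasurementPlanes(p1=p1, p2=p2, p3=p3, sections=tuple(sections))


def classical_aspect_ratio(frame_model: NeckFrameModel) -> float:
    """Height divided by neck width, the classical (view-dependent when
    measured on projections) aspect ratio.

    Neck width is the maximum in-plane chord of the neck polyline, which is
    rotation-independent.  Agrees with the size ratio exactly for circular
    necks.
    """
    morph = measure(frame_model)
    ring = frame_model.neck_curve.ring[:, :2]
    if len(ring) < 3:
        raise GeometryError("neck polyline is degenerate")
    try:
        hull = ring[ConvexHull(ring).vertices]
    except Exception as exc:  # collinear ring
        raise GeometryError("neck polyline is degenerate") from exc
    width = float(pdist(hull).max())
    if width <= 0:
        raise GeometryError("neck width is zero")
    return morph.h / width
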