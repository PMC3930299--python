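"""Height-graded anisotropic sac scaling.

A point of the sac at height ``z`` above the neck plane (anchored at the
neck centroid ``(x_m, y_m, z_m)``) is mapped by

    x_t - x_m = [1 + a (z - z_m)(k - 1)/h] (x - x_m)
    y_t - y_m = [1 + b (z - z_m)(k - 1)/h] (y - y_m)
    z_t - z_m = [1 + c (z - z_m)(k - 1)/h] (z - z_m)

for ``z > z_m`` only; the neck and the parent vessel are untouched.  The
per-point factor grows linearly with height, so growth is graded from zero
displacement at the neck to maximal displacement at the apex — the sac
expands (or shrinks) most at the fundus.  With ``c = 1`` the apex at
``z_m + h`` maps exactly to ``z_m + k h``, so ``k`` is the ratio of scaled
to original sac height and the size ratio scales exactly by ``k`` (the
neck perimeter being invariant).

Defaults ``a = b = 2, c = 1``.  Shrinking has a hard floor: with those
defaults any ``k <= 1/2`` drives the apex lateral factor ``1 + a(k-1)`` to
zero or below, collapsing or inverting the mesh.  ``validate_params``
reports this; strict mode refuses, stepwise mode splits ``k`` into equal
geometric sub-steps that each stay feasible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import FeasibilityError, GeometryError
from .mesh_core import LABEL_SAC, TriangleMesh, check_validity
from .morphometry import Morphometry, measure
from .neck_geometry import NeckFrameModel, extract_neck_curve

#: paper-configuration gradation coefficients
DEFAULT_ABC = (2.0, 2.0, 1.0)

#: default size-ratio schedule for series generation
DEFAULT_SCHEDULE = (0.3, 0.5, 0.7, 1.0, 1.3, 1.5, 1.7, 2.0)

#: every per-step scale factor must exceed this in stepwise mode
STEP_MARGIN = 0.05


@dataclass(frozen=True)
class ScalingParams:
    """Gradation coefficients (a, b, c), height factor k, and the neck-frame
    anchors: neck centroid (x_m, y_m, z_m) and pre-scaling sac height h."""

    a: float
    b: float
    c: float
    k: float
    x_m: float
    y_m: float
    z_m: float
    h: float

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise GeometryError(f"non-positive sac height h={self.h}")
        if self.k <= 0:
            raise GeometryError(f"non-positive scaling factor k={self.k}")

    @classmethod
    def from_model(
        cls,
        frame_model: NeckFrameModel,
        k: float,
        a: float = DEFAULT_ABC[0],
        b: float = DEFAULT_ABC[1],
        c: float = DEFAULT_ABC[2],
        morph: Morphometry | None = None,
    ) -> "ScalingParams":
        """Anchor parameters at the model's neck centroid and measured height."""
        if frame_model.neck_curve is None:
            raise GeometryError("neck curve not extracted")
        if morph is None:
            morph = measure(frame_model)
        cx, cy, _ = frame_model.neck_curve.centroid
        return cls(
            a=a, b=b, c=c, k=k, x_m=float(cx), y_m=float(cy),
            z_m=frame_model.d, h=morph.h,
        )


@dataclass(frozen=True)
class FeasibilityReport:
    """Injectivity / positivity diagnostics for a parameter set.

    ``lateral_x`` and ``lateral_y`` are the apex lateral factors
    ``1 + a(k-1)`` and ``1 + b(k-1)``; ``min_z_derivative`` is the minimum
    of the z-map derivative ``1 + 2c(z-z_m)(k-1)/h`` over the sac height,
    i.e. ``min(1, 1 + 2c(k-1))``.  Feasible iff all are positive.
    """

    lateral_x: float
    lateral_y: float
    min_z_derivative: float
    feasible: bool

    def worst(self) -> float:
        return min(self.lateral_x, self.lateral_y, self.min_z_derivative)

    def as_dict(self) -> dict:
        return {
            "lateral_x": self.lateral_x,
            "lateral_y": self.lateral_y,
            "min_z_derivative": self.min_z_derivative,
            "feasible": self.feasible,
        }


def validate_params(params: ScalingParams) -> FeasibilityReport:
    """Report whether the transform keeps all scale factors positive over
    the sac (guards injectivity, which shrinking can break)."""
    km1 = params.k - 1.0
    lat_x = 1.0 + params.a * km1
    lat_y = 1.0 + params.b * km1
    min_dz = min(1.0, 1.0 + 2.0 * params.c * km1)
    feasible = lat_x > 0 and lat_y > 0 and min_dz > 0
    return FeasibilityReport(
        lateral_x=lat_x, lateral_y=lat_y, min_z_derivative=min_dz,
        feasible=feasible,
    )


def solve_k(current_asr: float, target_asr: float) -> float:
    """Height factor taking the current size ratio to the target.

    Exact because (with c = 1) the sac height scales by k while the neck
    diameter is invariant, so ASR scales by k.
    """
    if current_asr <= 0 or target_asr <= 0:
        raise GeometryError("size ratios must be positive")
    return target_asr / current_asr


def scale_points(points: np.ndarray, params: ScalingParams) -> np.ndarray:
    """Vectorised height-graded map; rows with ``z <= z_m`` pass through."""
    pts = np.asarray(points, dtype=np.float64)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts).copy()
    dz = pts[:, 2] - params.z_m
    gate = dz > 0
    grade = dz[gate] * (params.k - 1.0) / params.h
    out = pts
    out[gate, 0] = params.x_m + (1.0 + params.a * grade) * (pts[gate, 0] - params.x_m)
    out[gate, 1] = params.y_m + (1.0 + params.b * grade) * (pts[gate, 1] - params.y_m)
    out[gate, 2] = params.z_m + (1.0 + params.c * grade) * dz[gate]
    return out[0] if single else out


def scale_point(point, params: ScalingParams) -> np.ndarray:
    """Single-point convenience wrapper around :func:`scale_points`."""
    return scale_points(np.asarray(point, dtype=np.float64), params)


@dataclass(frozen=True)
class ScaleResult:
    model: NeckFrameModel
    k: float
    n_steps: int
    feasibility: FeasibilityReport


def _minimal_steps(k: float, a: float, b: float, c: float, margin: float) -> int:
    """Smallest n such that each geometric sub-step k**(1/n) keeps every
    factor above ``margin``."""
    for n in range(1, 10_000):
        ks = k ** (1.0 / n)
        km1 = ks - 1.0
        if (
            1.0 + a * km1 > margin
            and 1.0 + b * km1 > margin
            and min(1.0, 1.0 + 2.0 * c * km1) > margin
        ):
            return n
    raise FeasibilityError(f"cannot decompose k={k} into feasible steps")


def scale_sac(
    frame_model: NeckFrameModel,
    params: ScalingParams,
    mode: str = "strict",
) -> ScaleResult:
    """Apply the height-graded map to sac-labeled vertices above the neck.

    Only sac-labeled vertices move (a curved parent vessel above the plane
    stays put); the neck curve and every vertex at or below ``z_m`` are
    unchanged, and topology is preserved.  In ``stepwise`` mode an
    infeasible single-step ``k`` is split into the minimal number of equal
    geometric sub-steps, re-measuring ``h`` between steps.
    """
    if mode not in ("strict", "stepwise"):
        raise ValueError(f"unknown mode {mode!r}")
    if frame_model.mesh.labels is None:
        raise GeometryError("sac not labeled; call split_sac first")
    report = validate_params(params)
    if mode == "strict":
        if not report.feasible:
            raise FeasibilityError(
                "infeasible scaling: "
                f"apex lateral factors ({report.lateral_x:.4g}, "
                f"{report.lateral_y:.4g}), min z-derivative "
                f"{report.min_z_derivative:.4g}; use stepwise mode"
            )
        n_steps = 1
    else:
        n_steps = _minimal_steps(
            params.k, params.a, params.b, params.c, STEP_MARGIN
        )

    k_step = params.k ** (1.0 / n_steps)
    model = frame_model
    step_params = replace(params, k=k_step)
    for _ in range(n_steps):
        mesh = model.mesh
        sac_mask = mesh.labels == LABEL_SAC
        verts = mesh.vertices.copy()
        verts[sac_mask] = scale_points(verts[sac_mask], step_params)
        model = replace(
            model,
            mesh=TriangleMesh(verts, mesh.faces.copy(), mesh.labels.copy()),
        )
        # height after a feasible step is exactly k_step * h for c = 1 and
        # (1 + c(k_step-1)) * h otherwise; re-measure rather than assume
        new_h = float(verts[sac_mask, 2].max() - model.d)
        step_params = replace(step_params, h=new_h)
    return ScaleResult(
        model=model, k=params.k, n_steps=n_steps, feasibility=report
    )


@dataclass(frozen=True)
class SeriesEntry:
    target_asr: float
    k: float
    n_steps: int
    measured_asr: float
    model: NeckFrameModel
    watertight: bool
    self_intersecting: bool | None


@dataclass(frozen=True)
class SeriesResult:
    entries: tuple

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "target_asr": e.target_asr,
                    "k": e.k,
                    "steps": e.n_steps,
                    "measured_asr": e.measured_asr,
                    "watertight": e.watertight,
                    "self_intersecting": e.self_intersecting,
                }
                for e in self.entries
            ]
        )


def generate_series(
    frame_model: NeckFrameModel,
    asr_schedule=DEFAULT_SCHEDULE,
    a: float = DEFAULT_ABC[0],
    b: float = DEFAULT_ABC[1],
    c: float = DEFAULT_ABC[2],
    mode: str = "strict",
    check_self_intersections: bool = False,
) -> SeriesResult:
    """One scaled model per schedule entry, each generated independently
    from the original (not chained), so entries are order-independent and
    ``k = target / current`` exactly.
    """
    schedule = [float(t) for t in asr_schedule]
    if any(t <= 0 for t in schedule):
        raise GeometryError("size-ratio schedule entries must be positive")
    morph = measure(frame_model)
    entries = []
    for target in schedule:
        k = solve_k(morph.asr, target)
        params = ScalingParams.from_model(frame_model, k=k, a=a, b=b, c=c, morph=morph)
        try:
            result = scale_sac(frame_model, params, mode=mode)
        except FeasibilityError as exc:
            raise FeasibilityError(
                f"schedule entry ASR={target} (k={k:.4g}) is infeasible in "
                f"strict mode: {exc}"
            ) from exc
        # re-extract the neck curve from the scaled mesh so the re-measured
        # ratio is a genuine recomputation, not a carried-over value
        scaled = extract_neck_curve(replace(result.model, neck_curve=None))
        remeasured = measure(scaled)
        validity = check_validity(
            scaled.mesh, self_intersections=check_self_intersections
        )
        entries.append(
            SeriesEntry(
                target_asr=target,
                k=k,
                n_steps=result.n_steps,
                measured_asr=remeasured.asr,
                model=scaled,
                watertight=validity.watertight,
                self_intersecting=validity.self_intersecting,
            )
        )
    return SeriesResult(entries=tuple(entries))
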