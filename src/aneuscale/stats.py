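"""Correlation of the size ratio with plane-averaged field summaries.

Hemodynamic fields (velocity, wall shear stress, ...) are external inputs
produced by a flow solver; this module only averages point samples over the
three measurement planes and correlates summaries against the size ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .errors import GeometryError
from .morphometry import MeasurementPlanes

#: required columns of a field-sample table
SAMPLE_COLUMNS = ("model_id", "x", "y", "z", "value", "field_name")


def pearson_r(x, y) -> float:
    """Product-moment correlation coefficient.

    Requires equal-length vectors with at least 3 entries and nonzero
    variance on both sides.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input")
    return float(_scipy_stats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class PlaneAverages:
    """Per-plane arithmetic means (NaN when a plane received no samples),
    their counts, and the grand mean taken as the mean of plane means."""

    mean_p1: float
    mean_p2: float
    mean_p3: float
    counts: tuple
    n_unassigned: int

    @property
    def grand_mean(self) -> float:
        means = np.array([self.mean_p1, self.mean_p2, self.mean_p3])
        if np.isnan(means).all():
            return float("nan")
        return float(np.nanmean(means))

    def as_dict(self) -> dict:
        return {
            "mean_P1": self.mean_p1,
            "mean_P2": self.mean_p2,
            "mean_P3": self.mean_p3,
            "grand_mean": self.grand_mean,
            "counts": list(self.counts),
            "n_unassigned": self.n_unassigned,
        }


def plane_average(
    points: np.ndarray,
    values: np.ndarray,
    planes: MeasurementPlanes,
) -> PlaneAverages:
    """Assign neck-frame samples to the nearest measurement plane and
    average per plane.

    A sample belongs to a plane when its height is within half the plane
    spacing (h/6) of it; samples outside every band are counted as
    unassigned and ignored.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    values = np.asarray(values, dtype=np.float64)
    if len(points) != len(values):
        raise ValueError("points and values must align")
    heights = planes.heights  # (z_p1, z_p2, z_p3)
    spacing = float(heights[0] - heights[1])
    if spacing <= 0:
        raise GeometryError("measurement planes are not ordered top-down")
    band = spacing / 2.0
    dist = np.abs(points[:, 2][:, None] - heights[None, :])
    nearest = np.argmin(dist, axis=1)
    within = dist[np.arange(len(points)), nearest] <= band

    means = []
    counts = []
    for p in range(3):
        sel = within & (nearest == p)
        counts.append(int(sel.sum()))
        means.append(float(values[sel].mean()) if sel.any() else float("nan"))
    return PlaneAverages(
        mean_p1=means[0],
        mean_p2=means[1],
        mean_p3=means[2],
        counts=tuple(counts),
        n_unassigned=int((~within).sum()),
    )


def summarize_samples(
    samples: pd.DataFrame,
    planes_by_model: dict,
    asr_by_model: dict,
    field_name: str | None = None,
) -> pd.DataFrame:
    """Collapse a long-format sample table into one summary row per model.

    ``samples`` must carry the columns ``model_id, x, y, z, value`` (and
    optionally ``field_name`` to filter on).
    """
    missing = [c for c in ("model_id", "x", "y", "z", "value") if c not in samples]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    if field_name is not None and "field_name" in samples:
        samples = samples[samples["field_name"] == field_name]
    rows = []
    for model_id, grp in samples.groupby("model_id"):
        if model_id not in planes_by_model:
            raise KeyError(f"no measurement planes for model {model_id!r}")
        avg = plane_average(
            grp[["x", "y", "z"]].to_numpy(),
            grp["value"].to_numpy(),
            planes_by_model[model_id],
        )
        rows.append(
            {
                "model_id": model_id,
                "ASR": asr_by_model[model_id],
                "mean_P1": avg.mean_p1,
                "mean_P2": avg.mean_p2,
                "mean_P3": avg.mean_p3,
                "grand_mean": avg.grand_mean,
            }
        )
    return pd.DataFrame(rows)


def correlate_table(table: pd.DataFrame, x_col: str = "ASR", y_col: str = "grand_mean"):
    """Pearson correlation between two columns of a summary table; returns
    ``(r, n)`` after dropping rows with missing values."""
    sub = table[[x_col, y_col]].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 complete rows for a correlation")
    return pearson_r(sub[x_col].to_numpy(), sub[y_col].to_numpy()), len(sub)
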