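"""Cartesian-domain fibrous-cap thickness quantification.

Cap thickness is measured in the Cartesian plane, not along A-lines: for
each point of the abluminal contour, a ray is cast from the centre of the
lumen through that point, and the thickness is the Euclidean distance
between the ray's intersections with the luminal and abluminal interfaces.
This makes the measure independent of an eccentric catheter position.  The
result is reported both as a per-A-line vector over the ROI and as the
frame minimum — the clinically decisive quantity (a minimum below the
conventional 65 um threshold flags a thin-cap fibroatheroma).

The "centre of the lumen" defaults to the area centroid of the closed
luminal polygon (a vertex-mean fallback handles degenerate,
self-intersecting polygons).  Contours are treated as linearly interpolated
polylines; when a ray crosses the luminal polyline more than once (possible
for non-star-shaped lumens), the intersection whose ray parameter is
nearest to the abluminal point is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from shapely.geometry import LineString, MultiPoint, Point, Polygon

from .errors import InputError
from .geometry import Contour, RoiArc

__all__ = [
    "ThicknessProfile",
    "TCFA_THRESHOLD_UM",
    "lumen_center",
    "thickness_profile",
]

#: Conventional minimal-cap-thickness threshold for thin-cap fibroatheroma.
TCFA_THRESHOLD_UM = 65.0


@dataclass
class ThicknessProfile:
    """Per-A-line cap thickness (um) over an ROI plus its minimum.

    ``per_aline_um`` holds NaN for columns whose measurement ray missed the
    luminal polyline (open-ROI edge effects); those are excluded from the
    minimum.  ``argmin_col`` is the frame theta index of the minimum.
    """

    per_aline_um: np.ndarray
    min_um: float
    argmin_col: int
    theta_start: int = 0

    @property
    def mean_um(self) -> float:
        return float(np.nanmean(self.per_aline_um))

    @property
    def is_tcfa(self) -> bool:
        return self.min_um < TCFA_THRESHOLD_UM


def _contour_xy_um(rows: np.ndarray, theta_cols: np.ndarray, n_theta: int,
                   pixel_um: float) -> np.ndarray:
    angles = 2.0 * np.pi * theta_cols / n_theta
    radii = rows * pixel_um
    return np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])


def lumen_center(
    lumen: Contour,
    pixel_um: float,
    method: Literal["centroid", "vertex-mean"] = "centroid",
) -> tuple[float, float]:
    """Centre of the lumen, in micrometres relative to the catheter.

    ``centroid`` (default) is the area centroid of the closed luminal
    polygon; ``vertex-mean`` is the plain mean of the contour vertices.  A
    self-intersecting polygon falls back to the vertex mean with a warning.
    """
    n = len(lumen)
    if n < 3:
        raise InputError("lumen centre needs at least 3 contour points")
    xy = _contour_xy_um(lumen.rows, np.arange(n, dtype=float), n, pixel_um)
    if method == "vertex-mean":
        return float(xy[:, 0].mean()), float(xy[:, 1].mean())
    if method != "centroid":
        raise InputError(f"unknown lumen centre method {method!r}")
    poly = Polygon(xy)
    if not poly.is_valid or poly.area <= 0:
        warnings.warn(
            "self-intersecting luminal polygon: falling back to vertex mean",
            stacklevel=2,
        )
        return float(xy[:, 0].mean()), float(xy[:, 1].mean())
    c = poly.centroid
    return float(c.x), float(c.y)


def _ray_intersection_t(
    ring: LineString,
    origin: np.ndarray,
    direction: np.ndarray,
    t_target: float,
) -> float | None:
    """Ray parameter of the luminal crossing nearest ``t_target`` (or None)."""
    seg = LineString(
        [tuple(origin), tuple(origin + direction * (2.0 * t_target + 1.0))]
    )
    hit = seg.intersection(ring)
    if hit.is_empty:
        return None
    if isinstance(hit, Point):
        pts = [hit]
    elif isinstance(hit, MultiPoint):
        pts = list(hit.geoms)
    else:  # collinear overlaps etc.: use every coordinate involved
        pts = [Point(c) for g in getattr(hit, "geoms", [hit])
               for c in g.coords]
    ts = [float(np.dot(np.asarray(p.coords[0]) - origin, direction))
          for p in pts]
    ts = [t for t in ts if t > 1e-9]
    if not ts:
        return None
    return min(ts, key=lambda t: abs(t - t_target))


def thickness_profile(
    lumen: Contour,
    abluminal: Contour,
    roi: RoiArc,
    pixel_um: float,
    center: tuple[float, float] | None = None,
    center_method: Literal["centroid", "vertex-mean"] = "centroid",
) -> ThicknessProfile:
    """Measure cap thickness along lumen-centre rays, one per ROI column.

    ``lumen`` must cover the full circumference; ``abluminal`` must cover
    the ROI.  All output lengths are in micrometres.
    """
    n_theta = len(lumen)
    if lumen.theta_start != 0:
        raise InputError("thickness needs a full-circumference lumen contour")
    cols = roi.columns(n_theta)
    if len(abluminal) != cols.size:
        raise InputError(
            f"abluminal contour length {len(abluminal)} does not match ROI "
            f"width {cols.size}"
        )
    if center is None:
        center = lumen_center(lumen, pixel_um, method=center_method)
    c = np.asarray(center, dtype=float)

    lumen_xy = _contour_xy_um(
        lumen.rows, np.arange(n_theta, dtype=float), n_theta, pixel_um
    )
    ring = LineString(np.vstack([lumen_xy, lumen_xy[:1]]))
    ablum_xy = _contour_xy_um(
        abluminal.rows, cols.astype(float), n_theta, pixel_um
    )

    values = np.full(cols.size, np.nan)
    for k in range(cols.size):
        p = ablum_xy[k]
        v = p - c
        t_p = float(np.linalg.norm(v))
        if t_p <= 1e-9:
            continue
        u = v / t_p
        t_l = _ray_intersection_t(ring, c, u, t_p)
        if t_l is None:
            continue
        values[k] = abs(t_p - t_l)

    if np.isnan(values).all():
        raise InputError("no measurement ray intersected the luminal contour")
    finite = np.nan_to_num(values, nan=np.inf)
    k_min = int(np.argmin(finite))
    return ThicknessProfile(
        per_aline_um=values,
        min_um=float(values[k_min]),
        argmin_col=int(cols[k_min]),
        theta_start=roi.theta_start,
    )
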