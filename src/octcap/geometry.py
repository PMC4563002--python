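"""Polar geometry: resampling, ROI arcs, guidewire masking, straightening.

Polar frames follow the native intravascular OCT acquisition geometry: row 0
is the catheter, rows run outward in depth (one sample every ``pixel_um``
micrometres) and columns are angular positions (A-lines), with column ``k``
of a full frame at angle ``2*pi*k/n_theta``.  The angle axis is periodic;
ROI arcs may cross the theta = 0 seam and are unwrapped contiguously.

The straightening transform ``T`` shifts each column up by the (rounded)
luminal contour row so that the lumen boundary becomes row 0; a diffuse
abluminal interface running roughly parallel to the lumen then appears as a
nearly horizontal structure, which is exactly the shape prior the
displacement-penalized path search encodes.  ``T`` is inverted exactly on
contours (integer shifts, no resampling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import InputError

__all__ = [
    "PolarImage",
    "RoiArc",
    "Contour",
    "StraightenTransform",
    "GuidewireMask",
    "cartesian_to_polar",
    "polar_to_cartesian",
    "extract_roi",
    "straighten",
    "unstraighten",
    "mask_guidewire",
    "interpolate_masked_columns",
]

DEFAULT_PIXEL_UM = 4.5


@dataclass
class PolarImage:
    """A polar-domain OCT frame with axial calibration.

    ``values[r, theta]``: row 0 at the catheter, depth increasing outward in
    steps of ``pixel_um``.  ``theta_offset`` records which column of the
    source frame column 0 corresponds to (nonzero for extracted ROIs).
    """

    values: np.ndarray
    pixel_um: float = DEFAULT_PIXEL_UM
    theta_offset: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InputError(f"polar image must be 2-D, got {self.values.shape}")
        if self.pixel_um <= 0:
            raise InputError(f"pixel_um must be > 0, got {self.pixel_um}")

    @property
    def n_r(self) -> int:
        return self.values.shape[0]

    @property
    def n_theta(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class RoiArc:
    """An angular arc (inclusive column bounds) on a given frame.

    ``theta_end < theta_start`` denotes an arc crossing the theta = 0 seam.
    """

    theta_start: int
    theta_end: int
    frame_id: int = 0

    def columns(self, n_theta: int) -> np.ndarray:
        """Contiguous, unwrapped source-column indices of the arc."""
        if not (0 <= self.theta_start < n_theta and 0 <= self.theta_end < n_theta):
            raise InputError(
                f"ROI arc [{self.theta_start}, {self.theta_end}] outside "
                f"0..{n_theta - 1}"
            )
        width = (self.theta_end - self.theta_start) % n_theta + 1
        return (self.theta_start + np.arange(width)) % n_theta

    def width(self, n_theta: int) -> int:
        return self.columns(n_theta).size


@dataclass
class Contour:
    """One real-valued radial coordinate (pixels) per angular column.

    ``theta_start`` is the source-frame column of entry 0; a
    full-circumference contour has ``theta_start = 0`` and one entry per
    A-line of the frame.
    """

    rows: np.ndarray
    theta_start: int = 0

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.ndim != 1 or self.rows.size == 0:
            raise InputError("contour rows must be a non-empty 1-D array")
        if not np.isfinite(self.rows).all():
            raise InputError("contour rows must be finite")

    def __len__(self) -> int:
        return self.rows.size

    def rows_um(self, pixel_um: float) -> np.ndarray:
        return self.rows * pixel_um


@dataclass
class StraightenTransform:
    """Per-column integer vertical shifts of the straightening transform T."""

    shifts: np.ndarray
    depth_out: int
    n_rows_source: int


@dataclass
class GuidewireMask:
    """Boolean flag per angular column; True where the guidewire shadows."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def masked_cols(self) -> np.ndarray:
        return np.nonzero(self.mask)[0]

    def any(self) -> bool:
        return bool(self.mask.any())


def cartesian_to_polar(
    values: np.ndarray,
    center: tuple[float, float],
    n_theta: int,
    n_r: int,
    pixel_um: float = DEFAULT_PIXEL_UM,
) -> PolarImage:
    """Resample a Cartesian frame onto rays from ``center``.

    Column ``k`` samples the ray at angle ``2*pi*k/n_theta``; row ``i``
    samples radius ``i`` pixels along it (isotropic pixels assumed, as in
    the acquisition geometry).  Bilinear interpolation; samples beyond the
    frame are 0.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise InputError("cartesian image must be 2-D")
    cx, cy = center
    h, w = values.shape
    if not (0 <= cx <= w - 1 and 0 <= cy <= h - 1):
        raise InputError(f"center {center} outside image {w}x{h}")
    angles = 2.0 * np.pi * np.arange(n_theta) / n_theta
    radii = np.arange(n_r, dtype=float)
    xs = cx + radii[:, None] * np.cos(angles)[None, :]
    ys = cy + radii[:, None] * np.sin(angles)[None, :]
    sampled = map_coordinates(
        values, [ys, xs], order=1, mode="constant", cval=0.0
    )
    return PolarImage(values=sampled, pixel_um=pixel_um)


def polar_to_cartesian(img: PolarImage, out_size: int) -> np.ndarray:
    """Inverse resampling of :func:`cartesian_to_polar` for display.

    The catheter maps to the centre of an ``out_size`` x ``out_size`` frame;
    the angle axis is treated periodically.
    """
    if out_size < 3:
        raise InputError("out_size must be >= 3")
    c = (out_size - 1) / 2.0
    ys, xs = np.mgrid[0:out_size, 0:out_size].astype(float)
    dx = xs - c
    dy = ys - c
    r = np.hypot(dx, dy)
    theta = np.mod(np.arctan2(dy, dx), 2.0 * np.pi) / (2.0 * np.pi) * img.n_theta
    # pad the seam so plain constant-mode interpolation is seam-continuous
    padded = np.concatenate([img.values, img.values[:, :1]], axis=1)
    out = map_coordinates(padded, [r, theta], order=1, mode="constant", cval=0.0)
    out[r > img.n_r - 1] = 0.0
    return out


def extract_roi(img: PolarImage, roi: RoiArc) -> PolarImage:
    """Cut the arc out of a frame, unwrapping across the seam if needed."""
    cols = roi.columns(img.n_theta)
    return PolarImage(
        values=img.values[:, cols],
        pixel_um=img.pixel_um,
        theta_offset=(img.theta_offset + roi.theta_start) % img.n_theta,
    )


def straighten(
    values: np.ndarray,
    lumen_rows: Sequence[float],
    depth_out: int,
    pad_value: float = 1.0,
) -> tuple[np.ndarray, StraightenTransform]:
    """Shift each column so the luminal interface lands on row 0.

    Shifts are the luminal rows rounded to the nearest integer (no
    resampling).  Rows shifted in from below the imaged depth are padded with
    ``pad_value`` — 1.0 for cost images, i.e. maximally unattractive, which
    forbids the path from leaving the imaged depth.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise InputError("image to straighten must be 2-D")
    n_r, n_c = values.shape
    lumen_rows = np.asarray(lumen_rows, dtype=float)
    if lumen_rows.size != n_c:
        raise InputError(
            f"lumen contour covers {lumen_rows.size} columns, image has {n_c}"
        )
    shifts = np.rint(lumen_rows).astype(int)
    if (shifts < 0).any() or (shifts > n_r - 1).any():
        raise InputError("lumen contour lies outside the imaged depth")
    if depth_out < 2:
        raise InputError("depth_out must be >= 2")
    out = np.full((depth_out, n_c), pad_value, dtype=float)
    for j in range(n_c):
        avail = min(depth_out, n_r - shifts[j])
        out[:avail, j] = values[shifts[j] : shifts[j] + avail, j]
    return out, StraightenTransform(
        shifts=shifts, depth_out=depth_out, n_rows_source=n_r
    )


def unstraighten(
    path_rows: Sequence[float], transform: StraightenTransform
) -> Contour:
    """Map a path in straightened coordinates back to frame coordinates."""
    path_rows = np.asarray(path_rows, dtype=float)
    if path_rows.size != transform.shifts.size:
        raise InputError("path length does not match the transform width")
    rows = path_rows + transform.shifts
    top = transform.n_rows_source - 1
    if (rows < 0).any() or (rows > top).any():
        warnings.warn(
            "unstraightened contour leaves the imaged depth; clipping",
            stacklevel=2,
        )
        rows = np.clip(rows, 0, top)
    return Contour(rows=rows)


def mask_guidewire(
    img: PolarImage,
    lumen_hint: Contour | None = None,
    depth_offset_px: int = 10,
    sum_fraction: float = 0.35,
    dilate_cols: int = 2,
) -> GuidewireMask:
    """Detect the angular sector shadowed by the guidewire.

    A column is flagged when its summed intensity beyond ``depth_offset_px``
    (or beyond the luminal interface when ``lumen_hint`` is given) falls
    below ``sum_fraction`` of the per-frame median column sum; the flags are
    then dilated circularly by ``dilate_cols`` columns.  Masks covering more
    than half the circumference trigger a warning (likely a calibration
    problem).
    """
    values = img.values
    n_r, n_c = values.shape
    if lumen_hint is not None and len(lumen_hint) == n_c:
        starts = np.clip(np.rint(lumen_hint.rows).astype(int), 0, n_r - 1)
        sums = np.array(
            [values[starts[j] :, j].sum() for j in range(n_c)], dtype=float
        )
    else:
        sums = values[min(depth_offset_px, n_r - 1) :, :].sum(axis=0)
    median = float(np.median(sums))
    if median <= 0.0:
        warnings.warn("all-dark frame: guidewire detection unreliable",
                      stacklevel=2)
        return GuidewireMask(mask=np.zeros(n_c, dtype=bool))
    mask = sums < sum_fraction * median
    if mask.any() and dilate_cols > 0:
        dilated = mask.copy()
        for k in range(1, dilate_cols + 1):
            dilated |= np.roll(mask, k) | np.roll(mask, -k)
        mask = dilated
    if mask.sum() > 0.5 * n_c:
        warnings.warn(
            f"guidewire mask covers {mask.sum()}/{n_c} columns (> 50% of the "
            "circumference): likely a calibration problem",
            stacklevel=2,
        )
    return GuidewireMask(mask=mask)


def interpolate_masked_columns(
    rows: np.ndarray, mask: np.ndarray, periodic: bool = True
) -> np.ndarray:
    """Bridge masked columns of a contour by linear interpolation in r.

    With ``periodic=True`` (full-circumference contours) interpolation wraps
    across the seam.  An all-masked input is returned unchanged.
    """
    rows = np.asarray(rows, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if rows.size != mask.size:
        raise InputError("contour and mask lengths differ")
    if not mask.any():
        return rows.copy()
    if mask.all():
        warnings.warn("all columns masked: contour left unchanged", stacklevel=2)
        return rows.copy()
    n = rows.size
    idx = np.arange(n)
    good = idx[~mask]
    if periodic:
        xp = np.concatenate([good - n, good, good + n])
        fp = np.tile(rows[good], 3)
    else:
        xp, fp = good, rows[good]
    out = rows.copy()
    out[mask] = np.interp(idx[mask], xp, fp)
    return out
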