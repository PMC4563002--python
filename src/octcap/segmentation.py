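"""OCT-specific segmentation pipelines: lumen, abluminal cap interface, sweep.

Two minimal-path extractions make up the framework:

* **Lumen** — the dark-to-bright luminal interface is well defined and is
  extracted over the full circumference directly in the polar frame, with
  parameters that weight the image data over the shape prior
  (alpha=0.1, beta=1, sigma=90 um, 2N+1=41 neighbors).
* **Abluminal** — the bright-to-dark boundary between the fibrous cap and the
  lipid pool is diffuse.  Inside the user ROI the cost image is first
  *straightened* (each column shifted so the lumen lands on row 0): because
  cap thickness varies slowly along the wall, the target interface becomes a
  nearly horizontal structure, and the displacement-penalized path search
  exploits exactly that prior (alpha=0.2, beta=1.8, sigma=45 um, 2N+1=41).
  The path found in the straightened domain is mapped back with the inverse
  shift.  Row 0 of the straightened search space is excluded, so the contour
  always stays strictly below the lumen (cap thickness >= 1 pixel).

User corrections arrive as control points in frame coordinates; they are
applied to the straightened cost image (anchor column zeroed elsewhere set
to infinity) so the corrected path passes through every point while the
search stays free elsewhere.

A training sweep evaluates the abluminal pipeline over a 10x10x10 grid of
{alpha, beta, sigma} (1000 parameter sets, N fixed at 20) against reference
contours, scoring each set by the per-frame mean absolute contour error in
micrometres averaged across frames; the ranked table is returned and the
choice among top-ranked sets is left to the user.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import dp
from .dp import ControlPoint, DPParams
from .errors import InfeasiblePathError, InputError
from .geometry import (
    Contour,
    GuidewireMask,
    PolarImage,
    RoiArc,
    extract_roi,
    interpolate_masked_columns,
    mask_guidewire,
    straighten,
    unstraighten,
)

__all__ = [
    "LUMEN_PARAMS",
    "ABLUMINAL_PARAMS",
    "SegmentationConfig",
    "SweepGrid",
    "segment_lumen",
    "segment_abluminal",
    "run_sweep",
]

#: Default luminal-interface parameters (heuristic set; positive transition).
LUMEN_PARAMS = DPParams(
    alpha=0.1, beta=1.0, sigma_um=90.0, half_neighbors=20, orientation="positive"
)

#: Default abluminal-interface parameters (training-selected set; negative
#: transition).
ABLUMINAL_PARAMS = DPParams(
    alpha=0.2, beta=1.8, sigma_um=45.0, half_neighbors=20, orientation="negative"
)


@dataclass
class SegmentationConfig:
    """Bundle of everything the two pipelines need.

    ``depth_out`` is the number of straightened rows searched below the
    lumen (default 200 rows = 900 um at 4.5 um/pixel, a generous upper bound
    on cap thickness).  ``guidewire`` selects shadow handling: automatic
    detection, a user-supplied mask, or off.
    """

    lumen_params: DPParams = LUMEN_PARAMS
    abluminal_params: DPParams = ABLUMINAL_PARAMS
    pixel_um: float = 4.5
    depth_out: int = 200
    guidewire: Literal["auto", "manual", "off"] = "auto"

    def __post_init__(self) -> None:
        if self.pixel_um <= 0:
            raise InputError("pixel_um must be > 0")
        if self.depth_out < 2:
            raise InputError("depth_out must be >= 2")
        if self.guidewire not in ("auto", "manual", "off"):
            raise InputError(f"unknown guidewire mode {self.guidewire!r}")


NEUTRAL_COST = 0.5


def segment_lumen(
    img: PolarImage,
    cfg: SegmentationConfig | None = None,
    guidewire_mask: GuidewireMask | None = None,
) -> Contour:
    """Extract the full-circumference luminal contour of one polar frame.

    Shadowed columns (detected or supplied, per ``cfg.guidewire``) receive a
    neutral cost so they do not attract or repel the path, and are bridged
    afterwards by periodic linear interpolation in r.
    """
    cfg = cfg or SegmentationConfig()
    if img.values.max() <= 0.0:
        raise InputError("all-dark frame: cannot segment the lumen")
    p = cfg.lumen_params
    grad = dp.gradient_image(img.values, p.sigma_um, img.pixel_um, p.orientation)
    cost = dp.build_cost(grad)
    if cfg.guidewire == "auto":
        guidewire_mask = mask_guidewire(img)
    elif cfg.guidewire == "off":
        guidewire_mask = None
    elif cfg.guidewire == "manual" and guidewire_mask is None:
        raise InputError("guidewire mode 'manual' requires a mask")
    if guidewire_mask is not None and guidewire_mask.any():
        cost = cost.copy()
        cost[:, guidewire_mask.mask] = NEUTRAL_COST
    prop = dp.propagate_front(cost, p.alpha, p.beta, p.half_neighbors)
    path = dp.backtrack(prop, cost)
    rows = path.rows.astype(float)
    if guidewire_mask is not None and guidewire_mask.any():
        rows = interpolate_masked_columns(rows, guidewire_mask.mask, periodic=True)
    return Contour(rows=rows, theta_start=img.theta_offset)


def _lumen_rows_for_roi(
    lumen: Contour, roi: RoiArc, n_theta: int
) -> np.ndarray:
    if len(lumen) != n_theta or lumen.theta_start != 0:
        raise InputError(
            "abluminal segmentation needs a full-circumference lumen contour"
        )
    return lumen.rows[roi.columns(n_theta)]


def segment_abluminal(
    img: PolarImage,
    lumen: Contour,
    roi: RoiArc,
    cfg: SegmentationConfig | None = None,
    control_points: Sequence[ControlPoint] | None = None,
) -> Contour:
    """Extract the abluminal cap interface within the ROI.

    Control points are expressed in original frame coordinates
    ``(theta column, r row)``; they are translated into the straightened ROI
    frame before constraining the cost.  The returned contour covers the ROI
    (``theta_start`` = the arc start) and lies strictly below the lumen.
    """
    cfg = cfg or SegmentationConfig()
    p = cfg.abluminal_params
    sub = extract_roi(img, roi)
    if sub.n_theta < 2:
        raise InputError("ROI must span at least 2 columns")
    lumen_roi = _lumen_rows_for_roi(lumen, roi, img.n_theta)

    grad = dp.gradient_image(sub.values, p.sigma_um, img.pixel_um, p.orientation)
    cost = dp.build_cost(grad)
    cost_T, transform = straighten(
        cost, lumen_roi, depth_out=cfg.depth_out, pad_value=1.0
    )
    # row 0 is the lumen itself; searching rows 1.. enforces a >= 1 px cap
    search = cost_T[1:, :]

    if control_points:
        translated = []
        cols = roi.columns(img.n_theta)
        col_of = {int(c): k for k, c in enumerate(cols)}
        for cp in control_points:
            if cp.col not in col_of:
                raise InputError(
                    f"control point column {cp.col} outside the ROI arc"
                )
            k = col_of[cp.col]
            local_row = int(cp.row) - int(transform.shifts[k]) - 1
            if not (0 <= local_row < search.shape[0]):
                raise InputError(
                    f"control point ({cp.col}, {cp.row}) maps to straightened "
                    f"row {local_row}, outside the search depth "
                    f"(0..{search.shape[0] - 1} below the lumen)"
                )
            translated.append(ControlPoint(col=k, row=local_row))
        search = dp.constrain_cost(search, translated, p.half_neighbors)

    prop = dp.propagate_front(search, p.alpha, p.beta, p.half_neighbors)
    path = dp.backtrack(prop, search)
    contour = unstraighten(path.rows + 1, transform)
    return Contour(rows=contour.rows, theta_start=roi.theta_start)


@dataclass(frozen=True)
class SweepGrid:
    """The 10x10x10 training grid over {alpha, beta, sigma}."""

    alpha_values: tuple[float, ...] = tuple(np.round(np.arange(1, 11) * 0.2, 10))
    beta_values: tuple[float, ...] = tuple(np.round(np.arange(1, 11) * 0.2, 10))
    sigma_values_um: tuple[float, ...] = tuple(float(9 * k) for k in range(1, 11))

    @property
    def n_sets(self) -> int:
        return (
            len(self.alpha_values)
            * len(self.beta_values)
            * len(self.sigma_values_um)
        )


def run_sweep(
    training_frames: Sequence[tuple[PolarImage, Contour, RoiArc, Contour]],
    grid: SweepGrid | None = None,
    cfg: SegmentationConfig | None = None,
) -> pd.DataFrame:
    """Score every parameter set of the grid against reference contours.

    Each training frame is a ``(image, lumen, roi, reference)`` tuple with
    the reference abluminal contour defined on the ROI.  For every
    {alpha, beta, sigma} set (N fixed by ``cfg.abluminal_params``) the
    abluminal pipeline runs on every frame; the per-frame score is the mean
    absolute radial error vs the reference in micrometres, and frames are
    averaged unweighted.  Returns a DataFrame sorted ascending by mean error
    with columns ``alpha, beta, sigma_um, mean_error_um, sd_error_um, rank``.
    """
    grid = grid or SweepGrid()
    cfg = cfg or SegmentationConfig()
    if len(training_frames) == 0:
        raise InputError("empty training set")
    for img, lumen, roi, ref in training_frames:
        if len(ref) != roi.width(img.n_theta):
            raise InputError(
                f"reference contour length {len(ref)} does not match ROI "
                f"width {roi.width(img.n_theta)} on frame {roi.frame_id}"
            )

    # the gradient/cost/straightening depend only on sigma: cache per frame
    prepared: dict[float, list] = {}
    for sigma in grid.sigma_values_um:
        per_frame = []
        for img, lumen, roi, ref in training_frames:
            sub = extract_roi(img, roi)
            lumen_roi = _lumen_rows_for_roi(lumen, roi, img.n_theta)
            grad = dp.gradient_image(
                sub.values, sigma, img.pixel_um,
                cfg.abluminal_params.orientation,
            )
            cost = dp.build_cost(grad)
            cost_T, transform = straighten(
                cost, lumen_roi, depth_out=cfg.depth_out, pad_value=1.0
            )
            per_frame.append((cost_T[1:, :], transform, ref, img.pixel_um))
        prepared[sigma] = per_frame

    N = cfg.abluminal_params.half_neighbors
    records = []
    for sigma in grid.sigma_values_um:
        per_frame = prepared[sigma]
        for alpha in grid.alpha_values:
            for beta in grid.beta_values:
                frame_errors = []
                for search, transform, ref, pixel_um in per_frame:
                    prop = dp.propagate_front(search, alpha, beta, N)
                    path = dp.backtrack(prop, search)
                    est = unstraighten(path.rows + 1, transform)
                    err = np.mean(np.abs(est.rows - ref.rows)) * pixel_um
                    frame_errors.append(err)
                records.append(
                    {
                        "alpha": alpha,
                        "beta": beta,
                        "sigma_um": sigma,
                        "mean_error_um": float(np.mean(frame_errors)),
                        "sd_error_um": float(np.std(frame_errors)),
                    }
                )
    table = pd.DataFrame.from_records(records)
    table = table.sort_values(
        ["mean_error_um", "alpha", "beta", "sigma_um"], kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table
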