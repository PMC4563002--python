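"""Synthetic polar OCT phantoms with known fibrous-cap geometry.

A phantom emulates the appearance of a lipid-rich plaque in a polar OCT
frame: a dark lumen, a bright fibrous band whose thickness profile is known
exactly, a signal-poor lipid pool reached through a diffuse (sigmoid)
abluminal transition, exponential depth attenuation of the signal beyond the
lumen, multiplicative Gamma speckle of unit mean, and an optional zeroed
guidewire-shadow sector.  The generator returns the exact ground-truth
luminal and abluminal contours alongside the image so every pipeline stage
can be scored without clinical data.

The speckle surrogate is multiplicative Gamma(k) noise with mean 1 — the
standard coherent-imaging stand-in; smaller shape k means heavier speckle
(k=4 by default).  The sigmoid transition is logistic with scale
``boundary_diffuseness_um``; its midpoint defines the true abluminal row.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import InputError
from .geometry import Contour, PolarImage, DEFAULT_PIXEL_UM

__all__ = [
    "PhantomSpec",
    "PhantomGroundTruth",
    "generate_phantom",
    "generate_pullback",
    "score_against_truth",
]

LumenProfile = Literal["constant", "sinusoidal", "offset-circle"]
CapProfile = Literal["constant", "sinusoidal"]


@dataclass(frozen=True)
class PhantomSpec:
    """Full parametric description of one phantom frame.

    Geometry (all lengths in micrometres):

    * lumen radius profile: constant ``lumen_radius_um``; sinusoidal adds
      ``lumen_amplitude_um * sin(lumen_cycles * angle + lumen_phase)``;
      offset-circle is a circle of that radius whose centre is displaced by
      ``lumen_amplitude_um`` along direction ``lumen_phase``.
    * cap thickness profile: constant at ``cap_min_um``; sinusoidal swings
      between ``cap_min_um`` and ``cap_max_um`` with ``cap_cycles`` periods
      around the circumference (the stated minimum is attained exactly).
    * the lipid pool occupies the angular sector ``pool_arc`` = (start
      column, width); real necrotic cores are sectors, not annuli (analyzed
      arcs average roughly a third of the circumference).  Outside the pool
      the wall is thick bright tissue with no abluminal interface.  The
      default sector is centred on the cap-thickness minimum at column 0;
      ``pool_arc=None`` puts the pool behind the whole circumference.

    Appearance: mean intensities of lumen/fibrous/lipid tissue (arbitrary
    units before attenuation), a sharp-ish luminal edge
    (``lumen_edge_um``), a diffuse abluminal sigmoid
    (``boundary_diffuseness_um``), exponential attenuation beyond the lumen
    (``attenuation_per_um``), Gamma speckle (``speckle_shape``; None
    disables it) and an optional zeroed shadow sector.
    """

    n_r: int = 304
    n_theta: int = 360
    pixel_um: float = DEFAULT_PIXEL_UM
    lumen_profile: LumenProfile = "sinusoidal"
    lumen_radius_um: float = 650.0
    lumen_amplitude_um: float = 45.0
    lumen_cycles: int = 3
    lumen_phase: float = 0.0
    cap_profile: CapProfile = "sinusoidal"
    cap_min_um: float = 100.0
    cap_max_um: float = 300.0
    cap_cycles: int = 2
    cap_phase: float = 0.0
    boundary_diffuseness_um: float = 30.0
    lumen_edge_um: float = 9.0
    intensity_lumen: float = 0.05
    intensity_fibrous: float = 0.8
    intensity_lipid: float = 0.15
    attenuation_per_um: float = 0.001
    speckle_shape: float | None = 4.0
    pool_arc: tuple[int, int] | None = (300, 120)
    shadow_arc: tuple[int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_r < 8 or self.n_theta < 8:
            raise InputError("phantom needs n_r >= 8 and n_theta >= 8")
        for name in ("pixel_um", "lumen_radius_um", "cap_min_um", "cap_max_um"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be > 0")
        if self.cap_max_um < self.cap_min_um:
            raise InputError("cap_max_um must be >= cap_min_um")
        if self.speckle_shape is not None and self.speckle_shape <= 0:
            raise InputError("speckle_shape must be > 0 or None")
        if self.boundary_diffuseness_um < 0 or self.lumen_edge_um < 0:
            raise InputError("diffuseness widths must be >= 0")


@dataclass
class PhantomGroundTruth:
    """Exact contours and minimal cap thickness used to build a phantom."""

    lumen: Contour
    abluminal: Contour
    min_thickness_um: float
    argmin_col: int


def _lumen_rows_px(spec: PhantomSpec) -> np.ndarray:
    theta = 2.0 * np.pi * np.arange(spec.n_theta) / spec.n_theta
    if spec.lumen_profile == "constant":
        r_um = np.full(spec.n_theta, spec.lumen_radius_um)
    elif spec.lumen_profile == "sinusoidal":
        r_um = spec.lumen_radius_um + spec.lumen_amplitude_um * np.sin(
            spec.lumen_cycles * theta + spec.lumen_phase
        )
    elif spec.lumen_profile == "offset-circle":
        d, R = spec.lumen_amplitude_um, spec.lumen_radius_um
        if d >= R:
            raise InputError("offset must be smaller than the circle radius")
        rel = theta - spec.lumen_phase
        r_um = d * np.cos(rel) + np.sqrt(R**2 - (d * np.sin(rel)) ** 2)
    else:
        raise InputError(f"unknown lumen profile {spec.lumen_profile!r}")
    return r_um / spec.pixel_um


def _cap_thickness_um(spec: PhantomSpec) -> np.ndarray:
    theta = 2.0 * np.pi * np.arange(spec.n_theta) / spec.n_theta
    if spec.cap_profile == "constant":
        return np.full(spec.n_theta, spec.cap_min_um)
    if spec.cap_profile == "sinusoidal":
        mid = 0.5 * (spec.cap_min_um + spec.cap_max_um)
        amp = 0.5 * (spec.cap_max_um - spec.cap_min_um)
        # minus-cosine so the stated minimum is attained exactly at phase 0
        return mid - amp * np.cos(spec.cap_cycles * theta + spec.cap_phase)
    raise InputError(f"unknown cap profile {spec.cap_profile!r}")


def _sigmoid(x: np.ndarray, scale_px: float) -> np.ndarray:
    if scale_px <= 0:
        return (x >= 0).astype(float)
    return 1.0 / (1.0 + np.exp(np.clip(-x / scale_px, -60, 60)))


def generate_phantom(spec: PhantomSpec) -> tuple[PolarImage, PhantomGroundTruth]:
    """Render one phantom frame and its exact ground truth.

    Deterministic for a fixed spec (the seed is part of the spec).  Rejects
    geometries where the cap is thinner than 2 pixels anywhere or the lipid
    pool would fall outside the imaged depth.
    """
    lumen_px = _lumen_rows_px(spec)
    cap_um = _cap_thickness_um(spec)
    cap_px = cap_um / spec.pixel_um
    if (cap_px < 2.0).any():
        raise InputError(
            f"cap thinner than 2 px (min {cap_um.min():.1f} um at "
            f"{spec.pixel_um} um/px)"
        )
    ablum_px = lumen_px + cap_px
    if (lumen_px < 1).any() or (ablum_px > spec.n_r - 2).any():
        raise InputError("phantom geometry outside the imaged depth")

    if spec.pool_arc is None:
        pool_cols = np.arange(spec.n_theta)
        pool_start = 0
    else:
        pool_start, pool_width = spec.pool_arc
        if not (0 < pool_width <= spec.n_theta):
            raise InputError("pool arc width must be in 1..n_theta")
        pool_cols = (pool_start + np.arange(pool_width)) % spec.n_theta
    in_pool = np.zeros(spec.n_theta, dtype=bool)
    in_pool[pool_cols] = True

    r = np.arange(spec.n_r, dtype=float)[:, None]
    w_lum = spec.lumen_edge_um / spec.pixel_um
    w_abl = spec.boundary_diffuseness_um / spec.pixel_um
    base = (
        spec.intensity_lumen
        + (spec.intensity_fibrous - spec.intensity_lumen)
        * _sigmoid(r - lumen_px[None, :], w_lum)
        + (spec.intensity_lipid - spec.intensity_fibrous)
        * _sigmoid(r - ablum_px[None, :], w_abl)
        * in_pool[None, :]
    )
    depth_um = np.maximum(0.0, r - lumen_px[None, :]) * spec.pixel_um
    image = base * np.exp(-spec.attenuation_per_um * depth_um)
    if spec.speckle_shape is not None:
        rng = np.random.default_rng(spec.seed)
        speckle = rng.gamma(
            spec.speckle_shape, 1.0 / spec.speckle_shape, size=image.shape
        )
        image = image * speckle
    if spec.shadow_arc is not None:
        start, width = spec.shadow_arc
        if not (0 < width <= spec.n_theta):
            raise InputError("shadow arc width must be in 1..n_theta")
        cols = (start + np.arange(width)) % spec.n_theta
        image[:, cols] = 0.0

    # the abluminal interface exists only where the pool does
    k_local = int(np.argmin(cap_um[pool_cols]))
    truth = PhantomGroundTruth(
        lumen=Contour(rows=lumen_px),
        abluminal=Contour(rows=ablum_px[pool_cols], theta_start=pool_start),
        min_thickness_um=float(cap_um[pool_cols][k_local]),
        argmin_col=int(pool_cols[k_local]),
    )
    return PolarImage(values=image, pixel_um=spec.pixel_um), truth


def generate_pullback(
    specs: Sequence[PhantomSpec],
) -> tuple[list[PolarImage], list[PhantomGroundTruth]]:
    """Render a stack of frames (one spec each, truths independent)."""
    if len(specs) == 0:
        raise InputError("empty spec list")
    frames, truths = [], []
    for spec in specs:
        img, truth = generate_phantom(spec)
        frames.append(img)
        truths.append(truth)
    return frames, truths


def score_against_truth(
    estimate,
    truth: PhantomGroundTruth,
    pixel_um: float,
    interface: Literal["abluminal", "lumen"] = "abluminal",
) -> dict[str, float]:
    """Error summary of an estimated contour or thickness profile vs truth.

    For a :class:`~octcap.geometry.Contour` (possibly covering only an ROI;
    columns are matched through ``theta_start`` with wrap-around) the summary
    holds mean absolute error, standard deviation of the signed error, bias
    and maximum absolute error, all in micrometres, against the chosen true
    interface.  For a thickness profile the signed minimal-thickness error is
    reported instead.
    """
    if isinstance(estimate, Contour):
        ref_contour = truth.abluminal if interface == "abluminal" else truth.lumen
        n = len(truth.lumen)  # lumen truth always covers the circumference
        offset = (estimate.theta_start - ref_contour.theta_start) % n
        if offset + len(estimate) > len(ref_contour):
            raise InputError(
                "estimate columns extend outside the ground-truth domain"
            )
        ref = ref_contour.rows[offset : offset + len(estimate)]
        err_um = (estimate.rows - ref) * pixel_um
        return {
            "mean_abs_um": float(np.mean(np.abs(err_um))),
            "sd_um": float(np.std(err_um)),
            "bias_um": float(np.mean(err_um)),
            "max_abs_um": float(np.max(np.abs(err_um))),
        }
    min_um = getattr(estimate, "min_um", None)
    if min_um is None:
        raise InputError(
            "estimate must be a Contour or a thickness profile with min_um"
        )
    return {
        "min_thickness_error_um": float(min_um - truth.min_thickness_um),
        "abs_min_thickness_error_um": float(
            abs(min_um - truth.min_thickness_um)
        ),
    }
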