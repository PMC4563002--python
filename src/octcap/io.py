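"""File formats, configuration and result reporting.

Conventions in every user-facing file:

* theta is a 0-based integer column index internally; ROI arcs and control
  points in CSV files give angles in **degrees** (converted to the nearest
  column), because that is how analysts think about arcs.
* r is stored both in pixels (``r_px``) and micrometres (``r_um``); row 0 is
  the catheter.
* Images are TIFF/PNG stacks or directories; 8-bit and 16-bit integer data
  are normalized to [0, 1] on reading.

``write_results`` emits a contour CSV, a thickness CSV + JSON summary, the
guidewire masks and a run manifest (full configuration, seed and library
versions) so that a run can be reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path as FsPath
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .dp import ControlPoint, DPParams
from .errors import InputError
from .geometry import Contour, GuidewireMask, PolarImage, RoiArc
from .segmentation import SegmentationConfig
from .thickness import ThicknessProfile

__all__ = [
    "read_frames",
    "write_frames",
    "read_rois",
    "read_control_points",
    "read_contours",
    "write_results",
    "load_config",
]

_IMAGE_SUFFIXES = {".tif", ".tiff", ".png"}


def _normalize(arr: np.ndarray) -> np.ndarray:
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / float(np.iinfo(arr.dtype).max)
    return arr.astype(float)


def read_frames(path: str | FsPath, pixel_um: float = 4.5) -> list[PolarImage]:
    """Read a TIFF/PNG stack or a directory of frames as polar images.

    Multi-page TIFFs become one frame per page.  All frames must share one
    shape.  Integer data are scaled by the dtype maximum to [0, 1].
    """
    path = FsPath(path)
    if not path.exists():
        raise InputError(f"no such input: {path}")
    arrays: list[np.ndarray] = []
    if path.is_dir():
        files = sorted(
            f for f in path.iterdir() if f.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not files:
            raise InputError(f"no TIFF/PNG frames in directory {path}")
        for f in files:
            arrays.extend(_read_one(f))
    else:
        arrays = _read_one(path)
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise InputError(f"mixed frame shapes in {path}: {sorted(shapes)}")
    return [PolarImage(values=_normalize(a), pixel_um=pixel_um) for a in arrays]


def _read_one(path: FsPath) -> list[np.ndarray]:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        data = tifffile.imread(path)
        if data.ndim == 2:
            return [data]
        if data.ndim == 3:
            return [data[i] for i in range(data.shape[0])]
        raise InputError(f"unsupported TIFF dimensionality {data.ndim} in {path}")
    if suffix == ".png":
        import imageio.v3 as iio

        data = iio.imread(path)
        if data.ndim == 3:  # collapse RGB(A) to gray
            data = data[..., :3].mean(axis=-1)
        return [data]
    raise InputError(f"unsupported image format {suffix!r}")


def write_frames(
    frames: Sequence[PolarImage], path: str | FsPath
) -> None:
    """Write frames as a 16-bit multi-page TIFF (values clipped to [0, ~2])."""
    path = FsPath(path)
    stack = np.stack([f.values for f in frames])
    peak = stack.max()
    scale = 65535.0 / peak if peak > 0 else 1.0
    tifffile.imwrite(path, np.clip(stack * scale, 0, 65535).astype(np.uint16))


def _deg_to_col(deg: float, n_theta: int) -> int:
    return int(np.rint(deg / 360.0 * n_theta)) % n_theta


def read_rois(path: str | FsPath, n_theta: int) -> dict[int, RoiArc]:
    """Read per-frame ROI arcs from CSV (frame_id, theta_start_deg, theta_end_deg)."""
    table = pd.read_csv(path)
    required = {"frame_id", "theta_start_deg", "theta_end_deg"}
    if not required.issubset(table.columns):
        raise InputError(f"ROI CSV needs columns {sorted(required)}")
    rois: dict[int, RoiArc] = {}
    for rec in table.itertuples(index=False):
        fid = int(rec.frame_id)
        if fid in rois:
            raise InputError(f"duplicate ROI for frame {fid}")
        rois[fid] = RoiArc(
            theta_start=_deg_to_col(float(rec.theta_start_deg), n_theta),
            theta_end=_deg_to_col(float(rec.theta_end_deg), n_theta),
            frame_id=fid,
        )
    return rois


def read_control_points(
    path: str | FsPath, n_theta: int
) -> dict[int, list[ControlPoint]]:
    """Read control points from CSV (frame_id, theta_deg, r_px)."""
    table = pd.read_csv(path)
    required = {"frame_id", "theta_deg", "r_px"}
    if not required.issubset(table.columns):
        raise InputError(f"control-point CSV needs columns {sorted(required)}")
    points: dict[int, list[ControlPoint]] = {}
    for rec in table.itertuples(index=False):
        points.setdefault(int(rec.frame_id), []).append(
            ControlPoint(
                col=_deg_to_col(float(rec.theta_deg), n_theta),
                row=int(np.rint(float(rec.r_px))),
            )
        )
    return points


def contours_to_table(
    contours: Mapping[int, Mapping[str, Contour]], pixel_um: float
) -> pd.DataFrame:
    records = []
    for frame_id in sorted(contours):
        for interface, contour in sorted(contours[frame_id].items()):
            for k, r in enumerate(contour.rows):
                records.append(
                    {
                        "frame": frame_id,
                        "theta_index": int(contour.theta_start + k),
                        "r_px": float(r),
                        "r_um": float(r * pixel_um),
                        "interface": interface,
                    }
                )
    return pd.DataFrame.from_records(
        records, columns=["frame", "theta_index", "r_px", "r_um", "interface"]
    )


def read_contours(path: str | FsPath) -> dict[int, dict[str, Contour]]:
    """Inverse of the contour CSV written by :func:`write_results`."""
    table = pd.read_csv(path)
    out: dict[int, dict[str, Contour]] = {}
    for (frame, interface), grp in table.groupby(["frame", "interface"]):
        grp = grp.sort_values("theta_index")
        start = int(grp["theta_index"].iloc[0])
        out.setdefault(int(frame), {})[str(interface)] = Contour(
            rows=grp["r_px"].to_numpy(), theta_start=start
        )
    return out


def _config_dict(cfg: SegmentationConfig) -> dict[str, Any]:
    d = dataclasses.asdict(cfg)
    return d


def write_results(
    outdir: str | FsPath,
    contours: Mapping[int, Mapping[str, Contour]],
    thickness: Mapping[int, ThicknessProfile] | None = None,
    masks: Mapping[int, GuidewireMask] | None = None,
    config: SegmentationConfig | None = None,
    seed: int | None = None,
) -> dict[str, FsPath]:
    """Write contours/thickness/masks plus a reproducibility manifest.

    Returns the paths written.  An empty thickness mapping (no ROIs
    analyzed) simply produces no thickness files.
    """
    outdir = FsPath(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config or SegmentationConfig()
    written: dict[str, FsPath] = {}

    contour_path = outdir / "contours.csv"
    contours_to_table(contours, cfg.pixel_um).to_csv(contour_path, index=False)
    written["contours"] = contour_path

    if thickness:
        rows = []
        summary = {}
        for frame_id in sorted(thickness):
            prof = thickness[frame_id]
            for k, t in enumerate(prof.per_aline_um):
                rows.append(
                    {
                        "frame": frame_id,
                        "theta_index": int(prof.theta_start + k),
                        "thickness_um": float(t),
                    }
                )
            summary[str(frame_id)] = {
                "min_um": prof.min_um,
                "argmin_col": prof.argmin_col,
                "mean_um": prof.mean_um,
                "is_tcfa": bool(prof.is_tcfa),
            }
        tpath = outdir / "thickness.csv"
        pd.DataFrame.from_records(rows).to_csv(tpath, index=False)
        written["thickness"] = tpath
        spath = outdir / "thickness_summary.json"
        spath.write_text(json.dumps(summary, indent=2, allow_nan=True))
        written["thickness_summary"] = spath

    if masks:
        mpath = outdir / "guidewire_masks.json"
        mpath.write_text(
            json.dumps(
                {
                    str(fid): mask.masked_cols.tolist()
                    for fid, mask in sorted(masks.items())
                },
                indent=2,
            )
        )
        written["masks"] = mpath

    manifest = {
        "config": _config_dict(cfg),
        "seed": seed,
        "versions": _library_versions(),
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    written["manifest"] = mpath
    return written


def _library_versions() -> dict[str, str]:
    import scipy
    import shapely

    from . import __version__

    return {
        "octcap": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "shapely": shapely.__version__,
        "tifffile": tifffile.__version__,
    }


def load_config(path: str | FsPath) -> SegmentationConfig:
    """Load a YAML segmentation config; missing keys keep their defaults."""
    raw = yaml.safe_load(FsPath(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise InputError(f"config {path} must be a YAML mapping")
    kwargs: dict[str, Any] = {}
    for key in ("lumen_params", "abluminal_params"):
        if key in raw:
            sub = raw.pop(key)
            if not isinstance(sub, dict):
                raise InputError(f"config key {key} must be a mapping")
            default = getattr(SegmentationConfig(), key)
            kwargs[key] = dataclasses.replace(default, **sub)
    known = {"pixel_um", "depth_out", "guidewire"}
    unknown = set(raw) - known
    if unknown:
        raise InputError(f"unknown config keys: {sorted(unknown)}")
    kwargs.update(raw)
    return SegmentationConfig(**kwargs)
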