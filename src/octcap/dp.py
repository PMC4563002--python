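"""Smoothness-penalized minimal-path extraction by dynamic programming.

This module is generic 2-D machinery, independent of OCT specifics: an
interface in a polar image is a curve with exactly one radial coordinate per
angular column.  Its location is found as the left-to-right path of minimal
cumulated cost through a gradient-derived cost image, where both high cost and
vertical displacement are penalized.

Conventions
-----------
Images are 2-D arrays indexed ``[r, theta]`` with ``r`` the row (depth) and
``theta`` the column (angle).  Indices are 0-based; the seed column of the
front propagation is column 0.  A path visits one row per column and may move
at most ``N`` rows between consecutive columns (``2N + 1`` reachable
neighbors).

The cumulated cost ``CC`` is built column by column (front propagation)::

    CC(r, t+1) = min_{d in [-N..N]} { CC(r+d, t)
                 + (C(r, t+1) + C(r+d, t)) * (1 + alpha * |d|**beta) }

with the left column seeded to zero so every left-border node is a potential
path start.  Because the data term is the cost of the *edge* (sum of both end
nodes) rather than of the current node alone, the minimal total cost is
independent of the propagation direction.  The displacement penalty uses
``|d|**beta`` so that fractional ``beta`` is well defined; it is a symmetric
displacement cost.

Out-of-range neighbor rows are clipped (excluded from the minimum), never
wrapped: the depth axis is not periodic.  Argmin ties are broken toward the
smallest ``|d|``, remaining ties toward negative ``d``; the path end on the
right border breaks ties toward the smallest row.  These tie-breaks make the
output fully deterministic and favor smooth paths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import InfeasiblePathError, InputError

__all__ = [
    "DPParams",
    "ControlPoint",
    "PropagationResult",
    "Path",
    "gradient_image",
    "build_cost",
    "propagate_front",
    "backtrack",
    "extract_min_path",
    "constrain_cost",
    "path_cost",
]

Orientation = Literal["positive", "negative"]


@dataclass(frozen=True)
class DPParams:
    """Parameter bundle governing cost construction and path smoothness.

    Attributes
    ----------
    alpha : float
        Flexibility weight (>= 0).  Small values allow vertical transitions;
        large values favor long horizontal plateaus.
    beta : float
        Roughness exponent (> 0).  Small values yield locally spiky contours;
        large values impose smooth ones.
    sigma_um : float
        Standard deviation of the Gaussian-derivative gradient kernel, in
        micrometres.
    half_neighbors : int
        ``N``; the number of reachable neighbors per column step is ``2N+1``.
    orientation : {"positive", "negative"}
        Sign of the intensity transition to enhance: positive for a dark-to-
        bright interface (lumen), negative for bright-to-dark (abluminal).
    """

    alpha: float
    beta: float
    sigma_um: float
    half_neighbors: int
    orientation: Orientation = "positive"

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise InputError(f"alpha must be >= 0, got {self.alpha}")
        if self.beta <= 0:
            raise InputError(f"beta must be > 0, got {self.beta}")
        if self.sigma_um <= 0:
            raise InputError(f"sigma_um must be > 0, got {self.sigma_um}")
        if self.half_neighbors < 1:
            raise InputError(
                f"half_neighbors must be >= 1, got {self.half_neighbors}"
            )
        if self.orientation not in ("positive", "negative"):
            raise InputError(f"unknown orientation {self.orientation!r}")


@dataclass(frozen=True)
class ControlPoint:
    """A user-placed anchor ``(col, row)`` the path must pass through."""

    col: int
    row: int


@dataclass
class PropagationResult:
    """Front-propagation state: cumulated cost and backpointers.

    ``cumulated[r, t]`` is the minimal cumulated cost of any path prefix
    ending at ``(r, t)``; column 0 is all zeros.  ``backpointers[r, t]`` is
    the row in column ``t-1`` the optimum came from (undefined for column 0).
    """

    cumulated: np.ndarray
    backpointers: np.ndarray


@dataclass
class Path:
    """A minimal path: one row index per column, plus its total cost."""

    rows: np.ndarray
    total_cost: float

    def __len__(self) -> int:
        return self.rows.size


def _validate_image(values: np.ndarray, name: str = "image") -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise InputError(f"{name} must be 2-D, got shape {values.shape}")
    if values.shape[1] < 2:
        raise InputError(f"{name} needs at least 2 columns")
    return values


def gradient_image(
    values: np.ndarray,
    sigma_um: float,
    pixel_um: float,
    orientation: Orientation = "positive",
) -> np.ndarray:
    """Column-wise Gaussian-derivative gradient along the depth axis.

    Each column is convolved with the first derivative of a Gaussian of
    standard deviation ``sigma_um`` (converted to pixels through
    ``pixel_um``), so the output is the vertical derivative of the smoothed
    image.  With ``orientation="positive"`` the result is large where
    intensity increases with depth; ``"negative"`` flips the sign so that
    bright-to-dark transitions are enhanced instead.

    The kernel is truncated at 4 sigma and columns are padded by reflection.
    """
    values = _validate_image(values)
    if not np.isfinite(values).all():
        raise InputError("image contains non-finite values")
    if pixel_um <= 0:
        raise InputError(f"pixel_um must be > 0, got {pixel_um}")
    sigma_px = sigma_um / pixel_um
    if sigma_px < 0.5:
        raise InputError(
            f"sigma of {sigma_um} um is {sigma_px:.3f} px at "
            f"{pixel_um} um/px; kernel not resolvable (needs >= 0.5 px)"
        )
    grad = gaussian_filter1d(
        values, sigma_px, axis=0, order=1, mode="reflect", truncate=4.0
    )
    if orientation == "negative":
        grad = -grad
    elif orientation != "positive":
        raise InputError(f"unknown orientation {orientation!r}")
    return grad


def build_cost(grad: np.ndarray) -> np.ndarray:
    """Normalize a gradient image into a cost image on [0, 1].

    The negated gradient is linearly rescaled so that its minimum is 0 and
    its maximum 1: the pixel with the strongest gradient in the chosen
    orientation gets cost 0.  A degenerate constant gradient yields an
    all-zero cost with a warning (blank columns then pass through freely).
    """
    grad = _validate_image(grad, "gradient image")
    if not np.isfinite(grad).all():
        raise InputError("gradient image contains non-finite values")
    cost = -grad
    cost = cost - cost.min()
    peak = cost.max()
    if peak <= 0.0:
        warnings.warn(
            "constant gradient image: cost defined as all zeros", stacklevel=2
        )
        return np.zeros_like(cost)
    return cost / peak


def _validate_cost(cost: np.ndarray) -> np.ndarray:
    cost = _validate_image(cost, "cost image")
    finite = np.isfinite(cost)
    if np.isnan(cost).any():
        raise InputError("cost image contains NaN")
    if (cost[finite] < -1e-12).any() or (cost[finite] > 1 + 1e-12).any():
        raise InputError("finite cost entries must lie in [0, 1]")
    blocked = ~finite.any(axis=0)
    if blocked.any():
        raise InfeasiblePathError(
            f"cost columns {np.nonzero(blocked)[0].tolist()} contain no "
            "finite entry: no feasible path"
        )
    return cost


def _displacement_order(half_neighbors: int) -> list[int]:
    # preference order for tie-breaking: 0, -1, +1, -2, +2, ...
    order = [0]
    for k in range(1, half_neighbors + 1):
        order.extend([-k, k])
    return order


def propagate_front(
    cost: np.ndarray, alpha: float, beta: float, half_neighbors: int
) -> PropagationResult:
    """Build the cumulated-cost matrix and backpointers column by column.

    The left column is seeded to zero.  Every node of column ``t+1`` takes
    the minimum over the ``2N+1`` reachable rows of column ``t`` (clipped at
    the image border) of the cumulated cost plus the displacement-penalized
    edge cost.  ``+inf`` cost entries (from control-point constraining)
    propagate naturally and exclude the node.
    """
    cost = _validate_cost(cost)
    if alpha < 0:
        raise InputError(f"alpha must be >= 0, got {alpha}")
    if beta <= 0:
        raise InputError(f"beta must be > 0, got {beta}")
    if half_neighbors < 1:
        raise InputError(f"half_neighbors must be >= 1, got {half_neighbors}")
    n_r, n_c = cost.shape
    N = half_neighbors
    cumulated = np.full((n_r, n_c), np.inf)
    cumulated[:, 0] = 0.0
    backpointers = np.zeros((n_r, n_c), dtype=np.intp)
    backpointers[:, 0] = np.arange(n_r)

    displacements = _displacement_order(N)
    penalties = [1.0 + alpha * abs(d) ** beta for d in displacements]
    rows = np.arange(n_r)

    for t in range(1, n_c):
        best = np.full(n_r, np.inf)
        best_src = np.arange(n_r, dtype=np.intp)
        col_now = cost[:, t]
        col_prev = cost[:, t - 1]
        cum_prev = cumulated[:, t - 1]
        for d, pen in zip(displacements, penalties):
            # source row s = r + d in the previous column
            if d >= 0:
                dst = slice(0, n_r - d)
                src = slice(d, n_r)
            else:
                dst = slice(-d, n_r)
                src = slice(0, n_r + d)
            cand = cum_prev[src] + (col_now[dst] + col_prev[src]) * pen
            sub = best[dst]
            update = cand < sub
            sub[update] = cand[update]
            best[dst] = sub
            srcrows = rows[dst] + d
            best_src[dst] = np.where(update, srcrows, best_src[dst])
        if not np.isfinite(best).any():
            raise InfeasiblePathError(
                f"front propagation blocked at column {t}: no finite "
                "cumulated cost (check control-point feasibility)"
            )
        cumulated[:, t] = best
        backpointers[:, t] = best_src
    return PropagationResult(cumulated=cumulated, backpointers=backpointers)


def backtrack(prop: PropagationResult, cost: np.ndarray) -> Path:
    """Extract the globally optimal path from the propagation state.

    The end point is the minimal cumulated cost on the right border
    (smallest row on ties); the path is then reconstructed right-to-left
    through the stored backpointers.
    """
    cost = np.asarray(cost, dtype=float)
    if prop.cumulated.shape != cost.shape:
        raise InputError(
            f"shape mismatch: cumulated {prop.cumulated.shape} vs "
            f"cost {cost.shape}"
        )
    n_r, n_c = cost.shape
    last = prop.cumulated[:, -1]
    if not np.isfinite(last).any():
        raise InfeasiblePathError("no finite cumulated cost on right border")
    end = int(np.argmin(last))  # np.argmin returns the smallest index on ties
    rows = np.empty(n_c, dtype=np.intp)
    rows[-1] = end
    for t in range(n_c - 1, 0, -1):
        rows[t - 1] = prop.backpointers[rows[t], t]
    return Path(rows=rows, total_cost=float(last[end]))


def path_cost(
    cost: np.ndarray, rows: Sequence[int], alpha: float, beta: float
) -> float:
    """Recompute the cumulated cost of an explicit path (for verification)."""
    rows = np.asarray(rows, dtype=np.intp)
    cost = np.asarray(cost, dtype=float)
    if rows.size != cost.shape[1]:
        raise InputError("path length must equal the number of columns")
    total = 0.0
    for t in range(1, rows.size):
        d = abs(int(rows[t]) - int(rows[t - 1]))
        total += (cost[rows[t], t] + cost[rows[t - 1], t - 1]) * (
            1.0 + alpha * d**beta
        )
    return total


def extract_min_path(
    values: np.ndarray,
    params: DPParams,
    pixel_um: float,
    control_points: Sequence[ControlPoint] = (),
) -> Path:
    """Gradient -> cost -> front propagation -> backtracking, composed.

    Optionally constrains the cost image with control points before the
    propagation.  The extracted path is invariant to any positive scaling of
    the input image because the cost normalization is affine-invariant.
    """
    grad = gradient_image(values, params.sigma_um, pixel_um, params.orientation)
    cost = build_cost(grad)
    if control_points:
        cost = constrain_cost(cost, control_points, params.half_neighbors)
    prop = propagate_front(cost, params.alpha, params.beta, params.half_neighbors)
    return backtrack(prop, cost)


def constrain_cost(
    cost: np.ndarray,
    points: Sequence[ControlPoint],
    half_neighbors: int | None = None,
) -> np.ndarray:
    """Force the path through control points by reshaping the cost image.

    For each point ``(col, row)`` the node cost is set to 0 and every other
    node of that column to ``+inf``; untouched columns keep their costs, so
    the search remains free away from the corrections.  At most one point per
    column is allowed.  When ``half_neighbors`` is given, pairwise
    reachability between constrained columns (``|dr| <= N * dcols``) is
    checked up front and violations rejected with a per-point diagnostic.
    """
    cost = np.asarray(cost, dtype=float)
    if len(points) == 0:
        return cost
    n_r, n_c = cost.shape
    seen: dict[int, ControlPoint] = {}
    for p in points:
        if not (0 <= p.col < n_c and 0 <= p.row < n_r):
            raise InputError(
                f"control point ({p.col}, {p.row}) outside image "
                f"{n_r}x{n_c}"
            )
        if p.col in seen:
            raise InputError(
                f"two control points in column {p.col}: "
                f"rows {seen[p.col].row} and {p.row}"
            )
        seen[p.col] = p
    if half_neighbors is not None:
        ordered = sorted(points, key=lambda p: p.col)
        for a, b in zip(ordered, ordered[1:]):
            max_step = half_neighbors * (b.col - a.col)
            if abs(b.row - a.row) > max_step:
                raise InputError(
                    f"control point ({b.col}, {b.row}) unreachable from "
                    f"({a.col}, {a.row}) with N={half_neighbors}: "
                    f"|dr|={abs(b.row - a.row)} > {max_step}"
                )
    out = cost.copy()
    for p in points:
        out[:, p.col] = np.inf
        out[p.row, p.col] = 0.0
    return out
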