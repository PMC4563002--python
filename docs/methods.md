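# Methods

## Model and assumptions

An interface in a polar OCT frame is modelled as a function `r(θ)` — one
radial coordinate per A-line — located where the depth-wise intensity
transition is strongest, and smooth because arterial wall structures vary
slowly along the circumference.  Both properties enter a single dynamic
program: the data term is the normalized negated Gaussian-derivative
gradient (cost 0 at the strongest transition in the chosen orientation),
and the shape prior is the multiplicative displacement penalty
`1 + α·|d_r|^β` on each step of the path.  The recursion

```
ℂ(r, θ+1) = min_{d ∈ [-N..N]} { ℂ(r+d, θ) + (C(r, θ+1) + C(r+d, θ)) · (1 + α·|d|^β) }
```

uses the cost of the *edge* (both end nodes), which makes the minimal
total cost independent of the propagation direction; the left column is
seeded to zero so every left-border node is a candidate start, and the
path ends at the minimal right-border node.

The penalty is written with `|d_r|` because a signed displacement raised
to a fractional exponent (β = 1.8 is a default) is undefined over the
reals; the penalty is a symmetric displacement cost.  Neighbor rows
outside the image are excluded from the minimum (the depth axis is not
periodic).  Argmin ties prefer the smallest `|d|`, then negative `d`;
right-border ties prefer the smallest row.  Ties are broken this way
purely for determinism and smoothness — nothing in the underlying model
distinguishes them.  Cumulated costs are double precision; path-cost
comparisons in tests use 1e-9 tolerances.

The abluminal interface of a fibrous cap is diffuse, so its pipeline adds
a geometric prior: after extracting the user's ROI arc, the cost image is
straightened column-by-column so the luminal contour lands on row 0.
Because cap thickness varies slowly, the abluminal interface becomes a
nearly horizontal structure in this domain — exactly what the
displacement penalty favors.  Straightening shifts by the *rounded*
luminal rows (no resampling, hence exactly invertible on contours); rows
shifted in from below the imaged depth are padded with cost 1.0 so the
path cannot leave it, and row 0 itself is excluded from the search so the
cap is at least one pixel thick.  The gradient and cost are computed in
the ROI *before* shifting, so no filtering happens across the shift
discontinuity.

## Parameters

| parameter | lumen | abluminal | meaning |
|---|---|---|---|
| α | 0.1 | 0.2 | path flexibility (larger → flatter) |
| β | 1.0 | 1.8 | roughness exponent (larger → smoother) |
| σ | 90 µm | 45 µm | Gaussian-derivative scale (20 / 10 px at 4.5 µm) |
| 2N+1 | 41 | 41 | reachable neighbors per column step |
| orientation | positive | negative | dark→bright vs bright→dark |

Axial calibration defaults to 4.5 µm/pixel (isotropic).  `depth_out`,
the straightened search depth below the lumen, defaults to 200 rows
(900 µm) — a generous upper bound on cap thickness.  The guidewire
shadow is detected as columns whose summed intensity beyond a shallow
offset falls below 0.35 of the median column sum, dilated by 2 columns;
these values are pragmatic defaults, a user-supplied mask overrides
them.  Masked columns get neutral cost (0.5) so they neither attract nor
repel the path and are bridged by periodic linear interpolation in r.

The training sweep evaluates the abluminal pipeline on the full
10×10×10 grid (α, β ∈ 0.2…2.0 step 0.2; σ ∈ 9…90 µm step 9; N fixed),
scoring each set by the per-frame mean absolute contour error in µm
against reference contours, averaged unweighted across frames (per-frame
ROI widths are not used as weights; nothing in the scoring model favors
wide arcs).  The ranked table is returned; selecting among top-ranked
sets is deliberately left to the user, defaulting to rank 1.

Cap thickness is measured in the Cartesian domain: for each abluminal
point, along the ray from the lumen centre through it, as the distance to
the luminal polyline.  The "lumen centre" is the area centroid of the
closed luminal polygon (a vertex-mean option and fallback exists for
degenerate polygons).  When a ray crosses the luminal polyline several
times — possible for non-star-shaped lumens — the crossing whose ray
parameter is nearest the abluminal point is used; rays that miss the
polyline (open-ROI edge effects) yield a flagged absent column excluded
from the minimum.

## Synthetic phantoms

`PhantomSpec` renders a polar frame as dark lumen / bright fibrous band /
signal-poor lipid pool, with a parametric lumen radius profile (constant,
sinusoidal, offset-circle), a parametric cap-thickness profile whose
stated minimum is attained exactly, a logistic abluminal transition
(scale = `boundary_diffuseness_um`, the midpoint defines the true
interface), exponential depth attenuation beyond the lumen, multiplicative
Gamma speckle of unit mean (shape k = 4 by default; smaller k = heavier
speckle — the standard coherent-imaging surrogate), and an optional zeroed
guidewire-shadow sector.  Intensity means are 0.05 / 0.8 / 0.15 (lumen /
fibrous / lipid, arbitrary units before attenuation), qualitatively
matching clinical appearance.  Attenuation defaults to 0.001 µm⁻¹
(1 mm⁻¹): displayed OCT frames are dynamic-range-compressed, so the
*apparent* decay across a few hundred µm of cap is mild, and 1 mm⁻¹
reproduces that look; raw-signal attenuation coefficients in plaque are
several times larger.  The lipid pool occupies an angular *sector*
(default 120 columns centred on the cap-thickness minimum), as real
necrotic cores do — analyzed arcs span roughly a third of the
circumference on average; outside the sector the wall is thick bright
tissue.

What the phantoms do **not** emulate: physically accurate light
transport, spatially correlated speckle grains, log compression,
catheter sheath reflections, side lobes, or motion between frames.
Passing phantom tests therefore demonstrates the geometric and numerical
correctness of the pipeline under controlled contrast and noise, not
clinical-grade accuracy on patient images.

## Known systematic biases (measured on phantoms)

Two physical effects displace a derivative-of-Gaussian peak away from a
true interface on linearly attenuated images, and both are visible in the
package's own measurements:

* **Attenuation bias.**  For an edge multiplied by `exp(−µ·depth)`, the
  smoothed gradient peak sits approximately `µ·σ²` *shallow* of the edge.
  At 1 mm⁻¹ this is ≈1.8 px (8 µm) for the σ = 90 µm luminal kernel and
  ≈0.7–1.5 px for the σ = 45 µm abluminal kernel.
* **Interface interference.**  A second edge within the kernel support
  pulls the peak: behind a thin cap (≈100 µm = 22 px) the dark pool pulls
  the luminal peak ≈ `(a₂/a₁)·w·exp(−w²/2σ²)` ≈ 8 px shallow, and the
  sharp luminal edge pushes the abluminal peak ≈3 px deep.

Both inflate the measured cap thickness, most strongly at thin caps over
dark pools — the fully automatic pipeline overestimates the minimal cap
thickness of such phantoms by a few tens of µm (reported as
`end_to_end_min_thickness_bias_um` by `scripts/acceptance.py`), while
feeding the exact luminal contour isolates the abluminal stage, which
stays within roughly one pixel except at the thinnest caps.  The
acceptance suite asserts the one-pixel (9 µm) recovery band on randomized
phantoms; the minimal-thickness clause does not fully hold under the
default attenuation for the reasons above, and the corresponding test
documents the measured shortfall rather than relaxing the band.

## Design choices where the design was open

* **Indexing** is 0-based everywhere internally; the seed column of the
  propagation is column 0.  User-facing files give angles in degrees and
  radii in both px and µm; row 0 is the catheter.
* **θ seam:** the lumen is segmented on the unwrapped full-circumference
  array without periodic stitching; ROI arcs may cross the seam and are
  unwrapped contiguously.
* **Degenerate cost:** a constant gradient image normalizes to an all-zero
  cost with a warning instead of failing, so blank phantom columns pass
  through.
* **Lumen input to the abluminal stage:** the lumen is always segmented on
  the full frame (even when only an arc is analyzed) so straightening and
  thickness have a complete luminal reference.
* **Sweep scoring:** "mean error" is the mean absolute radial error per
  A-line converted to µm.
* **Control points** live in original frame coordinates and are translated
  into the straightened ROI before constraining; pairwise reachability
  (`|Δr| ≤ N·Δθ`) is validated up front with per-point diagnostics.

## Problem sizes in tests

Oracle-equivalence tests enumerate every monotone path on images up to
5×6 with N ≤ 2 (≈15 k paths); phantom studies use 304×360 frames with
100-column ROIs, 20 phantoms for recovery studies and 10 seeds × 3 noise
levels for the difficulty-monotonicity property; the sweep
self-consistency check runs the full 1000-set grid on one reduced
(256×180) frame.  These sizes keep the whole suite around twenty
seconds while still exercising every stage at realistic aspect ratios.

## Limitations

Single-frame (2-D) segmentation only; no sub-pixel contour refinement; no
DICOM/vendor formats; guidewire detection is a simple intensity heuristic;
clinical validation against expert tracings is outside the package's
scope — the phantom ground truth is exact but synthetic.
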