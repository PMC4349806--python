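# Methods

## Scope and conventions

The package computes two per-tumor descriptors from co-registered CT
volumes and binary masks, plus the statistics used to evaluate them. All
volumes are indexed `(slice, row, col)`, 0-based; features are computed
per axial slice in native pixel units (no resampling — heterogeneous
acquisitions are analyzed on their own grids, and any spacing dependence
is treated as part of the feature). Masks are strict `{0, 1}` arrays on
the CT grid; geometry mismatches raise rather than resample. Segmentation
itself is out of scope: masks are inputs.

## Convexity

Per slice, `C = N_mask / N_hull` where `N_hull` counts pixels whose
center lies inside or on the convex hull polygon of the foreground pixel
centers. Choices that pin the value down exactly:

* Hull vertices come from Qhull (QuickHull family) on pixel centers;
  rasterization is an exact integer half-plane test, so there is no
  floating-point boundary ambiguity and a pixel center exactly on a hull
  edge counts as inside. Consequence: any convex pixel set — including
  digital disks and rectangles — scores exactly 1, and `0 < C ≤ 1`
  always. Degenerate (single-pixel or collinear) masks rasterize to the
  segment through the points and score 1.
* Multiple connected components in one slice are hulled as a single point
  set, matching the single-ROI framing of a tumor segmentation.
* An alternative `hull_area="polygon"` mode divides by the continuous
  shoelace area of the hull instead of its pixel count, as a sensitivity
  variant. By Pick's theorem the raster count equals shoelace area +
  boundary/2 + 1, so the continuous mode scores slightly above 1 on
  convex shapes; the raster rule is the default precisely because convex
  inputs should score 1.
* Slices with tiny cross-sections (1–2 px) are kept; they score 1 by the
  degenerate-hull rule.

**Pleural exclusion.** A slice is dropped from the tumor-level mean when
strictly more than half of its tumor-perimeter pixels (4-connectivity to
background, image border counts as background) coincide with lung-field
perimeter pixels. Exactly half is retained. Overlap is exact pixel
equality by default; a `tolerance_px` ring is available for clinical
masks that are co-registered but not pixel-aligned. A tumor slice with no
lung mask (or an empty lung slice) gets overlap 0 with a logged warning.
If every slice is excluded the mean is NaN and downstream tables carry an
empty cell.

## Entropy ratio

Per tumor-bearing slice: dilate the mask with an exact Euclidean lattice
disk of radius 3; erode the *dilated* mask with a radius-5 disk → core;
boundary = dilated − core. On a radius-R disk this leaves a core of
radius ≈ R−2 and a ring ≈ 5 px wide straddling the original border
(3 px outside, 2 px inside). Tumors thinner than the erosion have an
empty core; such slices contribute boundary pixels only, and the ratio is
defined as long as at least one slice retains a core.

Intensities are min–max binned into 256 integer levels over the dilated
ROI of that slice (bin edges round down; out-of-ROI values clip into
range; a constant ROI maps to bin 0, giving zero entropy everywhere).
ROI-scoped normalization is the default because the descriptor targets
*intratumor* contrast; `slice` and `volume` scopes exist for sensitivity
analysis. A consequence worth noting: adding a constant HU offset to the
volume changes nothing, so the feature is invariant to calibration shifts.

Local entropy at a pixel is `−Σ pᵢ log₂ pᵢ` (bits, `0·log 0 = 0`) over
the histogram of **all** pixels in its 7×7 window — tumor membership does
not restrict the window, mirroring a plain entropy filter pass — with the
window clipped at the image border (border histograms are smaller). The
implementation vectorizes per-pixel histograms and is tested to 1e-12
bits against a naive loop. Values are bounded by
`log₂(min(256, 49)) ≈ 5.61` bits.

Pooling is ensemble-style: core entropies of all slices form one pool,
boundary entropies another; the feature is the ratio of pool means. A
per-slice-ratio-then-mean variant would weight slices equally rather than
pixels; the pooled form is the default because small end slices should
not dominate.

## Test–retest statistics

* **CCC** — `2·cov(x,y) / (var x + var y + (Δmean)²)` with population
  (1/n) moments per Lin's original estimator; a 1/(n−1) variant is
  exposed since either convention appears in practice. Undefined (NaN)
  when both vectors are constant.
* **Dynamic range** — `1 − mean|xᵢ−yᵢ| / (max(x∪y) − min(x∪y))`:
  identical repeats give 1, and the statistic degrades as repeat error
  grows relative to the biological (inter-subject) spread. The raw ratio
  is also emitted for transparency. NaN when the pooled range is zero.
* **Bland–Altman** — bias `mean(x−y)`, limits `bias ± 1.96·sd(x−y)`
  (sample sd).
* **Absolute percent difference** — `|x−y| / mean(x,y) · 100` per
  subject; zero-mean pairs are dropped with a warning.

## Survival evaluation

Feature scores are dichotomized at the in-sample median (ties go to the
low group — the convention is configurable since either side is
defensible) or at an externally supplied threshold, e.g. a
training-cohort median applied to a validation cohort. Kaplan–Meier
curves and the two-group log-rank test are delegated to `lifelines` and
cross-checked in the tests against hand product-limit computations, an
explicit hypergeometric observed-minus-expected sum, and a
label-permutation reference. Cox regression is deliberately not wrapped:
the emitted feature table is ready for any standard survival package.

## Phantom generator

The generator emulates the pipeline's inputs with constructed ground
truth:

* **Shape**: per-slice foreground `r(θ) ≤ R₀·s(z)·(1 + a·cos kθ)` with
  amplitude `a ∈ [0, 0.6]`, lobe count `k`, and a constant or elliptic
  slice profile. `a = 0` gives digital disks (convexity exactly 1); the
  convexity ordering across an `a`-sweep is known by construction.
  Defaults `R₀ = 20 px` on a 96-px grid put the phantom in the size range
  of a 2–3 cm nodule at typical in-plane spacings.
* **Texture**: core and boundary painted with HU levels drawn uniformly
  from `bins_used` evenly spaced levels over a 200-HU span (discrete
  levels keep expected window histograms analytically tractable, unlike
  Gaussian fields). The boundary texture extends a 3-px apron beyond the
  dilated mask so ring pixels' 7×7 windows sample ring texture rather
  than the flat −800 HU background; without the apron even a symmetric
  construction reads a downward-biased boundary entropy.
* **Pleural contact**: the lung is a large ellipse whose right wall is a
  flat chord cut into the tumor; the cut depth is searched on the widest
  slice to approximate the requested perimeter-overlap fraction, and the
  *realized* per-slice fractions are measured and reported as ground
  truth (the function returns lung, clipped tumor and fractions
  together). Geometry caps what a straight wall can achieve: for a thick
  tumor the flat facet approaches but rarely exceeds half the digital
  perimeter, so overlap fractions well above 0.5 occur only for thin
  residual slivers — requests beyond the achievable maximum fall back to
  it with a warning.
* **Test–retest pairs**: one shared integer-rounded translation of image
  and masks, independent Gaussian HU noise, and per-round random
  perimeter flips (drop/add with probability 0.3) for mask-boundary
  jitter. Defaults (±0.5 px translation, 1 px jitter, 5 HU noise) emulate
  same-day repeat imaging with independent segmentations.

What the phantoms do **not** emulate: lung anatomy, partial-volume and
reconstruction-kernel effects, contrast enhancement, or realistic tumor
texture correlation structure. Passing tests therefore demonstrate that
the descriptors recover constructed shape and texture contrasts and obey
their exact-geometry contracts — not that they are prognostic in real
cohorts, which requires clinical data outside this package's scope.

## Problem sizes and numerics

Tests and the acceptance script use single- to three-slice phantoms on
96-px grids, 30-subject test–retest batches, 2 000–10 000-mask hull-oracle
sweeps, and 1000-replicate null simulations for log-rank calibration —
sizes chosen so the whole suite completes in a couple of minutes while
keeping Monte-Carlo error comfortably inside the asserted bounds (e.g.
type-I error 0.05 ± 0.02 at 1000 replicates). All stochastic tests are
seeded; identical specs and seeds reproduce phantom volumes bit-for-bit.
Known numerical edge cases: entropy of a constant region is exactly 0
(ratio NaN, flagged); CCC/DR are NaN for degenerate inputs rather than
clamped; convexity of an empty slice raises.
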