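# Methods

## Coordinate frame and the polar sweep

All computations are anchored at the nucleus center. In the original
workflow this center is placed by hand; `cellpolar` defaults to the
intensity-unweighted centroid of the nucleus mask so that batches run
unattended, with a manual override (`--center ROW,COL`) for non-convex
nuclei, where the centroid may fall outside the mask and an error asks for
the override rather than silently proceeding.

The sweep takes a line profile along a ray from the center at every angle,
default 0.1° steps (3600 rays), sampled every 0.5 px out to 2 px beyond
the furthest cell-mask pixel. Two choices resolve the mismatch between
square pixels and polar sampling:

* profiles are read by **bilinear subpixel interpolation**
  (`scipy.ndimage.map_coordinates`, order 1), and
* each sample carries a **Jacobian area weight** w = r·Δθ·Δr, so that
  Σ w·F over the polar map estimates the Cartesian integral of intensity.

This conservation property is the internal consistency check of the whole
transform: Cartesian total, polar-map weighted total and normalized-map
weighted total agree within a fraction of a percent on smooth images
(tested at 2%).

Angle convention: θ = 0 along the +column axis, θ increasing with
`atan2(Δrow, Δcol)`; pixel coordinates are 0-based, pixel-center.

## Boundary radii and the normalized radial axis

Per angle, both masks are sampled bilinearly along the ray and the
boundary radius is the **last 0.5-crossing** (sub-sample refined by linear
interpolation). Taking the last crossing makes the estimate robust to
holes inside a mask, and presumes the masks are star-convex about the
center — a ray that never meets a mask raises an error naming the angle.
An optional circular moving-average smoothing of the radius profiles
(window in degrees, default off) is available for ragged hand-drawn masks.

The radial axis is then rescaled per angle:

    u = 100 · (r − r_ne) / (r_edge − r_ne)    for r ≥ r_ne
    u =  25 · (r / r_ne − 1)                  for r < r_ne

so the cytoplasm spans 0–100% and the nucleoplasm −25–0. The nucleoplasm
mapping is linear in r — the minimal assumption for a band that serves as
a control; note that in a 2D projection this band also contains cytoplasm
and nuclear envelope lying above and below the nucleus, and no correction
is applied for that. Samples beyond the cell edge are dropped.

Resampling onto the fixed u grid (step 0.5%) is **conservative**: each
polar sample's mass (w·F) and area weight are split linearly between the
two adjacent u nodes (cloud-in-cell deposition), so the weighted total
inside the cell edge is preserved exactly. Each u bin also carries the
mass-weighted mean raw radius of its samples, so raw-scale statistics use
true distances rather than the inverse of the (mask-estimated) u mapping;
where a bin receives no mass, the geometric inverse is the fallback.

## The spatial PMF and the two statistics

The PMF is p(θᵢ, uₖ) = w·G / Σ w·G over the chosen domain — default
**full** (−25..100, nucleoplasm control band included, since nothing in
the measurement design excludes it), with `cytoplasm_only` as a config
switch. Cells with zero signal on the domain raise an explicit
empty-signal error; metrics are never NaN.

* **MDR** = Σ p·ρ with ρ = u (normalized, percent) or the raw radius in
  μm. Both scales are always computed; group comparisons default to the
  normalized scale, which is the evident purpose of the normalization
  (cells of different sizes become commensurable).
* **Asymmetry** is the first circular moment (mean resultant length) of
  the fluorescence-weighted angular marginal: q(θ) = Σₖ p, asymmetry =
  |Σ q·e^{iθ}|. It is the canonical normalized measure of an angular
  distribution concentrating to one side: bounded in [0, 1], invariant to
  rotation of the frame, 0 for angular uniformity, 1 for a single-angle
  point mass; the argument of the same sum is the reported mean angle.

Scale invariance (any c > 0 on intensities changes nothing), rotation
behavior and grid-refinement stability (halving all steps moves MDR by
< 0.5%) are enforced by tests.

## Synthetic phantoms and the ground-truth oracle

The generator emulates the analyzed objects, not their texture: a
star-convex cell outline r_cell(θ) = R₀(1 + Σ aₖcos(kθ+φₖ)) with
Σ|aₖ| < 0.5 (so every ray crosses the boundary exactly once — the sweep's
assumption), an elliptical nucleus, optional neighbor blobs at the image
border, and an organelle density **specified directly in (u, θ)**:

    f(u, θ) = f_rad(u) · vonMises(θ; μ, κ)

with f_rad a mixture of a perinuclear truncated Gaussian (center u₀,
width σ_u), a peripheral truncated Gaussian (u₁, σ_u1) and a uniform
component on [0, 100]. Because the density lives in u, the normalized MDR
(∫u·f_rad du) and the asymmetry (the von Mises mean resultant length
I₁(κ)/I₀(κ)) are geometry-independent; the raw MDR is derived per cell
from its boundary radii. Rendering converts mass per du·dθ to intensity
per pixel area through the Jacobian (du/dr)/r and normalizes the
noise-free image to the photon budget; noise is Poisson on the expected
signal plus Gaussian read noise, each independently switchable, and a
uniform background per pixel inside the cell mask.

The **oracle** integrates the continuous density on a tensor-product
trapezoid grid (3600 angular × 2001 radial nodes by default), exploiting
the separability of the density — the raw-radius integral factorizes
exactly because r(u, θ) is linear in u at fixed θ — and verifies
convergence by grid doubling (relative change < 1e-4, else an error). It
never touches the image-space code path, so pipeline-vs-oracle agreement
(tested at 5% on 20 random phantoms, typically < 0.5%) is a genuine
cross-validation.

### Phenotype presets

Presets reproduce the *direction* of the biological phenotypes, not any
particular measured magnitude (no public per-condition values exist to
calibrate against):

| preset | radial mixture (perinuc/periph/unif) | κ | emulates |
|---|---|---|---|
| wildtype  | 0.65 / 0.05 / 0.30 | U(0, 0.2) | perinuclear-dense, symmetric |
| dispersed | 0.20 / 0.40 / 0.40 | U(0, 0.2) | peripheral spread, higher MDR |
| clustered | 0.70 / 0.00 / 0.30 | U(2, 3)   | one-sided collapse, higher asymmetry |

Each cell draws jittered geometry (cell radius 70–88 px, nucleus semiaxes
13–23 px, low-order shape harmonics up to ±0.06, pixel size 0.2 μm —
i.e. ~15 μm cells at a typical confocal sampling) **and** jittered field
parameters (weights ± 0.03 s.d., u₀, σ, κ, random μ) from deterministic
substreams of a single panel seed (`SeedSequence(seed).spawn(cell_index)`),
so panels are reproducible at any size and cell i is identical regardless
of panel length. Field jitter is what gives within-preset variance to the
geometry-independent normalized metrics — without it, null-group
comparisons of ground truths would be degenerate. Defaults
photon_budget = 2×10⁶, read noise 2 counts, background 1 count/px give a
high-SNR summed projection typical of fixed-cell confocal imaging;
per-cell MDR recovery through the full pipeline stays within 5% of truth
at these settings (measured ~2%).

What the phantoms deliberately do **not** model: organelle texture
(tubules/sheets), 3D structure beyond the summed projection, uneven
illumination, or segmentation errors — passing tests therefore validate
the measurement chain, not robustness to poor upstream segmentation.

## Statistics

Group comparisons: unpaired two-sided t-test, Mann–Whitney,
Kruskal–Wallis, and one-way ANOVA followed by Dunnett's test against a
named reference (scipy implementations). Summaries are mean ± s.d. with
the sample (n−1) standard deviation — a convention choice, stated here
because either denominator is defensible. P values are reported to 4
significant figures; no multiple-testing correction is applied beyond
Dunnett where selected. The type-I error of the default t-test pathway is
simulated on null panels of per-cell **ground-truth** metrics (two groups
drawn from the same preset): the oracle makes 500-repeat simulations cheap
where re-rendering and re-quantifying ten thousand images would be
wasteful, and the pathway under test — the statistics on exchangeable
per-cell metrics — is identical.

## Numerical choices and limitations

* Sweep grid 0.1° × 0.5 px and u step 0.5% balance resolution against
  memory (a 3600 × ~340 float map per cell); results are stable to grid
  halving well below the grid-convergence tolerance.
* Boundary detection is half-pixel accurate on rasterized masks; on
  60–80 px cells this contributes ≲ 0.5% to MDR.
* Excluded (neighbor) pixels are zeroed, not treated as missing; if an
  exclusion region overlaps the analyzed cell, peripheral mass is slightly
  deflated.
* Masks must be star-convex about the center for the per-angle
  normalization to be well defined; violations raise errors rather than
  silently truncating.
* No background subtraction is applied before quantification; background
  in the image biases MDR toward the area-weighted mean radius of the cell.
* Relative asymmetry agreement is only meaningful away from 0; for
  angularly symmetric cells the statistic is compared on an absolute
  scale (< 0.02 through the pipeline).
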