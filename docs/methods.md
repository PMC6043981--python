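# Methods

## Measurement model

A scan is a stack of calibrated 8-bit cross-section images (default
calibration 1.024 px/mm in-plane, 0.6 mm slice thickness — the operating
point of a medical CT at 120 kVp) of up to 30 stems standing on a 5 × 6
platform. Tissue contrast drives every measurement: lignified rind
attenuates strongly (bright), living pith is intermediate, and "pithy"
tissue — dead, air-filled parenchyma — is nearly transparent (dark). The
per-slice chain is:

1. **Binarization** at intensity ≥ 40. This threshold is not a measured
   constant; it only needs to sit above air/background and below pith
   tissue, and it is exposed in the configuration.
2. **Morphological closing** with a disc of radius 3 px, reconnecting
   regions fragmented by noise.
3. **Hole filling, then connected components** (8-connectivity). Pithy
   tissue can fall below the binarization threshold, so without filling a
   heavily pithy stem would segment as an annulus plus speckle; filling
   makes a region the full cross-section, which the intensity, pithy and
   rind measures all require. Components smaller than
   `height · width · 0.00005` px (≈ 13 px on a 512² image) are discarded.
4. **Eccentricity filter.** Region eccentricity comes from the filled
   region's second-moment ellipse. Two modes exist: `exclude_below`
   (default) drops regions with eccentricity < cutoff (0.08), and
   `exclude_above` drops regions above the cutoff. A perfect disc has
   eccentricity 0, so the default mode excludes ideal circles; it is kept
   as the documented default for continuity with the pipeline this package
   operationalises, while `exclude_above` with a permissive cutoff
   (e.g. 0.9) is the mode a stem survey actually wants and is what the
   validation suites use. The active mode is recorded in each record's
   flags.
5. **Exterior circle.** Kåsa algebraic least squares — minimise
   Σ(x² + y² + ax + by + c)² — on the region's boundary pixels (pixels with
   at least one 4-connected background neighbour). The fit is closed-form,
   deterministic, and exact on true circle points. Because boundary pixel
   *centres* sit on average half a pixel inside the continuous outline, all
   boundary-fitted radii are expanded by a half-pixel correction
   (`radius_correction_px`, default 0.5) before diameters or areas are
   derived. Diameter in mm is `2 r · pixel_spacing`.
6. **Intensity** = mean region pixel value / 255 ∈ [0, 1]; a proxy for
   tissue density (it tracks dry-weight density in field material).
7. **Inner circle.** Pixels brighter than 175 are rind; the largest
   connected component of the remaining pixels is the interior, and the
   inner circle is the boundary fit (same fitter and correction) of that
   component, clamped to the exterior radius. Sections with fewer than
   three qualifying pixels are solid (fully lignified) and carry no inner
   circle, no pithy fraction, and all-rind area.
8. **Pithy fraction** = dark pixels (< 20) in the inner disc divided by the
   inner-disc area. Three denominator conventions are implemented:
   `component` (default) uses the pixel count of the segmented interior
   component, which is exact with respect to the rasterised pith disc;
   `circle_count` counts region pixels inside the fitted circle;
   `continuous` uses πr². The component convention is the default because
   at small pith radii (≲ 5 px) the circle-based denominators carry a
   quantisation error of several percent, exceeding the accuracy the rest
   of the chain achieves.
9. **Rind area** = region pixels outside the interior component — i.e. the
   bright annulus pixel count. (The alternative, pixels outside the fitted
   inner circle, differs only by rasterisation but inherits the circle's
   quantisation error on thin rinds.)

All thresholds assume the 8-bit scale; DICOM inputs are windowed to
[0, 255] on read.

## Tracking, cleaning, aggregation

Regions are assigned to the nearest platform-cell centre; within a stem,
a centroid jump > 15 px between consecutive slices flags the slice as
missing (the section drifted out of its measurement area), and two regions
claiming one cell keep the nearer with a conflict flag. Nodes are not
separable from internode tissue by the segmentation, so node slice indices
are a required annotation; each annotated index is removed with a
±1-slice guard band (configurable — at 0.6 mm slices a node spans several
images). Within each internode segment, slices whose diameter deviates
from the segment median by more than 3.5 MAD are dropped and logged; this
replaces visual outlier screening with a reproducible rule.

Internode 1 is the basal segment (stack bottom to first node). Internode
length uses the full slice span of the segment, so per stem the internode
lengths plus node-gap lengths always sum to the stack length; trait means
use only retained slices. Volume is `π r² h` with `r` from the mean
diameter; densities are mass/volume when masses are supplied.

## Biomechanics

Internodes are modelled as slender Euler–Bernoulli beams with a solid
circular cross-section: `λ = L/D` (specimens with λ ≤ 10 are flagged, not
rejected), `I = πD⁴/64`, `Z = I/r`, `E = F L³/(48 B I)` from a three-point
bending test, `σ_max = F_u L r/(4 I)`, `EI = E·I`. Units are mm, N, MPa.
No hollow-section variant is provided: the solid-section approximation is
part of the measurement definition. Stems are composite materials, so `E`
and `EI` are spatially averaged, effective quantities and are labelled as
such in the output.

## Statistics

The trait model is `y_ijk = µ + g_i + i(g)_ij + ε_ijk` with internode
nested in genotype. LS means use the cell-means OLS parameterisation; a
genotype's LS mean is the unweighted average of its cell means (equal to
the arithmetic mean for balanced data), and genotypes with incomplete
internode coverage are reported rather than silently averaged.

Repeatability refits the model with all terms random. The two variance
ratios (genotype and internode-within-genotype, relative to residual) are
estimated by numeric profile REML: the likelihood factors over genotype
blocks, the residual variance is profiled out in closed form, and L-BFGS-B
optimises the log-ratios; components below ~1e-7 of the residual are
truncated to zero. On balanced data the estimates agree with the ANOVA
method-of-moments estimators (the known REML coincidence), and with
`statsmodels` MixedLM to optimizer tolerance — both checks are in the test
suite. If optimisation fails, the ANOVA estimates are returned tagged
`"mom"`. Repeatability is `H² = σ_G²/(σ_G² + σ_E²)`, i.e. on a plot-mean
basis, excluding the internode component by definition.

LOOCV of `y ~ x` refits each fold explicitly; with one held-out point the
fold RMSE is the absolute prediction error, so both the mean of fold RMSEs
and the pooled RMSE (root of the mean squared fold error) are reported —
"average test error" is ambiguous between them — together with the full-fit
coefficients and R². The fold predictions coincide with the closed-form
PRESS residual predictions `ŷ_i = y_i − e_i/(1 − h_ii)`, which the tests
assert to 1e-10.

Quadrant accuracy places a cutoff at 50 % of each axis (midpoint of the
observed range by default; median optional — the range midpoint is the
natural reading of "50 % cut-off" on a trait axis) and scores the fraction
of points whose observed and predicted values fall on the same side of
their cutoffs.

## The phantom generator

Phantoms emulate what the scanner produces: a bright annular rind
(default intensity 200) around a mid-intensity pith disc (default 120,
chosen to straddle the 175 rind threshold — the instrument does not fix
tissue intensities, only their ordering), dark pithy pixels (value 0)
placed by seeded uniform sampling without replacement inside the pith disc
(pithiness is defined as a dark-area fraction, not a spatial pattern),
per-slice linear taper, solid bright node slices spanning two images, and
additive Gaussian noise clipped to [0, 255]. The truth table records
centres, radii, areas and realised pithy fractions by direct pixel count
on the noise-free rendering; identical seeds give bit-identical stacks.

What the phantom does *not* emulate: beam hardening, scatter, partial
volume at slice boundaries, leaf sheath remnants, non-circular sections,
and stems leaning across cells. Passing the phantom suites therefore
demonstrates that the measurement chain is correct and noise-tolerant on
idealised geometry, not that field scans are error-free.

The benchmark sampler (`sample_platform_spec`) draws 1–30 stems with outer
radii 5–40 px, rind 12–30 % of the radius (a few millimetres at this
calibration, typical of sorghum), and pithy fractions 0–0.8, on a
540 × 640 field of view — slightly wider than the default image so that
two maximal-radius neighbours remain separated by more than twice the
closing radius and are never morphologically bridged.

## Validation problem sizes

The test and acceptance suites use: 50 noise-free platforms (several
hundred stems) for geometry recovery, with tolerances of 1 px on diameter,
0.02 on pithy fraction and 5 % on rind area; 25 platforms at noise sd 10
with doubled tolerances required of ≥ 95 % of stems; 1,000 random draws for
the beam identity suite at 1e-12 relative error; 100 random regression sets
for LOOCV–PRESS agreement at 1e-10; and 200 simulated trials per generative
H² ∈ {0.3, 0.5, 0.7, 0.9} at the field design scale (19 genotypes × 6
plants × 7 internodes), requiring the mean estimate within 0.05 of truth.
These sizes give stable estimates while keeping a full run of the suites in
the low minutes on one CPU.

## Known limitations

* The binarization threshold, node guard band and outlier multiplier are
  heuristics; defaults are sensible for the intended contrast but real
  scans with unusual windowing need configuration.
* Stem identity is positional; stems that lean far enough to cross cell
  midlines will be mis-tracked (the jump flag catches most such slices but
  does not re-identify them).
* Pithy fraction is undefined (reported missing, not zero) for solid
  sections; downstream means skip missing values.
* The REML fit assumes independent normal effects; heavy-tailed residuals
  or genotype-by-internode interaction structure beyond the nested term
  are not modelled.
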