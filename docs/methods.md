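# Methods

This note documents the models, conventions and numerical choices behind
`hemoquant`, in the order data flows through the package.

## Coordinate and unit conventions

Stacks are `(C, Z, Y, X)` or `(C, T, Z, Y, X)`, channel first. The x–y
plane is isotropic with one pixel size; the z step is independent,
reflecting confocal sectioning where live cells are imaged at 0.5–1 µm
optical-path spacing (finer, 0.2–0.3 µm, for detailed reconstruction).
Lengths are µm (areas µm², volumes µm³); time is seconds internally and
minutes at reporting. Frame intervals are stored per movie — time-lapse
acquisition commonly varies between 90 and 120 s per frame across
series, and prevalence minutes are always converted with each movie's
own interval, never a global constant.

The default lateral sampling of the simulator is 0.1 µm/px. No pixel
size is canonical for this kind of data (objective magnification and
camera binning vary); 0.1 µm/px is a realistic value for a 63×/1.4 NA
oil objective and is configurable everywhere.

## Geometry: the cell, vacuoles, vesicles

The cytoplasm is modelled as an oblate ellipsoid with equatorial
semi-axis *a* ("radius", measured at the widest z-slice) and axial
semi-axis *b* ("height", half the top-to-bottom extent of the
orthogonal projection). Two volume arrangements are implemented:

- `as-printed`: V = 4/3·π·a·b² — the literal arithmetic of the
  workflow this package automates;
- `standard-oblate`: V = 4/3·π·a²·b — the volume of an oblate spheroid
  with semi-axes (a, a, b).

The two conventions conflict (the "as-printed" arrangement is the
prolate-style formula), and the available summary value of 311.06 µm³
for the wild-type average cannot discriminate which was actually
computed without the underlying per-cell radii. Both are therefore
provided; `as-printed` is the default so published index values are
replicated literally, and nothing in the package asserts that either is
the "true" historical arithmetic. Both reduce to the sphere when
a = b, which the test suite pins down.

Vacuoles — voids that disrupt the cytoskeleton — are modelled as
spheres sized from the widest diameter, V = 4/3·π·r³. Only vacuoles
with r ≥ 1.5 µm enter the occupied volume index (OVI); a cell whose
vacuoles are all smaller scores exactly 0. The OVI denominator is by
default the *fixed* wild-type average cytoplasmic volume (311.06 µm³)
for all groups — the design choice of the original analysis, justified
there by the small wild-type/mutant difference in cytoplasm volume — 
with a per-cell ellipsoid denominator available for methodological
comparison.

## Segmentation

**Cell body.** Otsu threshold on the analysed channel, largest
connected supra-threshold component (ties broken toward the lowest
label), holes filled both in 3D and per slice so that vacuole voids stay
inside the mask. *a* is the equivalent-circle radius of the widest
z-slice; *b* is half the axial extent of the mask. Otsu is appropriate
here because foreground and background are both abundant classes.

**Vacuoles.** Otsu fails for voids, which occupy a tiny fraction of the
in-cell intensity histogram, so voids are found with a half-depth rule:
voxels below the midpoint between the in-cell median and the in-cell
minimum, restricted to the cell mask eroded by 2 px in-plane (rim
artifacts are not voids). Candidate components must also reach within
25% of the in-cell depth minimum (rejecting shallow dips) and pass a
conservative voxel-count prefilter implied by the radius cutoff. Each
void's diameter is the maximum Feret diameter over its z-slices. The
Feret value returned by the marching-squares contour overestimates a
digitized disk's true diameter by ≈1.5 px essentially independently of
radius (measured 1.2–1.65 px over radii 15–50 px), so 1.5 px is
subtracted; the residual radius error is below half a pixel, and
end-to-end OVI recovery on noise-free scenes is within 1% of analytic
truth (the suite enforces 5%).

**Particles (vesicles, lysosomes).** ImageJ-style binary particle
analysis: Otsu threshold on the 2D plane or projection, 8-connected
components, filter by area and circularity. The area filter's unit is
declared explicitly (`px2` default, mirroring ImageJ's pixel-unit
behaviour for the "20–infinity" bound, `um2` optional) because the
published bound is ambiguous between the two. Circularity is 4πA/P²
clipped to [0, 1], with the Crofton perimeter — the step-count
perimeter undershoots badly for thin objects and would let elongated
debris through a circularity gate. Because the threshold is relative,
all particle measures are invariant to a positive intensity gain.

## Colocalization

Plain (unthresholded) sample Pearson correlation of two channels'
intensities within the cell mask, per cell; no Costes thresholding, no
Manders coefficients. A constant channel raises an error rather than
reporting 0. 3D stacks are correlated on their maximum projections by
default, matching a projection-based scoring workflow; a per-plane mode
exists, and is the right choice for anti-correlated channels, whose
inverted background saturates a maximum projection.

## Phagosome maturation scoring

The particle is localized per frame as the largest component above a
robust threshold (background median + max(6·robust σ, half the peak
height above the median), after 1 px in-plane smoothing) — a dim
pre-docking particle is a minute intensity class for which Otsu is
again unusable. Docking t0 is the first frame whose particle mask
overlaps the cell mask by ≥ 1 px; a particle that never contacts the
cell is flagged, not raised. Intensity is the pixel sum over a square
ROI of fixed physical area (0.9 µm², side = round(√0.9/pixel) px) on
the z-plane through the particle's middle, divided by the ROI pixel
count; raw values are reported (no background subtraction, no
photobleaching correction). "Surrounded by FYVE" — undefined in purely
visual scoring — is operationalised as ≥ 50% (configurable) of the 1-px
annulus just outside the particle boundary being FYVE-positive, with one
binarization threshold per movie computed by Otsu over the in-cell FYVE
voxels; if the "positive" class is not a distinct minority (> 30% of
voxels) the movie is judged coat-free and all frames are negative.
Prevalence is exactly positives × interval (minutes) — the suite checks
the integer bookkeeping identity. A single particle per movie is
assumed; there is no identity-switching multi-particle tracker.

## Synthetic data

The generators define the test conditions for everything above.

- **Cell scenes**: ellipsoid cell of uniform cytoskeleton intensity
  (default a = 5 µm, b = 3 µm, intensity 100 on background 2) with
  zero-intensity spherical voids and filled/ring vesicles in a second
  channel. Scene truth carries the closed-form volumes.
- **Colocalization scenes**: `round(|ρ|·n)` of n puncta are shared
  between channels, the rest drawn independently, giving an expected
  within-mask correlation of ≈ |ρ|; negative targets invert channel 1
  inside the cell. A constant cytoplasmic fill makes the scene
  segmentable without changing the correlation. The realized
  correlation converges to the target as n grows and is recorded in the
  truth.
- **Movies**: the particle sits just outside the cell until the docking
  frame, then inside it; its intensity follows a logistic ramp
  (baseline 10 → plateau 100, half-rise 10 min, time constant 2.5 min —
  a monotone acidification profile; the true functional form is not
  known, only its monotone rise). The FYVE coat is a spherical shell of
  0.3 µm (rings are observed, their thickness is not reported) drawn
  for a dwell sampled from a truncated normal (default mean 20 min,
  sd 5 min), truncated-and-flagged if it outlasts the movie.
- **Cohorts**: death days are discretized (⌈·⌉, ≥ 1) Weibull lifetimes
  parameterized by median and target sd — daily scoring implies integer
  death days; no censoring is modelled because cohorts are followed to
  death. Colony counts are Poisson with mean true CFU × sampling
  fraction / dilution; the CFU estimate (count × dilution at the lowest
  countable spot, saturation limit 150 per spot by default) is per
  plated aliquot.
- **Noise model**: ideal geometry → Gaussian blur (default σ 0.1 µm) →
  Poisson shot noise (default 1 count per intensity unit) → additive
  Gaussian read noise (default σ 1). This is a standard fluorescence
  forward model without PSF anisotropy physics or spectral
  bleed-through; parameters live on the spec so tests can switch noise
  off.

What the simulator does **not** emulate: cell-to-cell intensity
heterogeneity, textured cytoskeleton, irregular (non-ellipsoidal) cell
shapes, touching cells, stage drift, photobleaching, and true PSF
optics. Passing tests therefore demonstrate the correctness of the
measurement definitions and their noise robustness within this forward
model — not performance on arbitrary real micrographs, where
segmentation thresholds would need revisiting.

## Statistics

- One-way ANOVA from explicit sums of squares, F = MS_between/MS_within
  with df (k−1, N−k); undefined (raised) when all groups have zero
  within-group variance.
- Bonferroni post hoc: pairwise t with the pooled within-group variance
  over *all* groups (df N−k), adjusted p = min(1, m·p) — the classic
  "Bonferroni test" of common GUI stats packages, deliberately not Holm
  or Tukey. Null simulations in the suite confirm family-wise error
  ≤ α and type-I calibration of the ANOVA at 5% ± 2%.
- Mann-Whitney U with midrank ties: exact p by full enumeration of
  label assignments for small samples (≤ 8 per group or ≤ 10 pooled),
  matching an independent pairwise-counting enumeration oracle in the
  tests; otherwise the normal approximation with tie-corrected variance
  and continuity correction.
- Survival: per-replicate medians (midpoint convention), group summary
  mean ± SEM over replicates — the "median ± x d" reporting convention
  for cohorts split across tubes; relative lifespan = 100 × group /
  reference, rounded only at display.
- Time courses: two-factor group × time ANOVA on the long-format table
  plus per-timepoint one-way ANOVAs Bonferroni-adjusted over the number
  of timepoints, reporting the earliest adjusted-significant timepoint.
  Misaligned time grids are an error; nothing is interpolated.

## Problem sizes and determinism

Simulation-backed checks use sizes chosen to make their statistical
claims decisive at desk scale: 20 noise-free cells for end-to-end OVI
recovery (224² × 36 voxels at 0.05 µm/px, the "detailed imaging"
regime), 50 movies for dwell recovery, 25 cells per group × 10
replicates for the powered OVI/OAI contrast, 2000 null replicates for
ANOVA calibration. Every stochastic path takes an explicit seed and
identical spec + seed is bit-reproducible, including whole experiment
runs (byte-identical CSVs).

## Known limitations

- Vacuole sizing assumes approximately spherical, non-overlapping
  voids; fused voids are measured as one object at their widest span.
- Spot counting reports a lower bound when spots merge below the
  resolution limit (flagged via an oversize heuristic).
- The per-cell OVI denominator requires 3D cell measurements; 2D input
  supports only the fixed-reference mode.
- The Feret bias correction (−1.5 px) is calibrated for disk-like
  objects ≥ ~10 px across; much smaller or highly non-convex voids
  would need a different estimator.
- Maximum-projection colocalization inflates r when many puncta
  overlap in projection; use the per-plane mode for crowded or
  anti-correlated scenes.
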