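# Methods

This note documents the models and procedures implemented in `octa-surface`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data validation does and does not
demonstrate.

## Imaging geometry

A macular OCTA acquisition is a 3 × 3 × 2 mm cube sampled at
245 × 245 × 1024 voxels: lateral pitch 3/245 ≈ 12.2 µm, axial pitch
2/1024 ≈ 1.95 µm — a ~6.3 : 1 anisotropy that drives several choices below.
Volumes are indexed `(x fast, y slow, z depth)`; voxel (i, j, k) is centred
at ((i+0.5)dx, (j+0.5)dy, (k+0.5)dz) mm.  The vendor's raw `.img` layout is
undocumented, so the package defines its own raw dialect (uint8, x fastest,
en-face frames stacked along z, JSON sidecar) and treats en-face image-slice
stacks as the interchange format.  The device's 0–10 signal-quality grade is
carried as metadata only.

## Segmentation chain

Five deterministic stages; all protocol defaults are exposed in
`PipelineConfig`.

1. **CLAHE**, per en-face slice, 8 × 8 tile grid, clip limit 1.0 on the
   normalised [0, 1] scale, 5 histogram bins, uniform target distribution.
   "Clip limit 1" therefore means no histogram clipping — maximal adaptive
   equalisation.  The distribution shape parameter (`clahe_alpha`) is kept
   for config fidelity but is unused in uniform mode.  Constant slices are
   passed through unchanged and logged.  A consequence worth knowing:
   constant *tiles* inside a non-constant slice equalise to full brightness.
   Real flow volumes always carry a speckle floor, so this is harmless on
   acquired data, but a synthetic phantom on an exactly zero background is
   pathological for this stage (see "Synthetic validation" below).
2. **Unsharp masking**: out = in + 0.8·(in − G(in, σ=1 px)), blur applied
   within the en-face plane, clipped to [0, 255].  Radius and gain are not
   part of the documented protocol; conventional mild-sharpening values were
   chosen once and exposed in the config.
3. **Multiscale vesselness** (Frangi-type, bright tubes on dark
   background), 3D: Gaussian-derivative Hessian at σ ∈ {10, 11, …, 15}
   voxel units, γ = 2 scale normalisation, eigenvalues sorted by magnitude,
   α = β = 0.5, c = half the maximal Frobenius norm per scale ("auto").
   Response is zeroed where λ₂ > 0 or λ₃ > 0, maximised over scales, then
   min–max rescaled to [0, 255].  Scales are applied isotropically in index
   space by default (the protocol scales are unitless and the protocol does
   not resample the anisotropic grid); a "physical" sigma mode that
   equalises the smoothing width in mm per axis is available.  The filter
   runs in 3D because the measurement itself is volumetric.
4. **Hysteresis threshold** 40/45 on the rescaled vesselness: a voxel
   survives iff it is ≥ 40 and 26-connected through ≥ 40 voxels to some
   voxel ≥ 45.  Thresholds of this magnitude only make sense after the
   8-bit-style rescaling, which is why rescaling is part of stage 3's
   contract.
5. **Size filter**: components (26-connectivity) with fewer than 30 voxels
   are removed; "minimum size 30" is read as the smallest surviving size.

All convolutions use reflect padding.  The chain is a pure function of
(volume, config); per-stage summaries are logged.

## Surface area

Two estimators:

* **Mesh (default)**: marching cubes on the 0.5-level set at the mask's
  physical spacing, after padding with background so boundary-touching
  vessels are capped.  The binary field is first anti-aliased with a
  Gaussian of one coarsest-voxel-pitch width.  This matters: on a raw 0/1
  field the extracted surface follows the digitisation staircase, which
  inflates the area of smooth solids by ~19% on an isotropic grid and ~34%
  at the 6.3 : 1 acquisition anisotropy (measured on digitised cylinders),
  while the level set of the smoothed field tracks the true boundary to
  sub-voxel accuracy (cylinder errors 6.8 / 2.0 / 0.3 / 0.2 % at radii
  5 / 10 / 20 / 40 lateral voxels).  Anti-aliasing is skipped automatically
  when a structure is thinner than the smoothing width (a single-voxel mask
  must not vanish), and can be disabled (`smooth_sigma_mm=None`) — the
  right setting for deliberately blocky solids, where the raw isosurface is
  chamfer-exact.
* **Voxel faces**: the sum of exposed 6-neighbour face areas, exact integer
  arithmetic.  It deliberately over-counts staircase surfaces (mesh/face
  ratio ≈ 0.7–1.0 on convex solids) and serves as the independent oracle in
  the tests, never as the reported measurement.

## Ocular magnification

The device converts scan angle to lateral mm assuming a reference eye
(24.46 mm axial length by default — a common emmetropic assumption, not a
measured constant; configurable).  Following Littmann's method with
Bennett's reduced-eye simplification q = 0.01306·(AL − 1.82), the true
lateral scale differs by k = (AL − 1.82)/(AL_ref − 1.82).  Because the
measured object is a surface embedded in 3D, the default correction
rescales the mesh's x, y coordinates by k and recomputes the area — purely
lateral facets then scale by k², purely axial ones by k.  Whether the 2D
formulas transfer to 3D surfaces is unsettled, so a "planar" mode
(area × k²) is provided for comparison with en-face conventions.  The axial
dimension is optically determined and left untouched.  Correction is never
applied silently; raw areas remain the primary output.

## Cohort statistics

* **Summaries**: count / mean / sd (n − 1) / min / quartiles (linear
  interpolation) / max, per variable, overall and per stratum (e.g. sex ×
  laterality), on non-missing values only.
* **Correlation**: Pearson r with the two-sided non-correlation test,
  t = r√((n−2)/(1−r²)) on n − 2 df, pairwise deletion.
* **GLM**: ordinary least squares (Gaussian family, identity link) of
  surface area on sex + age + SE + AL + VA and all ten two-way
  interactions; each of the 15 effects is tested with a type-II F statistic
  (the effect's sum of squares conditions on every term not containing it,
  respecting marginality; the denominator is the full-model residual mean
  square).  Sex is coded 0/1 with female as reference (the larger group);
  type-II F tests are contrast-invariant, so this is cosmetic.  Eyes are
  analysed separately to avoid fellow-eye correlation; no mixed-effects
  modelling is attempted.  Degenerate cases are explicit: a perfect fit
  reports F = ∞, p = 0 for the real effects; rank deficiency and
  n ≤ parameter count raise errors naming the problem.  Visual acuity is
  modelled untransformed.
* **Paired t**: two-sided, on within-subject OD−OS differences.
* **Outliers**: flagged by a declared rule — Tukey far-out fences
  (3 × IQR) or |z| > 3 — and only ever removed by an explicit, logged
  caller decision.  Published normative analyses sometimes remove outliers
  without identifying them; with an unknown criterion and unknown removed
  observations, third-party F values cannot be reproduced exactly, which is
  why this package refuses to make that choice implicitly.  The acceptance
  suite demonstrates the mechanism: removing two extreme eyes from a
  107-eye cohort shifts GLM F statistics by order 1.

## Synthetic data

**Phantoms.** Straight capped cylinders (flat ends), rasterised by the
voxel-centre rule: axial coordinate in [0, L] and perpendicular distance
≤ r.  The analytic truth is Σ(2πrL + 2πr²); specs with intersecting tubes
are rejected so the truth stays exact.  Intensities are vessel/background
levels plus seeded Gaussian speckle, clipped to 8 bits; the truth mask
depends only on geometry, never on the noise seed.  Defaults (background
40, speckle σ 15, vessel 255) emulate a bright flow signal on a
speckle-noise floor.  Two deliberate mismatches with acquired data: no
capillary-network morphology (straight tubes only carry analytic areas) and
no structured OCT speckle or projection tails.  Hence passing phantom tests
shows the chain is correct and well-calibrated *for resolvable tubes on
speckle backgrounds*; it does not certify accuracy on capillary plexuses.

**Chain-validation conditions.** The standard validation phantom uses a
tube radius of 12 lateral voxels — inside the default filter scale range
(σ 10–15), as the scales must resolve the structure — on an
isotropic-pitch grid (the index-space sigmas then match physical space),
with ≥ 32 voxels of clearance.  Two conditions the chain is *not* expected
to handle, both traceable to stage 1: an exactly-zero noiseless background
(constant tiles equalise to full brightness, and the resulting slab edges
dominate the vesselness normalisation), and tubes much thinner than the
configured scales (a radius-6 tube under σ 10–15 reaches only ~63%
overlap).  Under the standard conditions the chain recovers 83–85% of true
tube voxels with ≤ 15% of the mask outside a 2-voxel dilation of the truth,
and the measured area closes to within a few percent of the analytic value
(the 25% end-to-end tolerance in the acceptance suite leaves headroom for
seed variation).

**Cohorts.** Per subject: sex ~ Bernoulli(0.617 female), age ~ N(43.39,
14.05²) years, AL ~ N(23.8, 1.03²) mm truncated > 20, SE ~ N(−0.41, 2.04²)
D, VA ~ N(0.97, 0.07²) clipped to (0, 1] (an acuity ceiling, as on real
charts).  Two eyes per subject share covariates; residuals are independent.
Surface = 54.53 − 2.7·(AL − 23.8) − 0.16·(age − 43.39) + ε, ε ~ N(0,
10.8²) mm².  The AL slope of −2.7 mm²/mm yields a surface–AL correlation of
about −0.26 at these spreads, and the age slope −0.16 mm²/year about −0.2;
both are fixture parameters chosen to give the generator the correlation
magnitudes typical of a healthy adult cohort, not estimates of any real
population.  The GLM calibration uses 100 cohorts of 200 subjects with only
the AL slope nonzero, pooling both eyes (400 rows, valid here because the
generative residuals are independent by construction); at these settings
the analytic power of the AL test at p < 0.001 is ≈ 0.97, and the
simulations detect it in ≈ 95% of replicates while each null effect stays
above p = 0.05 in > 90%.

## Problem sizes and determinism

Validation phantoms are run at roughly 190 × 90 × 90 voxels — large enough
for ≥ 3-radius background clearance around a scale-matched tube, small
enough that the whole suite stays interactive.  All stochastic tests and
the acceptance script draw every random number from explicit seeds;
identical seeds give bit-identical outputs, including the mask TIFFs and
result JSONs written by the CLI.

## Known limitations

* The chain's accuracy on real capillary plexuses is not established by
  phantom tests (no branching, no projection artifacts — the acquisition
  protocol itself provides no projection-artifact removal for raw exports).
* Index-space filter sigmas on the anisotropic acquisition grid mean the
  physical smoothing width differs per axis; the "physical" sigma mode
  exists but was not the validated default.
* The Bennett correction treats only the lateral scale; no standard exists
  for 3D surface-area magnification correction, and both provided modes are
  flagged as such.
* Fellow-eye correlation is handled by splitting, not modelling; a
  mixed-effects extension would use the same table layout.
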