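# octa-surface

Volume-rendered OCT angiography (OCTA) resolves retinal blood flow in three
dimensions, but almost all quantitative OCTA work collapses the volume into
2D en-face projections.  `octa-surface` measures the vasculature where it
lives: it segments the flow signal of a full 3D macular OCTA cube and
reports the **total retinal vessel surface area in mm²** — the physical
quantity behind metabolic exchange across the vessel wall — together with
the statistical toolkit needed to build and analyse a normative database of
such measurements.

The package is aimed at ophthalmic-imaging researchers who have raw OCTA
exports (3 × 3 × 2 mm macular cubes, 245 × 245 × 1024 voxels) and want a
fully automatic, reproducible pipeline from voxels to population statistics,
plus synthetic phantoms and cohorts to validate every stage without
patient data.

## What it computes

**Segmentation** is a five-stage chain applied to the flow volume:

1. CLAHE contrast enhancement per en-face slice (clip limit 1, 5 bins);
2. unsharp-mask sharpening (slice-wise Gaussian blur, σ = 1 px, gain 0.8);
3. multiscale Hessian vesselness (Frangi): with eigenvalues
   |λ₁| ≤ |λ₂| ≤ |λ₃| of the scale-normalised Hessian at σ ∈ {10…15} voxels,

   V = (1 − e^(−R_A²/2α²)) · e^(−R_B²/2β²) · (1 − e^(−S²/2c²)),

   R_A = |λ₂|/|λ₃|, R_B = |λ₁|/√(|λ₂λ₃|), S = ‖H‖_F, zero where λ₂ > 0 or
   λ₃ > 0 (bright tubes only), maximum over scales, rescaled to [0, 255];
4. hysteresis thresholding (40/45, 26-connectivity);
5. removal of connected components below 30 voxels.

**Surface area** comes from a marching-cubes triangulation of the mask at
its physical voxel spacing (the binary field is Gaussian anti-aliased by one
voxel pitch so staircase facets do not inflate the area; an exact
voxel-face counting estimator serves as an independent check).  Ocular
magnification is corrected via Littmann/Bennett: the lateral scale factor
k = (AL − 1.82)/(AL_ref − 1.82) rescales the mesh in x, y and the area is
recomputed (a planar k² mode is also provided).

**Cohort statistics** mirror a normative-database analysis: per-stratum
summary tables; Pearson correlation with the t-test for non-correlation;
a Gaussian GLM of surface area on sex, age, spherical equivalent, axial
length and visual acuity with all ten two-way interactions, tested with
type-II (marginality-respecting) F statistics; a two-sided paired t-test
between fellow eyes; and explicit, logged outlier rules.

**Synthetic data** closes the loop: tube phantoms with analytically known
surface area (2πrL + 2πr² per capped cylinder) on a speckle background, and
two-eyes-per-subject cohorts from a linear generative model with realistic
covariate distributions.

## Worked example

```python
from octa_surface import (
    CohortSpec, MagnificationParams, PipelineConfig,
    apply_magnification_correction, cylinder_phantom_spec, fit_glm_type2,
    generate_cohort, generate_phantom, segment_vessels, surface_area_mesh,
)

spec = cylinder_phantom_spec(radius_vox=12, length_vox=100, margin_vox=32,
                             speckle_sigma=15.0, background_level=40.0,
                             noise_seed=1)
phantom = generate_phantom(spec)
mask = segment_vessels(phantom["volume"], PipelineConfig())
result, mesh = surface_area_mesh(mask)
print(f"analytic tube area : {phantom['analytic_area_mm2']:.4f} mm^2")
print(f"measured area      : {result.area_mm2:.4f} mm^2 ({result.n_triangles} triangles)")

corrected = apply_magnification_correction(result, mesh,
                                           MagnificationParams(al_mm=25.6))
print(f"corrected area     : {corrected.corrected_area_mm2:.4f} mm^2 "
      f"(k = {corrected.correction_factor_k:.4f})")

cohort = generate_cohort(CohortSpec(n_subjects=107, seed=1))
glm = fit_glm_type2(cohort.eye_subset("OS"))
print(glm.table.loc[["al", "age", "sex"]].round(4))
```

prints

```
analytic tube area : 1.2662 mm^2
measured area      : 1.3221 mm^2 (23936 triangles)
corrected area     : 1.4147 mm^2 (k = 1.0504)
          F       p  df_num  df_den sign
al   6.5180  0.0123     1.0    91.0    *
age  6.8224  0.0105     1.0    91.0    *
sex  0.0774  0.7815     1.0    91.0
```

The tube phantom's true area is 1.2662 mm²; the automatic chain recovers it
within ~4%.  Magnification correction for a 25.6 mm eye stretches the
lateral scale by k = 1.05.  In the synthetic left-eye cohort the GLM flags
the axial-length slope (which the generator really put in) while sex stays
null; any single 107-subject draw can also show chance findings, which is
exactly what the calibration tests quantify over 100 replicates.

A command-line front end covers the same workflow for on-disk data:

```bash
octa-surface simulate --out demo --seed 1 --n-subjects 60
octa-surface segment demo/phantom.raw --out demo/seg --al 24.5 --correction mesh
octa-surface stats demo/cohort.csv --out demo/stats
```

## Layout

- `src/octa_surface/volume_io.py` — raw/slice-stack volumes, mask TIFFs, STL/PLY meshes, cohort CSVs
- `src/octa_surface/vessel_pipeline.py` — the five-stage segmentation chain
- `src/octa_surface/surface_metrics.py` — mesh and voxel-face areas, magnification correction
- `src/octa_surface/cohort_stats.py` — summaries, correlations, type-II GLM, paired t, outliers
- `src/octa_surface/synthetic_data.py` — tube phantoms and synthetic cohorts
- `src/octa_surface/cli.py` — `octa-surface segment | batch | stats | simulate`
- `docs/methods.md` — models, parameters, numerical choices and limitations
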