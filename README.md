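# fwpenumbra

Free-water imaging of the tissue band around white matter hyperintensities
(WMH) in cerebral small vessel disease.

WMH are the visible FLAIR lesions of small vessel disease, but the
*normal-appearing* white matter (NAWM) around them is already altered. This
package implements a complete, testable pipeline for delimiting that
"WMH penumbra" from single-shell diffusion MRI:

1. **Bi-tensor free-water fit.** Per voxel the DWI attenuation is modelled
   as two compartments,

   `A(b, g) = (1 − f) · exp(−b gᵀDg) + f · exp(−b d_w)`,

   where `f` is the free-water fractional volume, `D` the tissue diffusion
   tensor, and `d_w = 3.0×10⁻³ mm²/s` the diffusivity of free water at body
   temperature. The regularized non-linear fit (projected Gauss–Newton with
   an optional Laplacian smoothness penalty on `f`) yields FW maps and the
   FW-corrected fractional anisotropy FA-t of the tissue tensor.
2. **Rim ROIs.** The lesion mask (2 mm isotropic) is dilated voxel by voxel
   with a face-connectivity element and filtered with the white-matter mask,
   producing 8 disjoint one-voxel rims — a 16 mm distance band around WMH.
   Subjects with less than 4 lesion voxels (0.032 ml) are excluded.
3. **Adjacency-contrast mixed models.** FW and FA-t ROI means enter linear
   mixed-effects models (random subject intercept; age, sex and log WMH
   load as covariates) with forward-difference contrasts: coefficient *i*
   estimates mean(region *i*) − mean(region *i+1*). The penumbra is the
   contiguous run of rims supported by significant adjacent contrasts, and
   its merged mean feeds cerebrovascular-risk regressions (smoking,
   diabetes, hypertension).

Because the cohort data behind this design cannot be redistributed, the
package ships a first-class synthetic module: DWI phantoms with ellipsoidal
lesions, distance-driven FW/FA fields and Rician noise, plus an image-free
cohort generator whose covariate margins match the study population
(median age 64, 45.8 % female, 15.7 % smokers, 8.1 % diabetes, 68.7 %
hypertension). Every stage is validated against independent oracles on
these synthetic inputs; see `docs/methods.md` for the model details and
known limitations (in particular the weak identifiability of single-shell
free-water estimation at realistic SNR).

## Worked example

Simulate a 200-subject cohort whose FW is elevated through the fourth rim
and whose FA-t is altered through the sixth, then fit the mixed model and
delimit the penumbra:

```python
from fwpenumbra import CohortSpec, simulate_cohort_rois, fit_roi_lmm, detect_penumbra
from fwpenumbra.synthcohort import recovery_profiles

fw_p, fat_p = recovery_profiles()
table = simulate_cohort_rois(
    CohortSpec(n_subjects=200, fw_profile=fw_p, fat_profile=fat_p, seed=42)
)
res = fit_roi_lmm(table, outcome="fw")
print(res.contrasts)
pen = detect_penumbra(res.contrasts, alpha=0.05)
print(f"fw penumbra: {pen.extent_mm} mm {pen.member_rims}")
```

which prints

```
       name estimate     se    pvalue
  WMH - 2mm   0.1634 0.0020         0
  2mm - 4mm   0.0615 0.0020 2.43e-211
  4mm - 6mm   0.0593 0.0020 5.75e-197
  6mm - 8mm   0.0610 0.0020 2.59e-208
 8mm - 10mm   0.0585 0.0020 2.19e-191
10mm - 12mm   0.0010 0.0020     0.628
12mm - 14mm  -0.0021 0.0020     0.288
14mm - 16mm   0.0007 0.0020     0.732
fw penumbra: 8 mm ['2mm', '4mm', '6mm', '8mm']
```

Each contrast row is the estimated FW difference between a region and the
next rim outward, in FW units: large significant steps up to the 8–10 mm
transition, then nothing — so the four innermost rims (an 8 mm band) form
the free-water penumbra. The same call with `outcome="fa_t"` detects the
12 mm FA-t extent.

The same stages are available from a shell:

```sh
fwpenumbra simulate cohort --seed 2 --out out/
fwpenumbra analyze --table out/cohort_long_table.csv --outcome fw --out out/
fwpenumbra run --seed 3 --out demo/        # phantom + cohort, end to end
```

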