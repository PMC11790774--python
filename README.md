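# cardiodti

Analysis pipeline for high-resolution **ex-vivo cardiac diffusion tensor
imaging (DTI)** of the left ventricle (LV), aimed at small-animal studies of
myocardial microstructure — in particular atrophic remodeling such as
anthracycline-induced cardiotoxicity, where wall thinning and reduced radial
water diffusion alter the shape of the diffusion tensor. The package takes
4-D diffusion-weighted volumes (NIfTI-1 + FSL-style `bvals`/`bvecs`) with a
myocardial mask and produces voxelwise microstructure maps, regional
summaries and cohort-level statistics. Because such datasets are rarely
deposited, it ships a synthetic LV phantom with fully known ground truth
that exercises — and validates — every stage.

## What it computes

Signals follow the Stejskal–Tanner decay `S_k = S0 · exp(−b_k g_kᵀ D g_k)`
with a symmetric 3×3 tensor `D` per voxel, estimated by log-linear least
squares (optional single reweighted pass). From the sorted eigenvalues
λ₁ ≥ λ₂ ≥ λ₃ and eigenvectors e₁, e₂, e₃:

- **MD** = (λ₁+λ₂+λ₃)/3 and
  **FA** = √½ · √((λ₁−λ₂)² + (λ₂−λ₃)² + (λ₃−λ₁)²) / √(λ₁²+λ₂²+λ₃²);
- **Westin shape components** (trace-normalized, summing to 1):
  c_linear = (λ₁−λ₂)/T, c_planar = 2(λ₂−λ₃)/T, c_spherical = 3λ₃/T with
  T = λ₁+λ₂+λ₃;
- **helix angle (HA)**: elevation of e₁ within the wall tangent plane
  relative to the circumferential direction, positive endocardially;
  **transmural helicity** as the fitted HA slope in °/mm and per % wall
  thickness; proportions of voxels in the (−90,−30)/[−30,30]/(30,90] bands;
- **absolute sheetlet angle |E2A|**: elevation of e₂ out of the in-wall
  cross-fiber direction, in [0°, 90°];
- **AHA 17-segment** labelling with the standard ROI groups (anterior
  {1,7,13}, septal {2,3,8,9,14}, inferior {4,10,15}, lateral {5,6,11,12,16})
  and **LV mass** = myocardial volume × 1.05 g/cm³, indexed to tibial length;
- **cohort statistics**: Shapiro–Wilk screening, two-tailed unpaired
  Student's t-tests, OLS regression with 95% CI, and ROC discrimination
  with Mann–Whitney AUC, DeLong 95% CI, Youden-index cutoffs and Wilson
  intervals on sensitivity/specificity.

Optionally, stacks are denoised before fitting by sliding-window local PCA
with a Marchenko–Pastur noise threshold.

## Worked example

Simulate and analyse a small two-group cohort (3 controls, 3 subjects with
the atrophic "disease" preset: 25% thinner wall, λ₂ −15%, λ₃ −25%) at
SNR 50:

```python
from cardiodti.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(n_control=3, n_disease=3, snr=50.0, master_seed=7,
                     out_dir="demo_out")
results, metrics, manifest = run_pipeline(cfg)
print(results.summary())
```

prints (abridged):

```
Cohort analysis (mean ± SEM; two-tailed unpaired Student's t-test)
fa                  control 0.1756 ± 0.0034  disease 0.3032 ± 0.0079  t=-14.821 p=0.0001*
c_planar            control 0.1109 ± 0.018   disease 0.1691 ± 0.016   t=-2.413  p=0.0734
c_spherical         control 0.8273 ± 0.011   disease 0.7085 ± 0.013   t=+7.040  p=0.0021*
abs_e2a             control 29.98 ± 0.052    disease 30.03 ± 0.042    t=-0.769  p=0.4847
helicity_slope_mm   control -119.9 ± 3       disease -174.6 ± 7.1     t=+7.055  p=0.0021*
helicity_slope_pct  control -1.182 ± 0.0058  disease -1.202 ± 0.021   t=+0.914  p=0.4123
lv_mass_index       control 1.868 ± 0.014    disease 1.486 ± 0.028    t=+12.362 p=0.0002*

ROC fa          AUC=1.000 (1.00–1.00) p=0.0000 cutoff=0.2905 sens=1.0 spec=1.0
ROC c_spherical AUC=1.000 (1.00–1.00) p=0.0000 cutoff=0.7336 sens=1.0 spec=1.0
```

Reading: the atrophic group shows higher FA and tensor planarity, lower
sphericity, steeper helicity in °/mm (a pure wall-thickness effect — it
vanishes when normalized per % wall thickness), unchanged |E2A|, and lower
LV mass index; FA and sphericity separate the groups perfectly at this
construction-forced effect size. The same analyses run from the shell via
`cardiodti run --config cfg.yaml`, or stage by stage with
`cardiodti simulate / fit / angles / segment / cohort`.

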