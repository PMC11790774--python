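# Methods

This note documents the models, conventions and numerical choices behind
`cardiodti`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic validation does and does not show.

## Signal model and tensor estimation

Diffusion-weighted magnitudes are modelled as mono-exponential
Stejskal–Tanner decays, `S_k = S0 exp(−b_k g_kᵀ D g_k)`, with a single
symmetric positive tensor `D` per voxel. Estimation solves the linearised
system `ln S_k = ln S0 − b_k g_kᵀ D g_k` by ordinary least squares; a single
optional reweighted pass uses squared predicted signals as weights, the
usual first-order correction for the log-transform's noise heteroscedasticity.
No robust outlier rejection, free-water elimination or kurtosis terms are
fitted. Zero/negative signals inside the mask are clamped to the smallest
positive double before the logarithm; voxels with no positive signal at all
are flagged invalid and excluded from every derived map.

Eigenvalues are sorted descending. Noisy fits occasionally produce
non-positive-definite tensors; negative eigenvalues are clamped to a floor
of 1e−7 × the voxel's mean diffusivity (at least 1e−12 mm²/s) and the count
of affected voxels is reported — clamping keeps the shape metrics defined
without silently discarding voxels. Eigenvector sign is fixed by making each
vector's largest-magnitude component positive (eigenvectors are axes);
`e₃` is then recomputed as `e₁ × e₂` so the triad is right-handed. In exact
eigenvalue ties any orthonormal pair is acceptable; orthonormality is what
is guaranteed.

Westin shape components are normalized by the trace (so
c_linear + c_planar + c_spherical = 1), not by λ₁. Trace normalization is
the variant consistent with reported murine myocardium operating points
(c_spherical near 0.86–0.89 together with c_planar near 0.07–0.09).

## Wall coordinates, helix and sheetlet angles

The LV is treated as a near-axisymmetric shell around a long axis pointing
apex→base (the slice-stack normal for axis-aligned data, or the mask's
principal axis for oblique data). Per voxel: `l̂` is the long axis, `r̂`
points from the per-slice mask centroid through the voxel (Gram–Schmidt
orthogonalized against `l̂`), and `ĉ = l̂ × r̂`. Voxels at a slice centroid
have no defined azimuth and are excluded.

Helix angle: `e₁` is projected onto span(ĉ, l̂), its sign flipped so the
circumferential component is non-negative, and
`HA = atan2(p·l̂, p·ĉ) ∈ (−90°, 90°]`. Positive HA means the fiber tilts
toward the base while advancing counterclockwise viewed from the base — the
conventional endo-positive/epi-negative display. Fibers with
`|e₁·r̂| > 0.95` (near-radial, tangent projection unstable) are excluded and
counted rather than imputed: stability is preferred over coverage, and the
count is part of the QC output.

Sheetlet angle: the in-wall cross-fiber direction is `ŵ = normalize(r̂×e₁)`
and the wall-normal within the cross-fiber plane `n̂ = normalize(e₁×ŵ)`;
`|E2A| = atan(|e₂·n̂| / |e₂·ŵ|) ∈ [0°, 90°]`. Published in-house
implementations differ in the exact projection plane; this convention is
documented and validated against the phantom's prescribed sheet elevation,
but may differ from other groups' code in detail.

Transmural depth is `d = dist_endo / (dist_endo + dist_epi)` from per-slice
Euclidean distance transforms of the rasterized endo/epi boundaries (or of
the cavity/outside recovered from the mask alone). Half a pixel is
subtracted from each distance because the anatomical surface lies between
the boundary pixel centers; without this correction wall thickness is
overestimated by about one voxel and the helicity slope is biased. Slices
without a cavity (the apical cap) carry no depth.

Transmural profiles average HA in 10 equal-width depth bins (configurable);
the helicity slope is fitted by OLS on the bin means against the *realized*
mean depth of each bin — not the nominal bin center, since edge bins are
populated off-center and bin-center regression flattens the slope on thin
walls. Slopes are reported in °/mm (using the measured mean wall thickness)
and in ° per % wall thickness; the latter is the thickness-invariant
("normalized helicity") quantity.

## AHA segmentation and mass

Slices whose myocardium encloses a cavity are split into basal/mid/apical
thirds of equal long-axis extent; cavity-free apical slices form segment 17.
Basal and mid rings are divided into six 60° sectors, the apical ring into
four 90° sectors, all referenced to the anterior right-ventricular insertion
azimuth, which must be supplied (the phantom knows its own; on real data
there is no defensible default). Segments advance with increasing
counterclockwise azimuth from that reference. Transmural-profile-based
summaries exclude segment 17. LV mass is voxel count × voxel volume ×
1.05 g/cm³, indexed to tibial length.

## Denoising

The denoiser is a sliding-window local-PCA with a Marchenko–Pastur (MP)
noise threshold: window³ × n_volumes Casorati matrices are
eigen-decomposed, trailing eigenvalues consistent with an MP noise bulk are
suppressed (or, with known σ, eigenvalues below the MP edge
σ²(1+√(N/M))²), and overlapping reconstructions are averaged with
inverse-retained-rank weights. The default window is 5 (125 ≫ 15
measurements). This is a documented member of the local-PCA family rather
than a reimplementation of any specific published overcomplete variant; its
justification here is empirical — on phantoms it reduces RMSE against known
truth by roughly 2.5× at SNR 20 and is transparent (relative RMSE < 1e−6)
on noiseless data.

## The phantom

The synthetic LV is a truncated axisymmetric half-ellipsoid shell: epi
semi-axes (2.1, 2.1, 4.2) mm, endocardial cavity scaled so the basal wall is
1.0 mm and the apical cap equals the basal wall thickness, voxelized at
150 µm isotropic with voxel faces aligned to the base plane (center-aligned
grids systematically overcount a half-slab of the truncation). Acquisition
defaults: 3 b=0 references plus 12 directions at b = 1123 s/mm², directions
laid out by deterministic electrostatic repulsion on the half-sphere (the
true direction scheme of typical preclinical protocols is rarely reported;
any full-rank quasi-uniform scheme serves).

Ground truth per voxel: linear transmural HA ramp from +60° (endo) to −60°
(epi) in normalized depth — a monotone idealization of measured transmural
gradients, not a claim about their exact shape — a constant |E2A| of 30°
(typical diastolic sheet elevation), and the tensor `R diag(λ) Rᵀ` with
eigenvalues (0.95, 0.80, 0.70)×10⁻³ mm²/s. This triple puts the healthy
phantom at FA ≈ 0.15, c_planar ≈ 0.08, c_spherical ≈ 0.86 — inside the
published operating range for fixed murine myocardium and near reported ROC
cutoffs — and is a package convention, since eigenvalue magnitudes for this
preparation are not standardized. Rician noise is applied as
`√((S+n₁)² + n₂²)` with σ = S0/SNR referenced to the mean b=0 myocardial
signal; the SNR definition has to be fixed somewhere, and this is it.

The "disease" preset models atrophic remodeling: wall thickness −25%,
λ₂ −15%, λ₃ −25%. Reduced cross-fiber diffusivity with preserved λ₁ raises
FA and planarity and lowers sphericity by construction; the magnitudes are
free parameters chosen to give a clearly separable but not degenerate
effect. Cohorts add Gaussian between-subject jitter (default 5% CV on wall
thickness and λ₂/λ₃, 3° SD on the ramp endpoints, 0.25 mm SD on tibial
length), with bounded resampling if a draw violates the eigenvalue ordering.

What the phantom does *not* emulate: fixation and susceptibility artifacts,
eddy currents, partial-volume at the blood/tissue interface, crossing or
dispersing fibers, biexponential diffusion, regional wall-thickness
variation, and papillary/trabecular anatomy. Passing tests therefore
demonstrate the correctness of the estimators under the stated forward
model, not robustness to every property of real scans.

## Statistics

Group comparisons use the pooled-variance Student's t-test (two-tailed), the
naming convention of the reports this mirrors; Welch's test is available
behind a flag. Zero-variance degeneracies are resolved deterministically
(equal means → t=0, p=1; unequal → p=0). Per-segment comparisons are
reported without multiplicity adjustment, mirroring exploratory bull's-eye
practice; Benjamini–Hochberg values are emitted alongside and the report
carries a prominent note. ROC AUC is the Mann–Whitney pairwise-ranking
probability with ties counted ½; its CI and the test of AUC = 0.5 use the
DeLong variance (under complete separation the asymptotic variance
collapses and a degenerate CI is reported as such). Optimal cutoffs maximize
the Youden index with ties broken toward higher sensitivity and then the
less extreme threshold, making the output deterministic;
sensitivity/specificity carry Wilson score intervals. Monte-Carlo
calibration tests use a three-standard-error tolerance around nominal
levels.

## Problem sizes and determinism

Validation runs use the default ~33³ phantom grid (≈9000 myocardial voxels),
cohorts of 8 vs 7 subjects at SNR 50, 2000 null simulations for t-test
calibration, 500 cohorts for DeLong coverage and 500 draws for regression
recovery — sizes at which every Monte-Carlo tolerance is comfortably
resolved. All randomness flows from a single master seed; per-subject noise
seeds are drawn deterministically from it, so identical configurations
reproduce reports byte for byte.

## Known limitations

- The tensor model itself is the limitation at crossing-fiber voxels; no
  multi-compartment fitting is attempted.
- The E2A projection convention may differ from specific in-house codes.
- The AHA thirds are defined by equal long-axis extent of cavity-bearing
  slices; other groups anchor thirds to anatomical landmarks.
- DeLong CIs are asymptotic and degenerate under complete separation, which
  small, well-separated cohorts do reach.
- Whether HA histograms should count voxels or tractography streamlines is
  ambiguous in parts of the literature; this package counts voxels.
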