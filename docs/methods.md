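# Methods

This document records the model definitions, parameter defaults, numerical
choices and known limitations of `nhocrad`. Nothing here is an empirical
claim about clinical data; all quantitative statements refer to synthetic
data generated by `nhocrad.synthgen` or to closed-form oracles.

## Image model and conventions

- Volumes are 3-D scalar grids with a physical geometry: shape, voxel
  spacing (mm) and origin. The physical centre of voxel *(i, j, k)* is
  `origin + index × spacing` (node-centred convention).
- NIfTI inputs are reoriented to canonical RAS on load
  (`nibabel.as_closest_canonical`), so axis order is consistent
  package-wide.
- PET volumes must be non-negative and finite (SUV); CT volumes may be
  negative (HU). Masks are binarised at 0.5 with a log message if the
  input was not already binary.
- Resampling uses linear interpolation (`scipy.ndimage.map_coordinates`)
  with output voxel *j* centred at `j × target_spacing`; the default
  extraction grid is 3×3×5 mm, a common PET reconstruction spacing.
- Connectivity is 26-neighbour everywhere a connected component is needed
  (segmentation, size zones), so the package is internally consistent.

## NHOC

`NHOC = HOC / MSR` with

- `HOC` = Euclidean distance (mm) from the SUVmax voxel centre to the
  lesion's geometric (unweighted) centroid. Ties on SUVmax are resolved by
  taking the **minimum** distance over tied voxels (conservative: never
  overstates peripherality); the tie count is reported. An SUV-weighted
  centroid is available behind a flag.
- `MSR = (3 MV / 4π)^{1/3}` where `MV = N × V_v` is the metabolic volume.

Properties verified by tests: exact translation and 90°-rotation
invariance (the metric depends only on relative voxel geometry), recovery
of a programmed hotspot offset fraction on phantoms to ±0.05, and the
closed-form MSR of spherical masks.

## VOI construction

- **Lesion (MTV40):** threshold at 40% of the SUVmax of the seed's
  connected hot region (voxels above the image's median value, used as a
  noise floor), then keep the 26-connected component containing the
  hottest voxel. Lesions below 5 ml are rejected — below that size the
  40% isocontour is dominated by partial-volume effects and NHOC is not
  meaningful.
- **Annuli:** Euclidean distance transform of the lesion complement with
  anisotropic sampling in mm; shell *k* is `(k−1)·t < d ≤ k·t` with
  thickness `t = 10 mm` (one shell by default). Optionally clipped to a
  body/lung mask.
- **Background spheres:** 20 mm diameter, placed either at user-given
  voxel centres or automatically by walking outward from the lesion
  centroid along the 6 axis directions until the centre is
  annulus + 20 mm gap away from the lesion surface and the full sphere
  fits in the grid. Overlap with lesion or annuli raises an error.
- The three label groups are validated to be pairwise disjoint.

## Radiomics

- **Discretisation:** fixed bin count (64) between the VOI minimum and
  maximum. This makes texture features invariant to affine intensity
  rescaling, which suits SUV images whose calibration varies by scanner.
  Fixed bin width is available as an alternative.
- **Texture matrices:** GLCM and GLRLM are computed per direction over the
  13 unique 3-D directions and features averaged; matrices are
  symmetric/normalised. GLSZM zones and NGTDM neighbourhoods use
  26-connectivity. Formulas follow the IBSI definitions.
- **Wavelet:** one-level stationary (undecimated) 3-D transform
  (`pywt.swtn`, `coif1`), so all 8 sub-bands stay on the input grid and
  VOI masks apply unchanged. Odd axes are edge-padded and cropped back.
  Sub-band tags are three letters (L/H) in axis order.
- **LoG:** σ is specified in mm and converted per axis by the voxel
  spacing; second derivatives carry a 1/spacing² factor so the operator is
  the physical Laplacian. Responses are scale-normalised (×σ²). Kernel
  truncation is 8σ so constant regions map to ~0 (≤1e-15). Default scales
  1.5 / 2.5 / 3.5 mm.
- **Fractal dimension:** box counting with dyadic box sizes ε ∈ {1, 2, 4,
  …} anchored at the mask bounding-box corner; FD is the least-squares
  slope of log N(ε) vs log(1/ε). Oracles: filled cube → 3, plane → 2,
  single voxel → 0 (exact for dyadic shapes).
- VOIs with fewer than 8 voxels yield NaN features (flagged, not silently
  dropped). Feature names are
  `<modality>.<voi>.<transform>.<family>.<feature>`.

## Harmonisation and filtering cascade

Order: ComBat → ICC filter → correlation pruning → univariable Cox screen
→ z-scoring. Rationale: harmonise before any statistic that pools sites;
drop non-reproducible features before model-relevant selection; prune
redundancy before the multiplicity-corrected screen so the FDR correction
is not diluted by near-duplicates.

- **ComBat:** parametric empirical-Bayes location/scale harmonisation,
  implemented in-package (features × samples, standardise, iterate the
  γ*/δ* moment equations). A single batch is the identity; a batch with
  one sample raises (its variance is undefined).
- **ICC(2,1):** two-way random effects, absolute agreement, single rater,
  computed from ANOVA mean squares; features with ICC < 0.8 on a
  test–retest table are dropped. Requires ≥ 3 shared patients. Verified
  against `pingouin.intraclass_corr` (ICC(A,1)) in tests.
- **Pruning:** among pairs with |Pearson r| > 0.9, the lower-variance
  member is dropped, processing pairs in decreasing |r| (lexicographic
  tie-break) — deterministic.
- **Screen:** per-feature univariable Cox (lifelines, Efron ties), Wald
  p-values corrected by Benjamini–Hochberg; retain q ≤ 0.01. Requires
  ≥ 10 events; non-converging features are excluded and logged.
- **Z-scoring:** population SD (ddof = 0) estimated on the training set
  only; parameters serialized and re-applied to validation/external data.
  Zero-variance columns are dropped.

## Signatures and evaluation

- **RPV:** elastic-net Cox (`sksurv.CoxnetSurvivalAnalysis`), mixing
  α = 0.5 by default; λ by 5-fold cross-validation maximising the held-out
  Breslow partial likelihood (full-cohort minus train-fold difference),
  with a deterministic seeded fold split. An all-zero solution raises
  rather than silently returning a constant signature.
- **nLCEV / SMM:** unpenalised multivariable Cox (lifelines). Per-covariate
  HRs with 95% CIs and Wald p-values are stored with the signature. A
  condition-number guard (> 1e8) rejects collinear inputs, naming the
  worst pair.
- **Stratification:** 1-D two-cluster k-means on training scores, centres
  initialised at the 25th/75th percentiles, Lloyd iterations to
  convergence — fully deterministic. High risk = larger centre; new
  patients are assigned by the midpoint decision boundary.
- **Evaluation:** Kaplan–Meier curves with Greenwood CIs, two-group
  log-rank test, hazard ratio of the high-risk indicator (NaN with a
  warning when a group has zero events), and ROC AUC for death by 3 years
  (1095 days). Patients censored before the horizon carry no 3-year label
  and are excluded; their count is reported. Ties get half credit
  (Mann–Whitney convention).
- **Leakage control:** external scoring reads only serialized JSON
  artefacts (coefficients, standardisation parameters, cluster centres);
  a test perturbs validation data and asserts the artefacts are
  byte-identical after scoring.

## Synthetic data: scope and limits

- **Phantoms:** ellipsoidal lesion (default radius 15 mm) with a plateau
  SUV 5 on a 0.5 background, plus a Gaussian hotspot (peak 10, σ 4 mm)
  displaced along +x by a programmed fraction of the lesion radius and
  confined to the lesion. Because 0.4 × peak < plateau, MTV40 recovers
  the full ellipsoid and the measured NHOC approximates the programmed
  fraction. Optional additive Gaussian noise. This is a geometric test
  object, not a realistic PET simulation (no PSF, no Poisson noise, no
  respiratory blur).
- **Cohorts:** exponential proportional-hazards survival over centred
  covariates (NHOC ~ Beta(2,3), a latent risk factor, stage 1–4), default
  log-hazard coefficients (0.8, 1.0, 0.5) and baseline rate 1/600 days.
  Censoring is uniform on (0, u) with u calibrated analytically
  (`P(censored | λ) = (1 − e^{−λu})/(λu)` averaged over patients, solved
  by Brent's method) to hit a target censoring fraction. Informative
  features mix the latent factor with noise; optional per-site batch
  shifts/scales exercise ComBat. The generator encodes proportional
  hazards by construction, so it cannot probe PH violations.

## Parameter defaults

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| MTV threshold | 0.40 × SUVmax | — | standard MTV40 definition |
| Minimum lesion volume | 5 | ml | partial-volume reliability floor |
| Annulus thickness | 10 | mm | 1-cm peri-tumoural shell |
| Background sphere diameter | 20 | mm | 2-cm background sample |
| Sphere–lesion gap | 20 | mm | avoids spill-over uptake |
| Discretisation | 64 bins | — | affine-invariant, common IBSI choice |
| LoG scales | 1.5, 2.5, 3.5 | mm | fine-to-coarse around PET resolution |
| Resample spacing | 3×3×5 | mm | typical PET grid |
| ICC threshold | 0.8 | — | conventional "good reliability" cut |
| Correlation prune | \|r\| > 0.9 | — | near-duplicate removal |
| Screen FDR | q ≤ 0.01 | — | strict screen before penalised fit |
| Elastic-net mixing α | 0.5 | — | balanced sparsity/grouping |
| Survival horizon | 1095 | days | 3-year overall survival |

## Open design decisions

- The hotspot tie rule (minimum distance) is one of several defensible
  conventions; the tie count is always reported so users can detect when
  it matters.
- GLCM/GLRLM direction averaging (rather than merging matrices before
  feature computation) follows the commoner IBSI aggregation; both are
  defensible.
- The CV criterion for λ (held-out partial-likelihood difference) follows
  the Verweij–van Houwelingen construction; deviance-based criteria give
  similar selections.

## Limitations

- No PET physics in the phantoms (see above); NHOC recovery tolerances on
  real images will be wider.
- ComBat assumes the parametric (normal/inverse-gamma) prior forms; the
  non-parametric variant is not implemented.
- The Cox screen and composites assume proportional hazards; no PH
  diagnostics are included.
- Shape features use marching-cubes surfaces on binary masks, which
  slightly overestimates sphericity at coarse spacing.
- The pipeline expects complete cases; there is no missing-data handling
  beyond explicit NaN propagation for undersized VOIs.
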