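# Methods

`adctex` implements a quantitative analysis chain for apparent diffusion
coefficient (ADC) maps of patients with a single brain metastasis: region
derivation, per-subject ADC standardization, decomposition of the
peritumoral edema into distance shells, a 30-parameter imaging feature set,
and a survival-modelling stage that tests whether imaging features improve
established clinical risk scores (DS-GPA, RPA).  Because no patient data
ship with the package, a synthetic phantom/cohort generator with known
ground truth drives every test.

## Regions of interest and CSF exclusion

Inputs per subject are a 3D ADC map (units 10⁻³ mm²/s, physical voxel
spacing from the NIfTI header) and co-registered binary masks:
contrast-enhancing tumor (CE), necrosis, peritumoral T2-hyperintense zone
(T2PZ), gray matter, white matter, CSF.  Three analysis compartments are
derived:

* **CE** — the enhancing mask minus necrotic voxels;
* **T2PZ** — the edema mask minus CE and necrosis (enforced at mask
  construction, so `CE ∩ T2PZ = ∅` always holds);
* **GMWMC** — `(GM ∪ WM) \ (CE ∪ necrosis ∪ T2PZ ∪ CSF)`, the tumor- and
  edema-free brain used as the "healthy" reference.

Each subject gets an individual CSF-contamination threshold: mean minus two
standard deviations of the ADC over their CSF mask (sample SD by default,
population SD selectable).  ROI voxels with ADC at or above that threshold
are excluded before any statistic is computed.  The phrase "outside a
threshold of mean CSF ADC of 2 SD" admits a literal two-sided reading
(exclude voxels outside `[mean − 2SD, mean + 2SD]`); that mode exists as a
config switch but retains only CSF-like voxels and is not the default,
because the stated purpose of the filter is to remove CSF partial-volume
contamination from tumor/edema ROIs.  The filter is applied to all three
compartments by default (`apply_exclusion_to_gmwmc=False` restricts it to
CE and T2PZ).

## Normalization

To standardize across scanners, every CE/T2PZ/ring voxel value is divided
by the subject's mean GMWMC ADC, giving dimensionless ratios.  The GMWMC's
own summary features cannot be normalized by themselves (the ratio would be
identically 1), so they are referenced to the subject's mean CSF ADC —
another within-subject, scanner-free denominator.  A config alternative
reports raw GMWMC ADC instead.  All normalized and texture features are
invariant under global rescaling of the ADC volume (verified to 1e-10 in
the acceptance suite); only the raw-scale ADC slope scales with the volume.

## Peritumoral rings and the ADC slope

The T2PZ is split into three adjacent 3-mm shells by Euclidean distance
from the tumor surface, computed in physical millimetres with anisotropic
spacing honoured.  "Surface" is taken literally: distances are measured to
the 0.5 iso-surface of the binary CE∪necrosis mask (marching cubes),
the standard sub-voxel surface running midway between inside and outside
voxel centers.  Distance to the nearest CE voxel *center* would
systematically overstate surface distance by roughly half a voxel (ring-1
volume error ≈ −9% on a 6/15-mm spherical phantom), while distance to the
union of solid voxel cubes understates it because jagged corner
protrusions dominate the minimum (+28%); the iso-surface estimate brings
all three ring volumes within 5% of the analytic shell volumes with no
tunable constant.

Ring r covers distances in the half-open interval `(3(r−1), 3r]` mm, so
boundary voxels belong to the inner ring.  Edema farther than 9 mm from
the surface is folded into ring 3 by default (config flag to discard
instead), so ring statistics cover the whole edema.  The **ADC slope** is
the ordinary-least-squares slope of the ring mean ADCs against the ring
centers (1.5, 4.5, 7.5 mm), restricted to non-empty rings; positive slope
means ADC rises outward from the tumor.  With fewer than two non-empty
rings the slope is reported missing.  The two-point alternative
(outer minus inner mean over 6 mm) is exposed alongside.  The slope is
computed on raw ADC by default; a normalized variant is available since
either convention is defensible.

## The 30-parameter feature set

The registry (`feature_registry.yaml`, the single source of truth) holds:

* 12 first-order features — normalized mean and normalized 5th-percentile
  ADC in CE, whole T2PZ, rings 1–3, and GMWMC;
* 2 volumetric features — CE volume and T2PZ volume in cm³ (geometric:
  computed from the masks before CSF exclusion; CE volume excludes the
  necrotic core);
* 1 ADC slope;
* 2 distribution-shape features — 3D skewness `m₃/m₂^{3/2}` and 3D excess
  kurtosis `m₄/m₂² − 3` of the normalized T2PZ values (biased moment
  estimators; Pearson kurtosis selectable);
* 13 direction-averaged gray-level co-occurrence (Haralick) features of the
  T2PZ: angular second moment, contrast, correlation, sum-of-squares
  variance, inverse difference moment, sum average, sum variance, sum
  entropy, entropy, difference variance, difference entropy, and the two
  information measures of correlation.

GLCM construction: ROI values are min–max quantized into 64 gray levels
(linear binning, top edge closed), co-occurrences are counted at voxel
distance 1 along the 13 unique 3D directions, accumulated symmetrically,
and normalized per direction; each Haralick statistic is averaged over the
directions with at least one voxel pair.  Natural logarithms with
`0·log 0 = 0`; sum variance is centred on the sum average.  These
construction choices are documented package conventions (level count,
distance, symmetry, log base are all configurable), not facts inherited
from any particular clinical software.  Degenerate regions (empty after
exclusion, constant-valued) yield missing values with a recorded reason;
the vector always carries all 30 names.  Quantization depends on the data
only through the ROI min–max and ordering, which is what makes the texture
features scale-invariant.

## Survival stage

* **Kaplan–Meier / log-rank** (via `lifelines`): product-limit curves,
  median OS with Greenwood-based 95% CI, and the standard
  observed-minus-expected log-rank χ² across group levels.
* **Linear backward screening**: OLS of log overall survival on all
  candidate imaging features, *deceased subjects only*; the feature with
  the largest p-value ≥ α_remove is dropped and the model refit until all
  remaining p < α_remove.  α_remove defaults to 0.10 (0.05 and the
  AIC-equivalent 0.157 are the natural alternatives; all thresholds are
  arguments).  Constant, incomplete or collinear columns are removed up
  front with warnings.  When candidates outnumber deaths an optional
  univariate pre-screen (drop p > 0.5) guards the fit; the end-to-end
  pipeline enables it because its 40-subject demo is in exactly that
  regime.
* **Cox augmentation** (via `statsmodels` PHReg; Efron ties by default,
  Breslow selectable): the clinical score enters as indicator variables
  against the best-prognosis reference (DS-GPA group III, RPA class I) and
  is protected — it is the model being augmented; only imaging features are
  eliminated, by Wald p ≥ α_remove.  Covariates are standardized internally
  for fitting and coefficients mapped back, which the partial likelihood
  permits exactly.  A candidate on which the likelihood diverges
  (separation/collinearity) is unidentifiable and is eliminated with a
  warning recorded in the trace; divergence on a protected column raises.
* **AIC comparison**: `AIC = −2ℓ + 2k` on the partial likelihood; models
  are compared only on identical subject sets (enforced), and DS-GPA and
  RPA are augmented in separate models.

Missing clinical categories are handled complete-case with a warning; no
imputation, no proportional-hazards diagnostics, no time-varying
covariates.

## Synthetic data

The phantom is deliberately the simplest geometry with closed-form ROI
volumes: a cuboid brain (white matter plus a gray-matter slab), a planar
CSF slab and an ellipsoidal ventricle, and a concentric
necrosis ⊂ CE ⊂ T2PZ sphere complex centred in the white matter.
Compartment ADC values are i.i.d. normal truncated at zero with defaults
WM 0.75, GM 0.85, CSF 3.0, CE 1.0, necrosis 2.0, T2PZ 1.4 (×10⁻³ mm²/s,
SDs 0.05–0.15).  **These defaults are stand-ins chosen from textbook
ranges** — no distributional description of a clinical cohort's
compartment ADC exists to copy — and are fully overridable.  The CE radius
must exceed 5 mm, honouring the intended use on metastases larger than
1 cm diameter.  An optional linear radial gradient across the T2PZ gives
the ring/slope stage an exact ground truth.

Survival is linked to imaging through a proportional-hazards model with an
exponential baseline (one rate, default 1/12 per month — median OS near
8 months for a null subject, in the range reported for brain-metastasis
cohorts): subject hazard is `λ·exp(Σ βᵢ zᵢ)` with zᵢ the cohort-standardized
feature values, so the βs are per-SD log-hazard effects.  Censoring is
independent exponential with rate set so a null subject is censored with
the target probability (default 0.2).  Clinical scores are sampled from
configurable category probabilities, independent of imaging — adequate for
testing the modelling machinery, though real scores correlate with outcome.

Two cohort modes exist: the image-backed generator (phantom per subject,
features computed from the voxels; used by the 40-subject demo at 64³) and
a feature-level simulator that draws standard-normal feature scores
directly and reuses the same hazard linkage.  The statistical simulations
(CI coverage, selection calibration, AIC behaviour; 50 replicates at
n = 150–300) use the feature-level mode — the estimator properties under
test depend on the feature–survival joint law, not on how feature values
arose — keeping the whole suite within minutes on one CPU.

What the phantom does *not* emulate: realistic anatomy, registration
error, scanner noise fields, partial-volume mixtures at compartment
boundaries, spatially correlated texture within compartments, or
correlation between clinical scores and imaging.  Passing tests therefore
demonstrate that the machinery computes what it claims and recovers known
effects under its generative model — not that the clinical effect sizes of
any particular cohort are reproduced.

## Numerical choices and limitations

* 5th percentiles use linear interpolation between order statistics.
* Quantization bins are half-open with the top edge closed; a constant ROI
  is a quantization error, reported as missing texture features.
* Ring intervals are half-open `(lo, hi]`; ties at a ring boundary go
  inward.
* Wald 95% CIs use Φ⁻¹(0.975); HR CIs are `exp(β ± 1.96·se)`.
* Determinism: every stochastic component takes a seed; one seed fixes the
  whole cohort (volumes, masks, survival, tables), and the feature CSV is
  byte-reproducible across reruns.
* The backward-selection procedures inherit the usual caveats of stepwise
  regression (post-selection inference is not corrected); the AIC
  comparison is between the final fitted models only.
* NIfTI volumes are written as float32; reading them back reproduces the
  float32 values exactly.
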