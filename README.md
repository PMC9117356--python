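# adctex

Quantitative ADC-map analysis for single brain metastases: compartment ROI
derivation, per-subject ADC normalization, peritumoral ring decomposition,
a 30-parameter textural feature set, and survival-model augmentation of
clinical risk scores — with a synthetic phantom/cohort generator so the
whole chain is testable without patient data.

## The problem

Clinical risk scores for brain-metastasis patients (DS-GPA, RPA) use only
clinical variables.  Diffusion-weighted MRI yields quantitative apparent
diffusion coefficient (ADC) maps whose texture carries information about
tumor and peritumoral tissue micro-structure.  This package implements the
full analysis needed to ask whether ADC-derived imaging features add
prognostic value to those scores:

1. **Regions.** From co-registered masks: contrast-enhancing tumor (CE,
   necrosis excluded), peritumoral T2-hyperintense zone (T2PZ, enhancing
   and necrotic voxels excluded), and the tumor- and edema-free gray+white
   matter compartment (GMWMC).  A per-subject threshold — mean CSF ADC
   minus 2 SD — removes CSF-contaminated voxels from the ROIs.
2. **Normalization.** Voxel ratios against the GMWMC mean ADC standardize
   values across scanners; GMWMC's own features are referenced to the
   subject's CSF mean.
3. **Rings.** The T2PZ is split into three adjacent 3-mm shells by
   Euclidean distance from the tumor surface; the *ADC slope* is the OLS
   slope of the ring mean ADCs against the ring centers (1.5/4.5/7.5 mm).
4. **Features.** Exactly 30 parameters per subject: 12 normalized
   first-order values, 2 volumes (cm³), the slope, 3D skewness/kurtosis of
   the T2PZ, and 13 direction-averaged 3D gray-level co-occurrence
   (Haralick) features (64 levels, distance 1, 13 directions, natural log).
5. **Survival.** Kaplan–Meier and log-rank; backward-eliminated OLS of
   log(OS) on the features (deceased subjects); Cox proportional-hazards
   augmentation of a protected clinical score by backward-selected imaging
   features (Efron ties); model comparison by AIC = −2ℓ + 2k.

See `docs/methods.md` for the model details, conventions, and what the
synthetic generator does and does not emulate.

## A worked example

```python
import adctex as at

adc, masks = at.generate_phantom(at.PhantomConfig(seed=7))
fv = at.extract_features(adc, masks, subject_id="demo")
print(fv.values["norm_mean_adc_t2pz"], fv.values["adc_slope"])
```

```
1.8489596234881285 -0.00022202252646947622
```

The peritumoral zone's mean ADC is 1.85× the healthy-brain reference —
vasogenic edema diffuses more freely — and the ring profile is essentially
flat (slope ≈ −0.0002 ×10⁻³ mm²/s per mm) because this phantom has no
radial gradient.  Running the survival stage on a simulated cohort with
two planted per-SD log-hazard effects (+0.5, −0.5) among six noise
features (`python examples/04_survival_models.py`) prints:

```
linear backward selection kept: ['feat_a', 'feat_b']
Cox backward selection kept:    ['feat_a', 'feat_b']
                 coef     HR  HR_lower95  HR_upper95      p
feat_a          0.576  1.779       1.532       2.065  0.000
feat_b         -0.408  0.665       0.576       0.768  0.000
DS-GPA + imaging  AIC 2074.96   (best)
DS-GPA only       AIC 2145.45
```

Both planted effects are recovered with hazard ratios bracketing the truth
(e^0.5 ≈ 1.65, e^−0.5 ≈ 0.61), and adding them lowers the AIC of the
clinical-score model — the augmentation helped.

The `examples/` directory has one short script per capability (phantom and
ROIs, rings and slope, the feature vector, survival models, the full
pipeline); each prints what it computes and what the numbers mean.  A thin
CLI mirrors the pipeline for shell use:

```bash
adctex simulate --out cohort/ --seed 1 --n 40
adctex extract  --adc cohort/images/S0000_adc.nii.gz \
                --masks cohort/images/S0000_masks.nii.gz --out features.csv
adctex model    --features features.csv --clinical cohort/clinical.csv \
                --score both --out report.json
adctex run-all  --out demo/ --seed 1
```

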