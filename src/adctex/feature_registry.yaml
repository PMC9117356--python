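# The 30-parameter imaging feature registry — single source of truth.
# Order matters: it fixes the column order of every feature table.
#
# 12 first-order features: normalized mean ADC and normalized 5th-percentile
#    ADC in the contrast-enhancing region, the whole peritumoral zone, each of
#    its three 3-mm rings, and the tumor-free gray+white matter compartment.
# 2  volumetric features (cm^3).
# 1  ADC slope across the three rings (1e-3 mm^2/s per mm, raw ADC scale).
# 2  distribution-shape features of the normalized peritumoral ADC values.
# 13 direction-averaged 3D gray-level co-occurrence (Haralick) features of
#    the peritumoral ADC texture.
features:
  - norm_mean_adc_ce
  - norm_p5_adc_ce
  - norm_mean_adc_t2pz
  - norm_p5_adc_t2pz
  - norm_mean_adc_ring1
  - norm_p5_adc_ring1
  - norm_mean_adc_ring2
  - norm_p5_adc_ring2
  - norm_mean_adc_ring3
  - norm_p5_adc_ring3
  - norm_mean_adc_gmwmc
  - norm_p5_adc_gmwmc
  - volume_ce_cm3
  - volume_t2pz_cm3
  - adc_slope
  - skewness_3d_t2pz
  - kurtosis_3d_t2pz
  - glcm_mean_asm
  - glcm_mean_contrast
  - glcm_mean_correlation
  - glcm_mean_variance
  - glcm_mean_idm
  - glcm_mean_sum_average
  - glcm_mean_sum_variance
  - glcm_mean_sum_entropy
  - glcm_mean_entropy
  - glcm_mean_difference_variance
  - glcm_mean_difference_entropy
  - glcm_mean_imc1
  - glcm_mean_imc2
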