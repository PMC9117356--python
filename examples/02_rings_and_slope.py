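"""Decompose the peritumoral zone into 3-mm rings and recover an ADC slope.

A zero-noise phantom with a configured radial gradient of 0.05 (x1e-3
mm^2/s per mm) across the edema shows how the ring means rise with
distance from the tumor surface and how the fitted slope recovers the
ground truth.
"""

import adctex as at

zero_noise = {k: at.CompartmentAdc(v[0], 0.0)
              for k, v in at.synthetic.DEFAULT_ADC.items()}
g = 0.05
adc, masks = at.generate_phantom(
    at.PhantomConfig(adc=zero_noise, t2pz_gradient=g, seed=0)
)
rings = at.ring_partition(masks, adc.spacing)
vals = adc.values[rings.indices[:, 0], rings.indices[:, 1], rings.indices[:, 2]]
profile = at.ring_means_and_slope(vals, rings)

print("ring  center(mm)  voxels   mean ADC")
for r in range(3):
    print(f"  {r + 1}       {profile.center_distances[r]:.1f}    "
          f"{profile.counts[r]:6d}     {profile.means[r]:.4f}")
print(f"\nfitted ADC slope: {profile.slope:.4f} per mm (true gradient {g})")
print("positive slope = ADC increases outward from the tumor surface")
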