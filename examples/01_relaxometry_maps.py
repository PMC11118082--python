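"""Pixelwise T2 / T2* / T1 mapping on a noiseless phantom.

Builds the default two-region glioma phantom, simulates the multi-echo
spin-echo (75 TEs, 12-900 ms), multi-gradient-echo (20 TEs, 2.73-83.86 ms)
and saturation-recovery (8 TRs, 125-6000 ms) stacks, fits the
mono-exponential models per pixel and prints the ROI means.  On noiseless
input every ROI mean equals the region's ground-truth relaxation time.
"""

import numpy as np

from mparamap import phantom, relaxometry

gt = phantom.make_phantom(phantom.default_phantom_spec())
tumor = gt.region_mask("tumor")
contra = gt.region_mask("contralateral")

for model, simulate, name in [
    ("mse", phantom.simulate_mse, "T2"),
    ("mge", phantom.simulate_mge, "T2*"),
    ("satrec", phantom.simulate_satrec, "T1"),
]:
    series = simulate(gt)
    pmap = relaxometry.fit_map(series, model, gt.mask)
    print(f"{name:4s} tumor ROI mean = {np.nanmean(pmap.values[tumor]):8.2f} ms, "
          f"contralateral = {np.nanmean(pmap.values[contra]):8.2f} ms")

print("\nTumor relaxation times exceed contralateral for T2 and T1 "
      "(edema, necrosis, BBB disruption); T2* is similar in both regions.")
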