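"""Diffusion-tensor fit with MD and FA maps.

Simulates the 15-volume scheme (1 b=0 + 7 directions x b in {300, 1400}
s/mm^2), solves the log-linear Stejskal-Tanner model per pixel, and reports
mean diffusivity (average eigenvalue, um^2/s) and fractional anisotropy
(normalized eigenvalue dispersion) over each ROI.
"""

import numpy as np

from mparamap import dti, phantom

gt = phantom.make_phantom(phantom.default_phantom_spec())
scheme = dti.default_scheme()
series = phantom.simulate_dwi(gt, scheme)
field = dti.fit_tensor(series, scheme, gt.mask)

md = dti.mean_diffusivity(field)
fa = dti.fractional_anisotropy(field)
for region in ("tumor", "contralateral"):
    m = gt.region_mask(region)
    print(f"{region:14s} MD = {np.nanmean(md.values[m]):7.1f} um^2/s, "
          f"FA = {np.nanmean(fa.values[m]):.3f}")
print(f"eigenvalues clamped at zero: {field.n_clamped}")

print("\nElevated tumor MD indicates vasogenic edema/necrosis outweighing "
      "hypercellularity; FA is similar across regions.")
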