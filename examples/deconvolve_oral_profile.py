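"""Loo-Riegelman deconvolution of an oral plasma profile.

Simulates an oral dose with known first-order absorption, deconvolves the
plasma curve back into a fraction-absorbed curve, and reconvolves it to
verify the round trip.
"""

import numpy as np

from saltivivc import loo_riegelman, reconvolve, simulate_oral
from saltivivc.datasets import DKT_DISPOSITION

params = DKT_DISPOSITION
ka, absorbed_ug = 1.5, 22_500.0  # first-order absorption, ~28 min half-time

times = np.arange(0.0, 12.0001, 1.0 / 6.0)  # 10-min sampling
xa = absorbed_ug * (1 - np.exp(-ka * times))
rates = np.diff(xa) / np.diff(times)
plasma = simulate_oral(params, times, rates, time_unit="h", label="oral")

fa = loo_riegelman(plasma, params)
truth = (1 - np.exp(-ka * times)) / (1 - np.exp(-ka * times[-1]))
print("t [h]   C [ug/mL]   Fa (deconvolved)   Fa (true)")
for i in range(0, len(times), 6):
    print(f"{times[i]:5.1f}   {plasma.concentrations[i]:9.3f}   "
          f"{fa.fractions[i]:16.4f}   {truth[i]:9.4f}")

recon = reconvolve(fa, params, fa.metadata["plateau_over_v1"])
rc = np.interp(times, recon.times, recon.concentrations)
mask = plasma.concentrations > 0
worst = np.max(np.abs(rc[mask] - plasma.concentrations[mask])
               / plasma.concentrations[mask])
print(f"\nmax absolute Fa error: "
      f"{np.max(np.abs(fa.fractions - truth)):.4f}")
print(f"worst round-trip deviation (reconvolved vs input): {100 * worst:.2f}%")

# The deconvolved curve tracks the true fraction absorbed to within ~0.01
# and reconvolution reproduces the plasma profile to within ~1%: the
# deconvolution step is numerically invertible at this sampling density.
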