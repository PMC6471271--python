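"""Fit the two-compartment disposition model to a noisy intravenous dataset.

Generates a synthetic IV bolus profile (5% multiplicative assay noise) from
the published disposition constants and recovers them by nonlinear least
squares with curve-stripping initial estimates.
"""

import numpy as np

from saltivivc import fit_two_compartment, generate_iv_dataset, hybrid_constants
from saltivivc.datasets import DKT_DISPOSITION
from saltivivc.synthetic import StudySpec

times_h = np.array([0.083, 0.167, 0.25, 0.5, 0.75, 1, 1.5, 2, 3, 4, 6, 8, 12.0])
dose_ug = 25_000.0

iv = generate_iv_dataset(StudySpec(seed=42, noise_cv=0.05), dose_ug, times_h)
fit = fit_two_compartment(iv, dose_ug)

print("parameter      true      fitted        SE       CV%")
for name in ("v1", "k10", "k12", "k21"):
    print(f"{name:>6} {getattr(DKT_DISPOSITION, name):12.4g} "
          f"{getattr(fit.params, name):10.4g} {fit.se[name]:10.3g} "
          f"{fit.cv_pct[name]:8.2f}")

alpha, beta = hybrid_constants(fit.params)
print(f"\nhybrid constants: alpha = {alpha:.3f} /h, beta = {beta:.3f} /h")

# V1 and k10 are recovered tightly (CV% a few percent); the distribution
# constants k12/k21 carry larger uncertainty, as is typical when only the
# central compartment is observed.
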