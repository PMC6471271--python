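"""Packaged reference constants for the dexketoprofen trometamol (DKT) system.

These are the published physicochemical and pharmacokinetic constants for
dexketoprofen (DK, a lipophilic weak acid, pK_a 4.02 at 37 °C) and its 1:1
trometamol salt, used as package defaults and as fixtures in the examples:

* the salt system (Ksp, intrinsic acid solubility S0, both pK_a values),
* the two-compartment disposition parameters fitted to intravenous data,
* the reported experimental/predicted exposure metrics of the three tablet
  formulations (reference, a bioequivalent and a non-bioequivalent generic),
* the microscopy well conditions (high/low salt loads in 300 µL of pH 2
  medium) used for the saturation-state checks.
"""

from __future__ import annotations

from dataclasses import dataclass

from .pk import DispositionParams
from .salt_chemistry import SaltSystem

__all__ = [
    "DKT_SYSTEM",
    "DKT_DISPOSITION",
    "DKT_DISPOSITION_TABLE",
    "REPORTED_EXPOSURE_METRICS",
    "MicroscopyConditions",
    "MICROSCOPY",
    "MW_SALT",
    "MW_ACID",
    "TABLET_DOSE_SALT_UG",
]

#: Molar mass of the trometamol salt [g/mol] (dexketoprofen 254.28 + trometamol 121.14).
MW_SALT = 375.42
#: Molar mass of dexketoprofen free acid [g/mol].
MW_ACID = 254.28
#: Label claim per tablet: 36.9 mg DKT salt (25 mg dexketoprofen), in µg.
TABLET_DOSE_SALT_UG = 36_900.0

#: DKT salt system: Ksp 4.96e-1 M², S0 1.36e-3 M, pK_a(DK) 4.02, pK_a(trometamol) 8.1.
DKT_SYSTEM = SaltSystem(ksp=4.96e-1, s0=1.36e-3, pka_acid=4.02, pka_counterion=8.1)

#: Two-compartment disposition of DKT fitted to IV data (V1 mL, rates 1/h).
DKT_DISPOSITION = DispositionParams(v1=3549.53, k10=1.64, k12=0.93, k21=0.96)

#: Published estimate / standard error / CV% per disposition parameter.
DKT_DISPOSITION_TABLE = {
    "v1": {"value": 3549.53, "se": 201.23, "cv_pct": 5.67},
    "k10": {"value": 1.64, "se": 0.08, "cv_pct": 5.14},
    "k12": {"value": 0.93, "se": 0.13, "cv_pct": 14.34},
    "k21": {"value": 0.96, "se": 0.09, "cv_pct": 8.91},
}

#: Reported experimental and IVIVC-predicted Cmax / AUC per formulation.
#: Units are carried as printed ("ng/L", "ng/L*h") and treated as opaque tags;
#: only the dimensionless relative errors are ever recomputed from them.
REPORTED_EXPOSURE_METRICS = {
    "reference": {
        "cmax_exp": 2430.6, "cmax_pred": 2576.3,
        "auc_exp": 2497.3, "auc_pred": 2520.0,
    },
    "non_be": {
        "cmax_exp": 3177.3, "cmax_pred": 3062.5,
        "auc_exp": 2785.7, "auc_pred": 2739.0,
    },
    "be": {
        "cmax_exp": 2478.5, "cmax_pred": 2491.9,
        "auc_exp": 2626.0, "auc_pred": 2538.0,
    },
}

#: Reported per-metric averages of the absolute relative prediction errors [%].
REPORTED_AVERAGE_ABS_RE = {"cmax": 3.38, "auc": 1.98}


@dataclass(frozen=True)
class MicroscopyConditions:
    """Salt loads of the in-situ dissolution microscopy wells.

    ``high_ug``/``low_ug`` are the salt masses added to a ``well_volume_uL``
    aliquot of pH 2 medium; ``low_molar`` is the resulting total drug
    concentration at the low (dose-equivalent) load.
    """

    high_ug: float = 685.0
    low_ug: float = 38.0
    well_volume_uL: float = 300.0
    low_molar: float = 4.3e-4
    high_molar: float = 7.7e-3
    ph: float = 2.0

    @property
    def concentration_ratio(self) -> float:
        """Ratio of the high to the low well concentration (same volume)."""
        return self.high_ug / self.low_ug


MICROSCOPY = MicroscopyConditions()
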