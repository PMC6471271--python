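"""Solubility-pH relationships for a 1:1 salt of a weak acid with a basic counterion.

The model covers the classical solution equilibria of a weakly acidic drug
HA (pK_a,acid) formulated as a 1:1 salt with a protonatable base BH+
(pK_a,counterion), e.g. dexketoprofen trometamol:

* salt solubility   S_salt(pH) = sqrt(Ksp · (1 + 10^(pKa,acid − pH)) · (1 + 10^(pH − pKa,counterion)))
* acid solubility   S_acid(pH) = S0 · (1 + 10^(pH − pKa,acid))
* pH_max            pH at which the two curves intersect:
                    pH_max = pKa,acid + log10(sqrt(Ksp)/S0)

Below pH_max the salt is the more soluble phase and dissolving salt can
supersaturate the solution with respect to the free acid (the driving force
for disproportionation); at and above pH_max the salt is thermodynamically
stable. Ideal-solution behaviour is assumed throughout (no activity
corrections, no common-ion terms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SaltSystem",
    "PhaseClassification",
    "PhaseState",
    "ksp_from_salt_solubility",
    "salt_solubility",
    "acid_solubility",
    "ph_max",
    "supersaturation_ratio",
    "phase_state",
]


@dataclass(frozen=True)
class SaltSystem:
    """Physicochemical constants of a 1:1 weak-acid/basic-counterion salt.

    Parameters
    ----------
    ksp : float
        Salt solubility product [M^2].
    s0 : float
        Intrinsic (un-ionized) free-acid solubility [M].
    pka_acid : float
        pK_a of the acidic drug.
    pka_counterion : float
        pK_a of the protonated counterion (must exceed ``pka_acid``).
    """

    ksp: float
    s0: float
    pka_acid: float
    pka_counterion: float

    def __post_init__(self) -> None:
        if self.ksp <= 0:
            raise ValueError("ksp must be positive")
        if self.s0 <= 0:
            raise ValueError("s0 must be positive")
        if not self.pka_acid < self.pka_counterion:
            raise ValueError("pka_acid must be below pka_counterion")
        if math.sqrt(self.ksp) <= self.s0:
            raise ValueError(
                "sqrt(ksp) must exceed s0 for a pH_max above pka_acid to exist"
            )


class PhaseClassification(str, Enum):
    UNDERSATURATED = "undersaturated"
    SUPERSATURATED_VS_ACID = "supersaturated_vs_acid"
    SUPERSATURATED_VS_BOTH = "supersaturated_vs_both"


@dataclass(frozen=True)
class PhaseState:
    """Saturation state of a solution of total drug concentration c_total.

    ``sigma_acid`` and ``sigma_salt`` are the ratios of the total dissolved
    concentration to the free-acid and salt solubilities at the given pH;
    either ratio above 1 means the corresponding solid can precipitate.
    """

    sigma_acid: float
    sigma_salt: float
    classification: PhaseClassification


def _check_ph(ph: float) -> None:
    if not 0 < ph < 14:
        raise ValueError(f"pH must lie in (0, 14), got {ph}")


def ksp_from_salt_solubility(
    s_salt: float,
    *,
    ph: float | None = None,
    pka_acid: float | None = None,
    pka_counterion: float | None = None,
) -> float:
    """Estimate Ksp from a single measured salt solubility (1:1 stoichiometry).

    The default estimator squares the measured solubility: at salt saturation
    the two ions are equimolar, so Ksp = [A−][BH+] = S_salt², with no
    ionization correction. Supplying ``ph`` together with both pK_a values
    applies the ionization-corrected estimator
    Ksp = S_salt² · f_A(pH) · f_BH(pH), where f_A and f_BH are the ionized
    fractions of drug and counterion; it is not the default.
    """
    if s_salt <= 0:
        raise ValueError("salt solubility must be positive")
    if ph is None:
        return s_salt * s_salt
    if pka_acid is None or pka_counterion is None:
        raise ValueError("the corrected estimator needs ph, pka_acid and pka_counterion")
    _check_ph(ph)
    f_acid = 1.0 / (1.0 + 10.0 ** (pka_acid - ph))
    f_base = 1.0 / (1.0 + 10.0 ** (ph - pka_counterion))
    return s_salt * s_salt * f_acid * f_base


def salt_solubility(system: SaltSystem, ph: float) -> float:
    """Salt solubility [M] at the given pH.

    Equals sqrt(Ksp) when both the drug and the counterion are fully ionized
    (pKa,acid + 2 < pH < pKa,counterion - 2); rises towards lower pH (drug
    protonation) and towards higher pH (counterion deprotonation), with a
    unique minimum between the two pK_a values.
    """
    _check_ph(ph)
    acid_term = 1.0 + 10.0 ** (system.pka_acid - ph)
    base_term = 1.0 + 10.0 ** (ph - system.pka_counterion)
    return math.sqrt(system.ksp * acid_term * base_term)


def acid_solubility(system: SaltSystem, ph: float) -> float:
    """Free-acid solubility [M] at the given pH: S0·(1 + 10^(pH − pKa,acid))."""
    _check_ph(ph)
    return system.s0 * (1.0 + 10.0 ** (ph - system.pka_acid))


def ph_max(system: SaltSystem, *, method: str = "closed_form") -> float:
    """pH at which salt and free-acid solubility curves intersect.

    ``method="closed_form"`` evaluates pKa,acid + log10(sqrt(Ksp)/S0), exact
    when both species are fully ionized at the intersection.
    ``method="numeric"`` root-finds S_salt(pH) − S_acid(pH) on
    (pKa,acid, pKa,counterion + 4), which also captures the small correction
    when the counterion is only partially ionized there.
    """
    closed = system.pka_acid + math.log10(math.sqrt(system.ksp) / system.s0)
    if method == "closed_form":
        return closed
    if method == "numeric":
        def gap(ph_):
            return salt_solubility(system, ph_) - acid_solubility(system, ph_)

        lo = system.pka_acid
        hi = min(system.pka_counterion + 4.0, 13.9)
        # S_salt > S_acid at low pH; the gap changes sign exactly once above.
        if gap(lo) <= 0:
            raise ValueError("no intersection: salt not more soluble at low pH")
        return brentq(gap, lo, hi, xtol=1e-10)
    raise ValueError(f"unknown method {method!r}")


def supersaturation_ratio(system: SaltSystem, ph: float) -> float:
    """Ratio S_salt/S_acid at the given pH.

    Above 1 below pH_max (the salt can supersaturate the solution with
    respect to the acid), exactly 1 at pH_max in the fully-ionized regime,
    and decreasing as pH rises towards pH_max.
    """
    return salt_solubility(system, ph) / acid_solubility(system, ph)


def phase_state(system: SaltSystem, c_total: float, ph: float) -> PhaseState:
    """Classify a bulk solution by its saturation ratios at the given pH."""
    if c_total < 0:
        raise ValueError("c_total must be non-negative")
    sigma_acid = c_total / acid_solubility(system, ph)
    sigma_salt = c_total / salt_solubility(system, ph)
    if sigma_acid > 1 and sigma_salt > 1:
        cls = PhaseClassification.SUPERSATURATED_VS_BOTH
    elif sigma_acid > 1:
        cls = PhaseClassification.SUPERSATURATED_VS_ACID
    else:
        cls = PhaseClassification.UNDERSATURATED
    return PhaseState(sigma_acid=sigma_acid, sigma_salt=sigma_salt, classification=cls)


def solubility_curve(system: SaltSystem, ph_grid) -> np.ndarray:
    """Vectorized (n, 4) table: pH, S_salt [M], S_acid [M], S_salt/S_acid."""
    ph_grid = np.asarray(ph_grid, dtype=float)
    s_salt = np.array([salt_solubility(system, p) for p in ph_grid])
    s_acid = np.array([acid_solubility(system, p) for p in ph_grid])
    return np.column_stack([ph_grid, s_salt, s_acid, s_salt / s_acid])
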