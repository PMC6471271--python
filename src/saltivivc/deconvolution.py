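"""Loo-Riegelman mass-balance deconvolution for two-compartment drugs.

Given an oral plasma profile C(t) and the disposition constants fitted to IV
data, the cumulative absorbed amount (expressed per unit of central volume,
i.e. in concentration units) is

    X_A(t)/Vc = C(t) + k10·AUC(0→t) + P(t),

where P(t) = X_P(t)/Vc is the peripheral amount per central volume,

    P(t) = k12 · e^(−k21·t) · ∫0^t C(τ)·e^(k21·τ) dτ.

The integral is evaluated segment-by-segment assuming C is piecewise linear
between samples, which makes the discrete update exact for such profiles:

    P_n = P_{n−1}·e^(−k21·Δt) + k12·(a·C_{n−1} + b·C_n),

with interval weights a, b derived from the exponentially-weighted integral
of the linear interpolant. Fractions absorbed are obtained by normalizing to
the terminal plateau (absolute bioavailability is unidentifiable without IV
data in the same subjects); a non-decreasing isotonic pass is applied to the
fraction output only, with the raw amounts retained in metadata.

With k12 = 0 the peripheral term vanishes and the method reduces exactly to
Wagner-Nelson, provided here as :func:`wagner_nelson` for cross-checks.
"""

from __future__ import annotations

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .pk import DispositionParams
from .profiles import ConcentrationTimeProfile, FractionProfile

__all__ = [
    "cumulative_auc",
    "peripheral_profile",
    "loo_riegelman",
    "wagner_nelson",
    "normalize_cross_study",
    "TruncatedAbsorptionError",
]


class TruncatedAbsorptionError(ValueError):
    """Raised when the deconvolved amounts have not reached a flat plateau."""


def cumulative_auc(profile: ConcentrationTimeProfile) -> np.ndarray:
    """Cumulative linear-trapezoid AUC at every sampling time (first value 0)."""
    t, c = profile.times, profile.concentrations
    if t.size == 1:
        return np.zeros(1)
    seg = 0.5 * (c[1:] + c[:-1]) * np.diff(t)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _peripheral_weights(k21: float, dt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-interval weights (a, b) of C_{n-1} and C_n in the exact
    piecewise-linear peripheral update."""
    e = np.exp(-k21 * dt)
    b = 1.0 / k21 - (1.0 - e) / (k21 * k21 * dt)
    a = (1.0 - e) / k21 - b
    return a, b


def peripheral_profile(
    profile: ConcentrationTimeProfile, params: DispositionParams
) -> np.ndarray:
    """Peripheral amount over central volume P(t) at each sampling time.

    Exact for concentrations that are piecewise linear between samples. The
    profile must describe extravascular dosing, i.e. start from C = 0 at the
    first sample (time 0).
    """
    prof = profile.in_time_unit("h")
    t, c = prof.times, prof.concentrations
    p = np.zeros_like(c)
    if t.size == 1:
        return p
    dt = np.diff(t)
    a, b = _peripheral_weights(params.k21, dt)
    e = np.exp(-params.k21 * dt)
    for i in range(1, t.size):
        p[i] = p[i - 1] * e[i - 1] + params.k12 * (a[i - 1] * c[i - 1] + b[i - 1] * c[i])
    return p


def _amounts_to_fractions(
    times: np.ndarray,
    amounts: np.ndarray,
    *,
    time_unit: str,
    label: str,
    plateau_rtol: float,
    extra_meta: dict,
) -> FractionProfile:
    if amounts[-1] <= 0:
        raise ValueError("deconvolved amounts are all zero; nothing to normalize")
    rel_step = abs(amounts[-1] - amounts[-2]) / amounts[-1]
    if rel_step > plateau_rtol:
        raise TruncatedAbsorptionError(
            f"terminal plateau not reached: last step changes the deconvolved "
            f"amount by {100 * rel_step:.1f}% (> {100 * plateau_rtol:.0f}%); "
            "the absorption phase appears truncated"
        )
    iso = IsotonicRegression(increasing=True)
    mono = iso.fit_transform(times, amounts)
    plateau = mono[-1]
    fractions = np.clip(mono / plateau, 0.0, 1.0)
    if times[0] == 0:
        fractions[0] = 0.0
    meta = {"raw_amounts_over_v1": amounts, "plateau_over_v1": float(plateau)}
    meta.update(extra_meta)
    return FractionProfile(
        times=times, fractions=fractions, basis="absorbed",
        label=label, time_unit=time_unit, metadata=meta,
    )


def loo_riegelman(
    profile: ConcentrationTimeProfile,
    params: DispositionParams,
    *,
    plateau_rtol: float = 0.05,
    backextrapolate_c0: bool = False,
) -> FractionProfile:
    """Deconvolve an oral plasma profile into a fraction-absorbed curve.

    The profile must start at C = 0 (oral dosing). A nonzero first
    concentration raises unless ``backextrapolate_c0`` accepts it by
    back-extrapolating the initial sample to zero. Raises
    :class:`TruncatedAbsorptionError` when the deconvolved amounts still
    change by more than ``plateau_rtol`` (relative) over the final interval.

    Returns a :class:`FractionProfile` normalized to the terminal plateau;
    the raw amounts per central volume and the plateau value are kept in
    ``metadata`` for reconvolution.
    """
    prof = profile.in_time_unit("h")
    c = prof.concentrations.copy()
    if c[0] != 0:
        if not backextrapolate_c0:
            raise ValueError(
                "oral profiles must start at C=0; pass backextrapolate_c0=True "
                "to accept a nonzero first sample"
            )
        c[0] = 0.0
        prof = prof.with_concentrations(c)
    auc = cumulative_auc(prof)
    p = peripheral_profile(prof, params)
    amounts = prof.concentrations + params.k10 * auc + p
    out = _amounts_to_fractions(
        profile.times.copy(), amounts,
        time_unit=profile.time_unit, label=profile.label,
        plateau_rtol=plateau_rtol,
        extra_meta={"method": "loo_riegelman", "params": params},
    )
    return out


def wagner_nelson(
    profile: ConcentrationTimeProfile,
    k10: float,
    *,
    plateau_rtol: float = 0.05,
) -> FractionProfile:
    """One-compartment mass-balance deconvolution (X_A/V = C + k10·AUC).

    The limiting case of Loo-Riegelman for a drug without a peripheral
    compartment; used as an independent cross-check when k12 = 0.
    """
    prof = profile.in_time_unit("h")
    if prof.concentrations[0] != 0:
        raise ValueError("oral profiles must start at C=0")
    amounts = prof.concentrations + k10 * cumulative_auc(prof)
    return _amounts_to_fractions(
        profile.times.copy(), amounts,
        time_unit=profile.time_unit, label=profile.label,
        plateau_rtol=plateau_rtol, extra_meta={"method": "wagner_nelson"},
    )


def normalize_cross_study(
    test: ConcentrationTimeProfile,
    ref_in_test_study: ConcentrationTimeProfile,
    ref_in_anchor_study: ConcentrationTimeProfile,
    *,
    mode: str = "pointwise",
    floor: float = 1e-9,
) -> ConcentrationTimeProfile:
    """Rescale a test profile from one trial onto another trial's scale.

    Oral profiles measured in different bioequivalence trials carry
    trial-specific bioanalytical scale; with the reference formulation dosed
    in both trials, each test concentration is multiplied by
    ``ref_anchor(t)/ref_test_study(t)`` (``mode="pointwise"``) or by the
    single ratio of reference AUCs (``mode="auc"``). All three profiles must
    share sampling times; reference values below ``floor`` are rejected.
    """
    for ref in (ref_in_test_study, ref_in_anchor_study):
        if ref.time_unit != test.time_unit or not np.allclose(ref.times, test.times):
            raise ValueError(
                "profiles must share sampling times; align them first"
            )
    if mode == "pointwise":
        denom = ref_in_test_study.concentrations
        low = denom < floor
        # a zero reference is tolerable only where the test is also zero
        # (e.g. the pre-dose sample): the factor is then immaterial.
        if np.any(low & (test.concentrations >= floor)):
            raise ValueError(
                f"reference concentrations below the floor ({floor}) at times "
                "where the test profile is nonzero; use mode='auc' or raise "
                "the floor deliberately"
            )
        factor = np.ones_like(denom)
        np.divide(ref_in_anchor_study.concentrations, denom, out=factor, where=~low)
    elif mode == "auc":
        auc_ref = cumulative_auc(ref_in_test_study)[-1]
        if auc_ref < floor:
            raise ValueError("reference AUC below the floor")
        factor = cumulative_auc(ref_in_anchor_study)[-1] / auc_ref
    else:
        raise ValueError("mode must be 'pointwise' or 'auc'")
    out = test.with_concentrations(test.concentrations * factor)
    out.metadata = dict(test.metadata, normalization=mode)
    return out
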